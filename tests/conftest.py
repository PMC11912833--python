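import pytest

from phenokit.fixtures import make_bundle
from phenokit.pipeline import run_pipeline


@pytest.fixture(scope="session")
def bundle():
    return make_bundle(42)


@pytest.fixture(scope="session")
def refs(bundle):
    return bundle.refs


@pytest.fixture(scope="session")
def pipeline(bundle):
    return run_pipeline(bundle)


@pytest.fixture(scope="session")
def hierarchy(pipeline):
    return pipeline.hierarchy


@pytest.fixture(scope="session")
def labels(pipeline):
    return pipeline.labels
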