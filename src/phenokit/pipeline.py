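"""End-to-end orchestration: generate terms, classify, map, score.

Thin glue over the library modules so that the command-line interface, the
test-suite and reproduction scripts all execute exactly the same steps:

1. compile every pattern template against its filler table into
   species-neutral phenotype terms (``generate``);
2. classify the generated terms together with the species ontologies'
   (bridge-rewritten) EQ definitions into one rooted hierarchy
   (``classify``);
3. derive cross-species logical and lexical mappings (``map``);
4. build an annotation corpus and score cross-species similarity (``sim``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .eq_model import EQDefinition
from .eq_reasoner import (
    ConformanceReport,
    PhenotypeHierarchy,
    SubsumptionIndex,
    classify,
    conformance_report,
)
from .fixtures import PHENOTYPE_ROOT, TASTE_OLFACTION, FixtureBundle, make_corpus
from .ontology_io import Curie
from .pattern_engine import GeneratedTerm, InstantiationResult, instantiate_all
from .phenosim import AnnotationCorpus, ICIndex, similarity_table
from .xspecies_mapper import Mapping, apply_bridges, lexical_matches, logical_matches

__all__ = ["GenerationOutput", "PipelineResult", "generate_terms", "classify_bundle",
           "derive_mappings", "run_pipeline", "CURIE_MAP"]

CURIE_MAP = {
    "EX": "https://example.org/phenokit/EX_",
    "HP": "http://purl.obolibrary.org/obo/HP_",
    "MP": "http://purl.obolibrary.org/obo/MP_",
    "ZP": "http://purl.obolibrary.org/obo/ZP_",
    "UPHENO": "http://purl.obolibrary.org/obo/UPHENO_",
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "PATO": "http://purl.obolibrary.org/obo/PATO_",
    "GO": "http://purl.obolibrary.org/obo/GO_",
    "CL": "http://purl.obolibrary.org/obo/CL_",
    "CHEBI": "http://purl.obolibrary.org/obo/CHEBI_",
    "NBO": "http://purl.obolibrary.org/obo/NBO_",
    "RO": "http://purl.obolibrary.org/obo/RO_",
    "BFO": "http://purl.obolibrary.org/obo/BFO_",
    "semapv": "https://w3id.org/semapv/vocab/",
}


@dataclass
class GenerationOutput:
    per_pattern: dict[str, InstantiationResult]
    terms: list[GeneratedTerm]
    eqs: dict[Curie, EQDefinition]

    @property
    def ids(self) -> set[Curie]:
        return set(self.eqs)


def generate_terms(bundle: FixtureBundle, strict: bool = False) -> GenerationOutput:
    """Instantiate every template of the bundle's library against its filler
    table, in library order."""
    per_pattern: dict[str, InstantiationResult] = {}
    terms: list[GeneratedTerm] = []
    eqs: dict[Curie, EQDefinition] = {}
    by_name = {t.pattern_id.rsplit("/", 1)[-1].removesuffix(".yaml"): t for t in bundle.templates}
    for name, template in by_name.items():
        table = bundle.filler_tables.get(name)
        if table is None:
            continue
        result = instantiate_all(template, table, bundle.refs, bundle.minter, strict=strict)
        per_pattern[name] = result
        terms.extend(result.terms)
        eqs.update(result.eqs)
    return GenerationOutput(per_pattern=per_pattern, terms=terms, eqs=eqs)


def bundle_labels(bundle: FixtureBundle, generated: GenerationOutput) -> dict[Curie, str]:
    labels = bundle.refs.label_map()
    for species in bundle.species.values():
        labels.update(species.labels)
    for term in generated.terms:
        labels[term.id] = term.label
    labels[PHENOTYPE_ROOT] = "phenotype"
    labels[TASTE_OLFACTION] = "taste/olfaction phenotype"
    return labels


def classify_bundle(
    bundle: FixtureBundle, generated: GenerationOutput
) -> tuple[PhenotypeHierarchy, SubsumptionIndex]:
    """Classify neutral + species terms into one hierarchy.

    Species EQ definitions are bridge-rewritten to neutral anatomy first;
    generated (species-neutral) ids act as grouping terms, so species terms
    with identical definitions classify beneath them.
    """
    idx = SubsumptionIndex(bundle.refs)
    terms: dict[Curie, EQDefinition | None] = dict(generated.eqs)
    for species in bundle.species.values():
        for term_id, eq in species.eqs.items():
            terms[term_id] = None if eq is None else apply_bridges(eq, species.bridge)
    hierarchy = classify(
        terms,
        idx,
        asserted=bundle.asserted_edges(),
        root=PHENOTYPE_ROOT,
        grouping_terms=generated.ids,
    )
    return hierarchy, idx


def conformance_reports(bundle: FixtureBundle) -> dict[str, ConformanceReport]:
    """Per-species conformance of (bridge-rewritten) definitions against the
    template library."""
    out: dict[str, ConformanceReport] = {}
    for name, species in sorted(bundle.species.items()):
        bridged = {
            term_id: (None if eq is None else apply_bridges(eq, species.bridge))
            for term_id, eq in species.eqs.items()
        }
        out[name] = conformance_report(bridged, bundle.templates, bundle.refs)
    return out


def derive_mappings(
    bundle: FixtureBundle,
    labels: dict[Curie, str],
    include_lexical: bool = True,
) -> list[Mapping]:
    """Logical (and optionally lexical) matches over every species pair."""
    names = sorted(bundle.species)
    mappings: list[Mapping] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = bundle.species[a], bundle.species[b]
            eqs_a = {c: eq for c, eq in sa.eqs.items() if eq is not None}
            eqs_b = {c: eq for c, eq in sb.eqs.items() if eq is not None}
            mappings.extend(
                logical_matches(eqs_a, eqs_b, sa.bridge, sb.bridge, labels=labels)
            )
            if include_lexical:
                mappings.extend(
                    lexical_matches(sa.lexical_entries(), sb.lexical_entries())
                )
    return mappings


@dataclass
class PipelineResult:
    bundle: FixtureBundle
    generated: GenerationOutput
    labels: dict[Curie, str]
    hierarchy: PhenotypeHierarchy
    idx: SubsumptionIndex
    conformance: dict[str, ConformanceReport]
    mappings: list[Mapping]
    corpus: AnnotationCorpus
    ic_index: ICIndex
    similarity: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    bundle: FixtureBundle,
    n_genes: int = 60,
    zipf_exponent: float = 1.2,
    similarity_threshold: float = 0.0,
    similarity_pair: tuple[str, str] = ("human", "mouse"),
) -> PipelineResult:
    generated = generate_terms(bundle)
    labels = bundle_labels(bundle, generated)
    hierarchy, idx = classify_bundle(bundle, generated)
    conformance = conformance_reports(bundle)
    mappings = derive_mappings(bundle, labels)
    corpus = make_corpus(bundle.seed, n_genes, zipf_exponent, hierarchy)
    ic_index = ICIndex(hierarchy, corpus)
    a, b = similarity_pair
    sim = similarity_table(
        sorted(bundle.species[a].eqs, key=str),
        sorted(bundle.species[b].eqs, key=str),
        hierarchy,
        ic_index,
        threshold=similarity_threshold,
    )
    return PipelineResult(
        bundle=bundle,
        generated=generated,
        labels=labels,
        hierarchy=hierarchy,
        idx=idx,
        conformance=conformance,
        mappings=mappings,
        corpus=corpus,
        ic_index=ic_index,
        similarity=sim,
    )
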