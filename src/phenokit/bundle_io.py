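"""Serialize a fixture bundle to (and load it back from) plain-text files.

Layout under the bundle directory::

    bundle.yaml                    seed, root CURIEs, file manifest
    refs/<name>.obo                reference graphs (quality, anatomy, ...)
    templates/<pattern>.yaml       template library
    fillers/<pattern>.tsv          filler tables
    species/<name>.obo             species phenotype ontologies; each term's
                                   EQ is carried as a `logical_definition`
                                   annotation in the Manchester grammar
    species/<name>_bridge.tsv      anatomy bridge tables
    asserted.tsv                   manually asserted (child, parent, comment)
    minter_ledger.json             minted-id ledger

Everything is written deterministically (sorted, atomic), so regenerating a
bundle with the same seed produces byte-identical files.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import yaml

from .cli_util import atomic_write_text
from .eq_model import parse_manchester, render_manchester
from .errors import ParseError
from .fixtures import FixtureBundle, SpeciesOntology, make_minter
from .ontology_io import Curie, OntologyGraph, OntologyTerm, as_curie, load_graph, save_graph
from .pattern_engine import FillerTable, IdMinter, dump_template, load_template_file
from .references import References
from .xspecies_mapper import BridgeTable

__all__ = ["write_bundle", "load_bundle"]

EQ_TAG = "logical_definition"


def write_bundle(bundle: FixtureBundle, directory: str | os.PathLike) -> None:
    directory = Path(directory)
    ref_names = ["quality"] + sorted(bundle.refs.entity_graphs)
    manifest = {
        "seed": bundle.seed,
        "quality_root": str(bundle.refs.quality_root),
        "modifier_root": str(bundle.refs.modifier_root),
        "process_root": str(bundle.refs.process_root),
        "reference_graphs": ref_names,
        "species": sorted(bundle.species),
        "templates": sorted(
            t.pattern_id.rsplit("/", 1)[-1].removesuffix(".yaml") for t in bundle.templates
        ),
    }
    atomic_write_text(directory / "bundle.yaml", yaml.safe_dump(manifest, sort_keys=False))

    save_graph(bundle.refs.quality, str(directory / "refs" / "quality.obo"))
    for name in sorted(bundle.refs.entity_graphs):
        save_graph(bundle.refs.entity_graphs[name], str(directory / "refs" / f"{name}.obo"))

    for template in bundle.templates:
        name = template.pattern_id.rsplit("/", 1)[-1].removesuffix(".yaml")
        atomic_write_text(directory / "templates" / f"{name}.yaml", dump_template(template))
    for name in sorted(bundle.filler_tables):
        atomic_write_text(directory / "fillers" / f"{name}.tsv", bundle.filler_tables[name].to_tsv())

    labels = bundle.refs.label_map()
    for name in sorted(bundle.species):
        species = bundle.species[name]
        graph = OntologyGraph(species.graph.ontology_id, species.graph.version)
        for curie in sorted(species.graph.terms):
            term = species.graph.terms[curie]
            annotations = list(term.annotations)
            eq = species.eqs.get(curie)
            if eq is not None:
                annotations.append((EQ_TAG, render_manchester(eq, labels)))
            graph.add_term(
                OntologyTerm(
                    id=term.id,
                    label=term.label,
                    text_definition=term.text_definition,
                    synonyms=term.synonyms,
                    obsolete=term.obsolete,
                    annotations=tuple(annotations),
                )
            )
        for e in species.graph.edges:
            graph.add_edge(e.subject, e.predicate, e.object)
        save_graph(graph, str(directory / "species" / f"{name}.obo"))
        atomic_write_text(directory / "species" / f"{name}_bridge.tsv", species.bridge.to_tsv())

    atomic_write_text(directory / "asserted.tsv", bundle.asserted_tsv())
    atomic_write_text(directory / "minter_ledger.json", bundle.minter.ledger_json())


def load_bundle(directory: str | os.PathLike) -> FixtureBundle:
    directory = Path(directory)
    with open(directory / "bundle.yaml", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)

    quality = load_graph(str(directory / "refs" / "quality.obo"))
    entity_graphs = {
        name: load_graph(str(directory / "refs" / f"{name}.obo"))
        for name in manifest["reference_graphs"]
        if name != "quality"
    }
    refs = References(
        quality=quality,
        entity_graphs=entity_graphs,
        quality_root=as_curie(manifest["quality_root"]),
        modifier_root=as_curie(manifest["modifier_root"]),
        process_root=as_curie(manifest["process_root"]),
    )
    label_to_id = {label: curie for curie, label in sorted(refs.label_map().items())}

    templates = [
        load_template_file(str(directory / "templates" / f"{name}.yaml"))
        for name in manifest["templates"]
    ]
    filler_tables = {}
    for name in manifest["templates"]:
        path = directory / "fillers" / f"{name}.tsv"
        if path.exists():
            filler_tables[name] = FillerTable.from_tsv(
                path.read_text(encoding="utf-8"), source=path.name
            )

    species = {}
    for name in manifest["species"]:
        graph = load_graph(str(directory / "species" / f"{name}.obo"))
        eqs = {}
        clean = OntologyGraph(graph.ontology_id, graph.version)
        for curie in sorted(graph.terms):
            term = graph.terms[curie]
            kept = []
            eq = None
            for tag, value in term.annotations:
                if tag == EQ_TAG:
                    eq = parse_manchester(value, label_to_id)
                else:
                    kept.append((tag, value))
            eqs[curie] = eq
            clean.add_term(
                OntologyTerm(
                    id=term.id,
                    label=term.label,
                    text_definition=term.text_definition,
                    synonyms=term.synonyms,
                    obsolete=term.obsolete,
                    annotations=tuple(kept),
                )
            )
        for e in graph.edges:
            clean.add_edge(e.subject, e.predicate, e.object)
        bridge_path = directory / "species" / f"{name}_bridge.tsv"
        bridge = (
            BridgeTable.from_tsv(bridge_path.read_text(encoding="utf-8"))
            if bridge_path.exists()
            else BridgeTable(rows={})
        )
        species[name] = SpeciesOntology(name=name, graph=clean, eqs=eqs, bridge=bridge)

    asserted = []
    asserted_path = directory / "asserted.tsv"
    if asserted_path.exists():
        for lineno, line in enumerate(asserted_path.read_text(encoding="utf-8").splitlines()):
            if lineno == 0 or not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ParseError(f"asserted.tsv line {lineno + 1}: expected >= 2 columns")
            comment = cells[2] if len(cells) > 2 else ""
            asserted.append((as_curie(cells[0]), as_curie(cells[1]), comment))

    minter = make_minter()
    ledger_path = directory / "minter_ledger.json"
    if ledger_path.exists():
        ledger = json.loads(ledger_path.read_text(encoding="utf-8"))
        minter.ledger.update({k: as_curie(v) for k, v in ledger.items()})
        minter._taken.update(minter.ledger.values())

    return FixtureBundle(
        seed=int(manifest["seed"]),
        refs=refs,
        templates=templates,
        filler_tables=filler_tables,
        species=species,
        minter=minter,
        asserted=asserted,
    )
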