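"""Deterministic synthetic fixtures: mini reference ontologies, a template
library, filler tables, three species phenotype ontologies with anatomy
bridges, and a gene-annotation corpus.

These stand in for the real reference hierarchies (a PATO-like quality
graph, an Uberon-like anatomy, GO-like processes, CL-like cells, ChEBI-like
chemicals) at desk scale.  Identifiers follow one rule: ids that are fixed
points of the public cross-species phenomics landscape (heart, aortic valve,
forelimb zeugopod, morphology, thickness, abnormal, the Cardiomegaly /
enlarged-heart / heart-increased-size trio, and their species-neutral
grouping classes) keep their canonical CURIEs; everything else is minted in
a fixture-local ``EX:`` namespace.

Everything is seed-deterministic: regenerating a bundle with the same seed
serializes byte-identically.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import ValidationError
from .eq_model import EntityExpression, EQDefinition
from .eq_reasoner import CONFORMANT, EQ_NOT_CONFORMANT, NO_EQ
from .ontology_io import (
    IS_A,
    PART_OF,
    Curie,
    OntologyGraph,
    OntologyTerm,
    as_curie,
)
from .pattern_engine import FillerTable, IdMinter, PatternTemplate, load_template
from .phenosim import AnnotationCorpus
from .references import References
from .xspecies_mapper import BridgeTable

__all__ = [
    "PHENOTYPE_ROOT",
    "ABNORMAL",
    "QUALITY_ROOT",
    "SpeciesOntology",
    "FixtureBundle",
    "make_reference_fixture",
    "make_template_library",
    "make_filler_tables",
    "make_species_fixture",
    "make_corpus",
    "make_bundle",
]

# Fixed-point CURIEs of the cross-species phenomics landscape.
PHENOTYPE_ROOT = Curie("EX", "0000000")
QUALITY_ROOT = Curie("EX", "Q0000001")
MODIFIER_ROOT = Curie("EX", "Q0000090")
ABNORMAL = Curie("PATO", "0000460")
NORMAL = Curie("EX", "Q0000091")
MORPHOLOGY = Curie("PATO", "0000051")
THICKNESS = Curie("PATO", "0000915")
DECREASED_PROCESS_QUALITY = Curie("PATO", "2302".zfill(7))
SIZE = Curie("EX", "Q0000010")
INCREASED_SIZE = Curie("EX", "Q0000011")
DECREASED_SIZE = Curie("EX", "Q0000012")
INCREASED_THICKNESS = Curie("EX", "Q0000013")
PROCESS_QUALITY = Curie("EX", "Q0000030")
FRAGILITY = Curie("EX", "Q0000032")  # deliberately not used by any template
AMOUNT = Curie("EX", "Q0000020")
INCREASED_AMOUNT = Curie("EX", "Q0000021")
DECREASED_AMOUNT = Curie("EX", "Q0000022")
FUSED_WITH = Curie("EX", "Q0000016")

ANATOMICAL_ENTITY = Curie("UBERON", "0001062")
HEART = Curie("UBERON", "0000948")
AORTIC_VALVE = Curie("UBERON", "0002137")
AORTIC_VALVE_LEAFLET = Curie("EX", "A0000001")
FORELIMB_ZEUGOPOD = Curie("UBERON", "0002386")
BIOLOGICAL_PROCESS = Curie("GO", "0008150")
BEHAVIOR_PROCESS = Curie("NBO", "0000313")
CELL = Curie("CL", "0000000")
CHEMICAL_ENTITY = Curie("CHEBI", "24431")
METABOLITE = Curie("CHEBI", "25212")
CHEMICAL_ROLE = Curie("CHEBI", "50906")

HP_CARDIOMEGALY = Curie("HP", "0001640")
MP_ENLARGED_HEART = Curie("MP", "0000274")
ZP_HEART_INCREASED_SIZE = Curie("ZP", "0000532")
HP_ABNORMAL_FOREARM = Curie("HP", "0002973")
MP_ABNORMAL_ZEUGOPOD = Curie("MP", "0003855")
TASTE_OLFACTION = Curie("UPHENO", "3000006")

UPHENO_INCREASED_HEART_SIZE = Curie("UPHENO", "0001471")
UPHENO_SIZE_OF_HEART = Curie("UPHENO", "0075162")
UPHENO_HEART_MORPHOLOGY = Curie("UPHENO", "0076810")
UPHENO_INCREASED_LEAFLET_THICKNESS = Curie("UPHENO", "0047922")

FISH_HEART = Curie("EX", "F0000001")
FISH_FIN_RADIAL = Curie("EX", "F0000002")
FISH_EYE = Curie("EX", "F0000003")

PATTERN_BASE = "https://example.org/phenokit/patterns/"


def _term(graph: OntologyGraph, curie: Curie, label: str, *parents, part_of=()):
    graph.add_term(OntologyTerm(id=curie, label=label))
    for p in parents:
        graph.add_edge(curie, IS_A, p)
    for p in part_of:
        graph.add_edge(curie, PART_OF, p)
    return curie


def make_reference_fixture(seed: int = 42) -> References:
    """Mini quality / anatomy / process / cell / chemical reference graphs.

    The quality graph encodes thickness ⊑ morphology and size ⊑ morphology;
    the anatomy graph encodes aortic valve part_of heart and a leaflet
    part_of the aortic valve, so mixed is_a/part_of chains reach the heart.
    The structure is fixed; ``seed`` only participates in the determinism
    contract.
    """
    del seed  # structure is fixed
    quality = OntologyGraph("mini-quality", "fixture-1")
    _term(quality, QUALITY_ROOT, "quality")
    _term(quality, MORPHOLOGY, "morphology", QUALITY_ROOT)
    _term(quality, SIZE, "size", MORPHOLOGY)
    _term(quality, INCREASED_SIZE, "increased size", SIZE)
    _term(quality, DECREASED_SIZE, "decreased size", SIZE)
    _term(quality, THICKNESS, "thickness", MORPHOLOGY)
    _term(quality, INCREASED_THICKNESS, "increased thickness", THICKNESS)
    _term(quality, Curie("EX", "Q0000014"), "decreased thickness", THICKNESS)
    _term(quality, Curie("EX", "Q0000015"), "length", MORPHOLOGY)
    _term(quality, FUSED_WITH, "fused with", MORPHOLOGY)
    _term(quality, AMOUNT, "amount", QUALITY_ROOT)
    _term(quality, INCREASED_AMOUNT, "increased amount", AMOUNT)
    _term(quality, DECREASED_AMOUNT, "decreased amount", AMOUNT)
    _term(quality, PROCESS_QUALITY, "process quality", QUALITY_ROOT)
    _term(quality, DECREASED_PROCESS_QUALITY, "decreased process quality", PROCESS_QUALITY)
    _term(quality, Curie("EX", "Q0000031"), "increased process quality", PROCESS_QUALITY)
    _term(quality, FRAGILITY, "fragility", QUALITY_ROOT)
    _term(quality, MODIFIER_ROOT, "phenotypic modifier")
    _term(quality, ABNORMAL, "abnormal", MODIFIER_ROOT)
    _term(quality, NORMAL, "normal", MODIFIER_ROOT)

    anatomy = OntologyGraph("mini-anatomy", "fixture-1")
    _term(anatomy, ANATOMICAL_ENTITY, "anatomical entity")
    _term(anatomy, HEART, "heart", ANATOMICAL_ENTITY)
    _term(anatomy, AORTIC_VALVE, "aortic valve", ANATOMICAL_ENTITY, part_of=[HEART])
    _term(anatomy, AORTIC_VALVE_LEAFLET, "aortic valve leaflet", ANATOMICAL_ENTITY,
          part_of=[AORTIC_VALVE])
    _term(anatomy, Curie("EX", "A0000012"), "cardiac ventricle", ANATOMICAL_ENTITY,
          part_of=[HEART])
    _term(anatomy, FORELIMB_ZEUGOPOD, "forelimb zeugopod", ANATOMICAL_ENTITY)
    for local, label in [
        ("A0000002", "kidney"),
        ("A0000003", "lung"),
        ("A0000004", "liver"),
        ("A0000005", "brain"),
        ("A0000006", "eye"),
        ("A0000007", "tail"),
        ("A0000008", "bone"),
        ("A0000009", "blood vessel"),
        ("A0000010", "stomach"),
        ("A0000011", "limb"),
    ]:
        _term(anatomy, Curie("EX", local), label, ANATOMICAL_ENTITY)

    process = OntologyGraph("mini-process", "fixture-1")
    _term(process, BIOLOGICAL_PROCESS, "biological process")
    _term(process, BEHAVIOR_PROCESS, "behavior process", BIOLOGICAL_PROCESS)
    _term(process, Curie("EX", "P0000001"), "blood circulation", BIOLOGICAL_PROCESS)
    _term(process, Curie("EX", "P0000002"), "glycolysis", BIOLOGICAL_PROCESS)
    _term(process, Curie("EX", "P0000003"), "digestion", BIOLOGICAL_PROCESS)
    _term(process, Curie("EX", "P0000004"), "neural tube closure", BIOLOGICAL_PROCESS)

    cell = OntologyGraph("mini-cell", "fixture-1")
    _term(cell, CELL, "cell")
    _term(cell, Curie("EX", "C0000001"), "neuron", CELL)
    _term(cell, Curie("EX", "C0000002"), "cardiomyocyte", CELL)
    _term(cell, Curie("EX", "C0000003"), "erythrocyte", CELL)

    chemical = OntologyGraph("mini-chemical", "fixture-1")
    _term(chemical, CHEMICAL_ENTITY, "chemical entity")
    _term(chemical, METABOLITE, "metabolite", CHEMICAL_ENTITY)
    _term(chemical, Curie("EX", "H0000001"), "glucose", METABOLITE)
    _term(chemical, Curie("EX", "H0000002"), "calcium", CHEMICAL_ENTITY)
    _term(chemical, CHEMICAL_ROLE, "role")
    _term(chemical, Curie("EX", "H0000011"), "toxin role", CHEMICAL_ROLE)

    # Fish-local anatomy, bridged to the species-neutral anatomy.
    fish_anatomy = OntologyGraph("mini-fish-anatomy", "fixture-1")
    _term(fish_anatomy, Curie("EX", "F0000000"), "fish anatomical entity")
    _term(fish_anatomy, FISH_HEART, "cardiac organ", Curie("EX", "F0000000"))
    _term(fish_anatomy, FISH_FIN_RADIAL, "pectoral fin radial", Curie("EX", "F0000000"))
    _term(fish_anatomy, FISH_EYE, "optic organ", Curie("EX", "F0000000"))

    return References(
        quality=quality,
        entity_graphs={
            "anatomy": anatomy,
            "process": process,
            "cell": cell,
            "chemical": chemical,
            "fish_anatomy": fish_anatomy,
        },
        quality_root=QUALITY_ROOT,
        modifier_root=MODIFIER_ROOT,
        process_root=BIOLOGICAL_PROCESS,
    )


# ---------------------------------------------------------------------------
# Template library
# ---------------------------------------------------------------------------

_CONTRIBUTORS = [
    "https://orcid.org/0000-0000-0000-0001",
    "https://orcid.org/0000-0000-0000-0002",
    "https://orcid.org/0000-0000-0000-0003",
]

_COMMON_CLASSES = {
    "quality": str(QUALITY_ROOT),
    "morphology": str(MORPHOLOGY),
    "size": str(SIZE),
    "increased size": str(INCREASED_SIZE),
    "decreased size": str(DECREASED_SIZE),
    "thickness": str(THICKNESS),
    "increased thickness": str(INCREASED_THICKNESS),
    "amount": str(AMOUNT),
    "increased amount": str(INCREASED_AMOUNT),
    "decreased amount": str(DECREASED_AMOUNT),
    "process quality": str(PROCESS_QUALITY),
    "decreased process quality": str(DECREASED_PROCESS_QUALITY),
    "fused with": str(FUSED_WITH),
    "abnormal": str(ABNORMAL),
    "anatomical entity": str(ANATOMICAL_ENTITY),
    "biological process": str(BIOLOGICAL_PROCESS),
    "cell": str(CELL),
    "chemical entity": str(CHEMICAL_ENTITY),
}

_RELATION_DECLS = {
    "has part": "BFO:0000051",
    "characteristic of": "RO:0000052",
    "characteristic of part of": "RO:0002314",
    "has modifier": "RO:0002573",
    "occurs in": "BFO:0000066",
    "towards": "RO:0002503",
}


def _template_yaml(
    name: str,
    description: str,
    var_ranges: dict[str, str],
    name_text: str,
    def_text: str,
    eq_text: str,
    synonyms: list[str] | None = None,
) -> str:
    import yaml as _yaml

    var_names = list(var_ranges)
    doc = {
        "pattern_iri": PATTERN_BASE + name + ".yaml",
        "pattern_name": name,
        "description": description,
        "contributors": list(_CONTRIBUTORS),
        "classes": dict(_COMMON_CLASSES),
        "relations": dict(_RELATION_DECLS),
        "vars": {v: rng for v, rng in var_ranges.items()},
        "name": {"text": name_text, "vars": var_names},
        "def": {"text": def_text, "vars": var_names},
        "equivalentTo": {"text": eq_text, "vars": var_names},
    }
    if synonyms:
        doc["synonyms"] = [{"text": s, "vars": var_names} for s in synonyms]
    return _yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def make_template_library() -> list[PatternTemplate]:
    """Fifteen patterns spanning the anatomy / process / cell / chemical /
    relational-quality categories of a shared phenotype pattern library."""
    anat = {"anatomical_entity": "'anatomical entity'"}
    proc = {"process": "'biological process'"}
    cellv = {"cell_type": "cell"}
    chem = {"chemical": "'chemical entity'"}

    specs = [
        (
            "abnormalAnatomicalEntity",
            "A phenotype marked by any abnormality of an anatomical entity.",
            anat,
            "abnormal %s",
            "Any abnormality of %s.",
            "'has part' some (quality and 'characteristic of part of' some %s and "
            "'has modifier' some abnormal)",
            ["%s abnormal"],
        ),
        (
            "abnormalAnatomicalEntityMorphology",
            "Any morphological abnormality of an anatomical entity or its parts.",
            anat,
            "%s morphology phenotype",
            "Any morphological abnormality of the %s or one of its parts.",
            "'has part' some (morphology and 'characteristic of part of' some %s and "
            "'has modifier' some abnormal)",
            ["abnormal %s morphology"],
        ),
        (
            "abnormalSizeOfAnatomicalEntity",
            "Any abnormality of size of an anatomical entity or its parts.",
            anat,
            "size of %s phenotype",
            "Any abnormality of the size of the %s or one of its parts.",
            "'has part' some (size and 'characteristic of part of' some %s and "
            "'has modifier' some abnormal)",
            ["abnormal %s size"],
        ),
        (
            "increasedSizeOfAnatomicalEntity",
            "An abnormally increased size of an anatomical entity.",
            anat,
            "increased size of the %s",
            "An abnormal increase in the size of the %s.",
            "'has part' some ('increased size' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            ["enlarged %s"],
        ),
        (
            "decreasedSizeOfAnatomicalEntity",
            "An abnormally decreased size of an anatomical entity.",
            anat,
            "decreased size of the %s",
            "An abnormal decrease in the size of the %s.",
            "'has part' some ('decreased size' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "increasedThicknessOfAnatomicalEntity",
            "An abnormally increased thickness of an anatomical entity.",
            anat,
            "increased thickness of the %s",
            "An abnormal increase in the thickness of the %s.",
            "'has part' some ('increased thickness' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormalThicknessOfAnatomicalEntity",
            "Any abnormality of thickness of an anatomical entity or its parts.",
            anat,
            "thickness of %s phenotype",
            "Any abnormality of the thickness of the %s or one of its parts.",
            "'has part' some (thickness and 'characteristic of part of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormalBiologicalProcess",
            "Any functional abnormality of a biological process.",
            proc,
            "abnormal %s",
            "Any functional abnormality of the process %s.",
            "'has part' some ('process quality' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormallyDecreasedRateOfBiologicalProcess",
            "An abnormally decreased rate of a continuous biological process.",
            proc,
            "decreased rate of %s",
            "An abnormal decrease in the rate of %s.",
            "'has part' some ('decreased process quality' and 'characteristic of' some %s "
            "and 'has modifier' some abnormal)",
            ["%s decreased rate, abnormal"],
        ),
        (
            "abnormalBiologicalProcessInAnatomicalEntity",
            "An abnormality of a process taking place in a given anatomical location.",
            {**proc, "location": "'anatomical entity'"},
            "abnormal %s in the %s",
            "Any abnormality of %s occurring in the %s.",
            "'has part' some ('process quality' and 'characteristic of' some "
            "(%s and 'occurs in' some %s) and 'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormallyIncreasedNumberOfCell",
            "An abnormally increased number of cells of a given type.",
            cellv,
            "increased number of %s",
            "An abnormal increase in the number of cells of type %s.",
            "'has part' some ('increased amount' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormallyDecreasedNumberOfCell",
            "An abnormally decreased number of cells of a given type.",
            cellv,
            "decreased number of %s",
            "An abnormal decrease in the number of cells of type %s.",
            "'has part' some ('decreased amount' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormalCellMorphology",
            "Any morphological abnormality of a cell type or its parts.",
            cellv,
            "%s morphology phenotype",
            "Any morphological abnormality of cells of type %s.",
            "'has part' some (morphology and 'characteristic of part of' some %s and "
            "'has modifier' some abnormal)",
            None,
        ),
        (
            "abnormallyIncreasedLevelOfChemical",
            "An abnormally increased level of a chemical entity.",
            chem,
            "increased level of %s",
            "An abnormal increase in the amount of %s.",
            "'has part' some ('increased amount' and 'characteristic of' some %s and "
            "'has modifier' some abnormal)",
            ["abnormally increased %s levels"],
        ),
        (
            "fusedAnatomicalEntities",
            "Two anatomical entities abnormally fused with one another.",
            {"anatomical_entity": "'anatomical entity'", "fused_to": "'anatomical entity'"},
            "%s fused with %s",
            "The %s is abnormally fused with the %s.",
            "'has part' some ('fused with' and 'characteristic of' some %s and "
            "'has modifier' some abnormal and towards some %s)",
            None,
        ),
    ]
    return [
        load_template(_template_yaml(name, desc, vars_, nm, df, eq, syn))
        for name, desc, vars_, nm, df, eq, syn in specs
    ]


def make_filler_tables() -> dict[str, FillerTable]:
    """Filler tables keyed by pattern name."""

    def table(columns: tuple[str, ...], rows: list[tuple[Curie, ...]], source: str) -> FillerTable:
        return FillerTable(
            rows=[dict(zip(columns, row)) for row in rows], columns=columns, source=source
        )

    kidney = Curie("EX", "A0000002")
    lung = Curie("EX", "A0000003")
    liver = Curie("EX", "A0000004")
    brain = Curie("EX", "A0000005")
    eye = Curie("EX", "A0000006")
    tail = Curie("EX", "A0000007")
    bone = Curie("EX", "A0000008")
    vessel = Curie("EX", "A0000009")
    limb = Curie("EX", "A0000011")
    circulation = Curie("EX", "P0000001")
    glycolysis = Curie("EX", "P0000002")
    digestion = Curie("EX", "P0000003")
    neuron = Curie("EX", "C0000001")
    cardiomyocyte = Curie("EX", "C0000002")
    erythrocyte = Curie("EX", "C0000003")
    glucose = Curie("EX", "H0000001")
    calcium = Curie("EX", "H0000002")

    anat_col = ("anatomical_entity",)
    tables = {
        "abnormalAnatomicalEntity": table(
            anat_col, [(HEART,), (kidney,), (FORELIMB_ZEUGOPOD,), (brain,), (limb,)],
            "abnormalAnatomicalEntity.tsv",
        ),
        "abnormalAnatomicalEntityMorphology": table(
            anat_col,
            [(HEART,), (kidney,), (FORELIMB_ZEUGOPOD,), (AORTIC_VALVE_LEAFLET,), (eye,)],
            "abnormalAnatomicalEntityMorphology.tsv",
        ),
        "abnormalSizeOfAnatomicalEntity": table(
            anat_col, [(HEART,), (kidney,), (AORTIC_VALVE,)], "abnormalSizeOfAnatomicalEntity.tsv"
        ),
        "increasedSizeOfAnatomicalEntity": table(
            anat_col,
            [(HEART,), (kidney,), (liver,), (brain,), (eye,), (tail,), (lung,), (AORTIC_VALVE,)],
            "increasedSizeOfAnatomicalEntity.tsv",
        ),
        "decreasedSizeOfAnatomicalEntity": table(
            anat_col, [(HEART,), (kidney,), (brain,)], "decreasedSizeOfAnatomicalEntity.tsv"
        ),
        "increasedThicknessOfAnatomicalEntity": table(
            anat_col, [(AORTIC_VALVE_LEAFLET,), (bone,), (vessel,)],
            "increasedThicknessOfAnatomicalEntity.tsv",
        ),
        "abnormalThicknessOfAnatomicalEntity": table(
            anat_col, [(AORTIC_VALVE_LEAFLET,), (bone,)], "abnormalThicknessOfAnatomicalEntity.tsv"
        ),
        "abnormalBiologicalProcess": table(
            ("process",), [(circulation,), (digestion,), (BEHAVIOR_PROCESS,)],
            "abnormalBiologicalProcess.tsv",
        ),
        "abnormallyDecreasedRateOfBiologicalProcess": table(
            ("process",), [(circulation,), (glycolysis,), (digestion,)],
            "abnormallyDecreasedRateOfBiologicalProcess.tsv",
        ),
        "abnormalBiologicalProcessInAnatomicalEntity": table(
            ("process", "location"),
            [(glycolysis, liver), (circulation, HEART)],
            "abnormalBiologicalProcessInAnatomicalEntity.tsv",
        ),
        "abnormallyIncreasedNumberOfCell": table(
            ("cell_type",), [(neuron,), (cardiomyocyte,)], "abnormallyIncreasedNumberOfCell.tsv"
        ),
        "abnormallyDecreasedNumberOfCell": table(
            ("cell_type",), [(neuron,), (erythrocyte,)], "abnormallyDecreasedNumberOfCell.tsv"
        ),
        "abnormalCellMorphology": table(
            ("cell_type",), [(neuron,), (cardiomyocyte,)], "abnormalCellMorphology.tsv"
        ),
        "abnormallyIncreasedLevelOfChemical": table(
            ("chemical",), [(glucose,), (calcium,), (METABOLITE,)],
            "abnormallyIncreasedLevelOfChemical.tsv",
        ),
        "fusedAnatomicalEntities": table(
            ("anatomical_entity", "fused_to"),
            [(AORTIC_VALVE_LEAFLET, AORTIC_VALVE), (tail, bone)],
            "fusedAnatomicalEntities.tsv",
        ),
    }
    return tables


def make_minter() -> IdMinter:
    """Minter pinning the canonical grouping-class ids for the worked examples."""
    overrides = {
        IdMinter.key(
            PATTERN_BASE + "increasedSizeOfAnatomicalEntity.yaml",
            {"anatomical_entity": HEART},
        ): UPHENO_INCREASED_HEART_SIZE,
        IdMinter.key(
            PATTERN_BASE + "abnormalSizeOfAnatomicalEntity.yaml",
            {"anatomical_entity": HEART},
        ): UPHENO_SIZE_OF_HEART,
        IdMinter.key(
            PATTERN_BASE + "abnormalAnatomicalEntityMorphology.yaml",
            {"anatomical_entity": HEART},
        ): UPHENO_HEART_MORPHOLOGY,
        IdMinter.key(
            PATTERN_BASE + "increasedThicknessOfAnatomicalEntity.yaml",
            {"anatomical_entity": AORTIC_VALVE_LEAFLET},
        ): UPHENO_INCREASED_LEAFLET_THICKNESS,
    }
    return IdMinter(prefix="EX", base=5_000_000, span=1_000_000, pad=7, overrides=overrides)


# ---------------------------------------------------------------------------
# Species ontologies
# ---------------------------------------------------------------------------


@dataclass
class SpeciesOntology:
    name: str
    graph: OntologyGraph
    eqs: dict[Curie, EQDefinition | None]
    bridge: BridgeTable
    categories: dict[Curie, str] = field(default_factory=dict)

    @property
    def labels(self) -> dict[Curie, str]:
        return self.graph.label_map()

    def lexical_entries(self) -> dict[Curie, tuple[str, tuple[str, ...]]]:
        return {
            c: (t.label, tuple(s for s, _ in t.synonyms))
            for c, t in self.graph.terms.items()
        }


def _species_label(style: str, base: str) -> str:
    if style == "human":
        return base[:1].upper() + base[1:]
    if style == "fish":
        return f"{base}, abnormal"
    return base


def make_species_fixture(
    seed: int = 42,
    sizes: int = 10,
    conformant_fraction: float = 0.6,
    eq_fraction: float = 0.3,
    include_examples: bool = True,
) -> dict[str, SpeciesOntology]:
    """Three species phenotype ontologies (human-, mouse- and fish-like).

    Each carries the cross-species worked examples (the enlarged-heart trio
    sharing one increased-size-of-heart EQ, and the forelimb-zeugopod /
    forearm pair defined on the same anatomy id) plus ``sizes`` randomized
    terms hitting the requested conformance-category fractions exactly.
    Fish bearers use fish-local anatomy ids, bridged to the neutral anatomy.
    """
    if conformant_fraction < 0 or eq_fraction < 0 or conformant_fraction + eq_fraction > 1:
        raise ValidationError(
            f"infeasible category fractions: {conformant_fraction}+{eq_fraction} > 1"
        )
    refs = make_reference_fixture(seed)
    anatomy = refs.entity_graphs["anatomy"]

    increased_heart_eq = EQDefinition(
        quality=INCREASED_SIZE,
        bearer=EntityExpression(HEART),
        bearer_mode="characteristic_of",
        modifier=ABNORMAL,
    )
    fish_increased_heart_eq = EQDefinition(
        quality=INCREASED_SIZE,
        bearer=EntityExpression(FISH_HEART),
        bearer_mode="characteristic_of",
        modifier=ABNORMAL,
    )
    zeugopod_eq = EQDefinition(
        quality=MORPHOLOGY,
        bearer=EntityExpression(FORELIMB_ZEUGOPOD),
        bearer_mode="characteristic_of_part_of",
        modifier=ABNORMAL,
    )

    # Random-term raw material: (quality, style template) pairs mirroring the
    # library for the conformant category, plus library-free qualities for
    # the EQ-not-conformant category.
    conformant_recipes = [
        (INCREASED_SIZE, "characteristic_of", "increased size of the {}"),
        (DECREASED_SIZE, "characteristic_of", "decreased size of the {}"),
        (SIZE, "characteristic_of_part_of", "size of {} phenotype"),
        (MORPHOLOGY, "characteristic_of_part_of", "{} morphology phenotype"),
        (THICKNESS, "characteristic_of_part_of", "thickness of {} phenotype"),
        (INCREASED_THICKNESS, "characteristic_of", "increased thickness of the {}"),
    ]
    anat_fillers = sorted(
        (c for c in anatomy.terms if c not in (ANATOMICAL_ENTITY,)), key=str
    )

    species_specs = [
        ("human", "HP-like", 1),
        ("mouse", "MP-like", 2),
        ("fish", "ZP-like", 3),
    ]
    out: dict[str, SpeciesOntology] = {}
    for style, ontology_id, offset in species_specs:
        rng = random.Random(seed * 10 + offset)
        graph = OntologyGraph(ontology_id, f"fixture-{seed}")
        eqs: dict[Curie, EQDefinition | None] = {}
        categories: dict[Curie, str] = {}
        bridge_pairs: list[tuple[Curie, Curie]] = []

        if include_examples:
            if style == "human":
                graph.add_term(OntologyTerm(HP_CARDIOMEGALY, "Cardiomegaly",
                                            synonyms=(("Enlarged heart", "EXACT"),)))
                eqs[HP_CARDIOMEGALY] = increased_heart_eq
                categories[HP_CARDIOMEGALY] = CONFORMANT
                graph.add_term(OntologyTerm(HP_ABNORMAL_FOREARM, "Abnormal forearm morphology"))
                eqs[HP_ABNORMAL_FOREARM] = zeugopod_eq
                categories[HP_ABNORMAL_FOREARM] = CONFORMANT
            elif style == "mouse":
                graph.add_term(OntologyTerm(MP_ENLARGED_HEART, "enlarged heart"))
                eqs[MP_ENLARGED_HEART] = increased_heart_eq
                categories[MP_ENLARGED_HEART] = CONFORMANT
                graph.add_term(OntologyTerm(MP_ABNORMAL_ZEUGOPOD, "abnormal forelimb zeugopod morphology"))
                eqs[MP_ABNORMAL_ZEUGOPOD] = zeugopod_eq
                categories[MP_ABNORMAL_ZEUGOPOD] = CONFORMANT
            else:
                graph.add_term(OntologyTerm(ZP_HEART_INCREASED_SIZE, "heart increased size, abnormal"))
                eqs[ZP_HEART_INCREASED_SIZE] = fish_increased_heart_eq
                categories[ZP_HEART_INCREASED_SIZE] = CONFORMANT

        if style == "fish":
            bridge_pairs = [
                (FISH_HEART, HEART),
                (FISH_FIN_RADIAL, FORELIMB_ZEUGOPOD),
                (FISH_EYE, Curie("EX", "A0000006")),
            ]

        n_conf = round(sizes * conformant_fraction)
        n_eq = round(sizes * eq_fraction)
        n_no = sizes - n_conf - n_eq
        if n_no < 0:
            raise ValidationError("rounded category counts exceed requested size")

        counter = 0

        def mint_species_id() -> Curie:
            nonlocal counter
            counter += 1
            return Curie("EX", f"S{offset}{counter:06d}")

        for _ in range(n_conf):
            quality, mode, label_tpl = rng.choice(conformant_recipes)
            filler = rng.choice(anat_fillers)
            term_id = mint_species_id()
            base = label_tpl.format(anatomy.label(filler))
            graph.add_term(OntologyTerm(term_id, _species_label(style, base)))
            eqs[term_id] = EQDefinition(
                quality=quality,
                bearer=EntityExpression(filler),
                bearer_mode=mode,
                modifier=ABNORMAL,
            )
            categories[term_id] = CONFORMANT
        for _ in range(n_eq):
            filler = rng.choice(anat_fillers)
            term_id = mint_species_id()
            base = f"fragility of {anatomy.label(filler)}"
            graph.add_term(OntologyTerm(term_id, _species_label(style, base)))
            # fragility is not used by any library pattern: EQ but not conformant
            eqs[term_id] = EQDefinition(
                quality=FRAGILITY,
                bearer=EntityExpression(filler),
                bearer_mode="characteristic_of",
                modifier=ABNORMAL,
            )
            categories[term_id] = EQ_NOT_CONFORMANT
        for _ in range(n_no):
            term_id = mint_species_id()
            graph.add_term(
                OntologyTerm(term_id, _species_label(style, f"uncharacterized phenotype {counter}"))
            )
            eqs[term_id] = None
            categories[term_id] = NO_EQ

        out[style] = SpeciesOntology(
            name=style,
            graph=graph,
            eqs=eqs,
            bridge=BridgeTable.from_pairs(bridge_pairs),
            categories=categories,
        )
    return out


# ---------------------------------------------------------------------------
# Annotation corpus
# ---------------------------------------------------------------------------


def make_corpus(
    seed: int,
    n_genes: int,
    zipf_exponent: float,
    hierarchy,
    annotations_per_gene: int = 2,
    ensure_coverage: bool = True,
) -> AnnotationCorpus:
    """Genes annotated to hierarchy leaves with Zipf-distributed popularity.

    Leaf ranks follow sorted id order; leaf ``r`` (1-based) has sampling
    weight ``1 / r**zipf_exponent``.  With ``ensure_coverage`` every leaf
    receives at least one annotation afterwards (deterministically), so IC
    is defined everywhere without fallback.
    """
    if n_genes <= 0:
        raise ValidationError("n_genes must be positive")
    leaves = sorted(
        (n for n in hierarchy.nodes if not hierarchy.children(n) and n != hierarchy.root),
        key=str,
    )
    if not leaves:
        raise ValidationError("hierarchy has no leaves to annotate")
    weights = [1.0 / (rank ** zipf_exponent) for rank in range(1, len(leaves) + 1)]
    rng = random.Random(seed)
    associations: list[tuple[Curie, Curie]] = []
    genes = [Curie("EX", f"G{i:05d}") for i in range(1, n_genes + 1)]
    for gene in genes:
        for _ in range(annotations_per_gene):
            associations.append((gene, rng.choices(leaves, weights=weights, k=1)[0]))
    if ensure_coverage:
        annotated = {p for _, p in associations}
        for i, leaf in enumerate(l for l in leaves if l not in annotated):
            associations.append((genes[i % len(genes)], leaf))
    return AnnotationCorpus(associations=associations)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    seed: int
    refs: References
    templates: list[PatternTemplate]
    filler_tables: dict[str, FillerTable]
    species: dict[str, SpeciesOntology]
    minter: IdMinter
    asserted: list[tuple[Curie, Curie, str]]  # (child, parent, comment)

    def asserted_edges(self) -> list[tuple[Curie, Curie]]:
        return [(c, p) for c, p, _ in self.asserted]

    def asserted_tsv(self) -> str:
        lines = ["child_id\tparent_id\tcomment"]
        for c, p, comment in self.asserted:
            lines.append(f"{c}\t{p}\t{comment}")
        return "\n".join(lines) + "\n"


def make_bundle(seed: int = 42, sizes: int = 10,
                conformant_fraction: float = 0.6, eq_fraction: float = 0.3) -> FixtureBundle:
    """Everything the pipeline consumes, generated deterministically."""
    refs = make_reference_fixture(seed)
    species = make_species_fixture(
        seed, sizes=sizes, conformant_fraction=conformant_fraction, eq_fraction=eq_fraction
    )
    asserted = [
        (
            TASTE_OLFACTION,
            PHENOTYPE_ROOT,
            "grouping class too complex for a simple EQ definition; manually classified",
        )
    ]
    return FixtureBundle(
        seed=seed,
        refs=refs,
        templates=make_template_library(),
        filler_tables=make_filler_tables(),
        species=species,
        minter=make_minter(),
        asserted=asserted,
    )
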