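"""Structural subsumption vs semantic oracle; hierarchy construction;
conformance categorization."""

import itertools
import random

import pytest

from phenokit.eq_model import EntityExpression, EQDefinition
from phenokit.eq_reasoner import (
    CONFORMANT,
    EQ_NOT_CONFORMANT,
    NO_EQ,
    SubsumptionIndex,
    classify,
    conformance_report,
    eq_subsumes,
    query_descendants,
)
from phenokit.errors import ValidationError
from phenokit.fixtures import (
    ABNORMAL,
    AORTIC_VALVE_LEAFLET,
    HEART,
    INCREASED_THICKNESS,
    MORPHOLOGY,
    make_reference_fixture,
    make_species_fixture,
    make_template_library,
)
from phenokit.ontology_io import IS_A, PART_OF, Curie, OntologyGraph, OntologyTerm
from phenokit.references import References
from phenokit.xspecies_mapper import apply_bridges

from .oracles import EqTuple, semantic_subsumes, transitive_reduction_oracle

CO, COPO = "characteristic_of", "characteristic_of_part_of"
_MODE = {CO: "co", COPO: "copo"}


def _eq_tuple(eq: EQDefinition) -> EqTuple:
    return EqTuple(
        quality=str(eq.quality),
        entity=str(eq.bearer.entity),
        mode=_MODE[eq.bearer_mode],
        modifier=str(eq.modifier),
        occurs_in=None if eq.bearer.occurs_in is None else str(eq.bearer.occurs_in),
        towards=None if eq.bearer.towards is None else str(eq.bearer.towards),
        role=None if eq.bearer.role is None else str(eq.bearer.role),
    )


def _graphs_to_dicts(quality: OntologyGraph, entity: OntologyGraph):
    q_isa, e_isa, e_po = {}, {}, {}
    for e in quality.edges:
        if e.predicate == IS_A:
            q_isa.setdefault(str(e.subject), set()).add(str(e.object))
    for e in entity.edges:
        target = e_isa if e.predicate == IS_A else e_po
        target.setdefault(str(e.subject), set()).add(str(e.object))
    return q_isa, e_isa, e_po


def _toy_universe():
    """5 qualities x 6 entities, with part_of chains and an abnormal node."""
    quality = OntologyGraph("toy-quality")
    for local, label, parent in [
        ("Q1", "quality", None),
        ("Q2", "morphology", "Q1"),
        ("Q3", "size", "Q2"),
        ("Q4", "increased size", "Q3"),
        ("Q5", "thickness", "Q2"),
        ("AB", "abnormal", None),
    ]:
        quality.add_term(OntologyTerm(Curie("T", local), label))
        if parent:
            quality.add_edge(Curie("T", local), IS_A, Curie("T", parent))
    entity = OntologyGraph("toy-entity")
    for local, label, isa, po in [
        ("E1", "anatomical entity", None, None),
        ("E2", "heart", "E1", None),
        ("E3", "aortic valve", "E1", "E2"),
        ("E4", "leaflet", "E1", "E3"),
        ("E5", "kidney", "E1", None),
        ("E6", "ventricle", "E1", "E2"),
    ]:
        entity.add_term(OntologyTerm(Curie("T", local), label))
        if isa:
            entity.add_edge(Curie("T", local), IS_A, Curie("T", isa))
        if po:
            entity.add_edge(Curie("T", local), PART_OF, Curie("T", po))
    refs = References(quality=quality, entity_graphs={"e": entity})
    return refs, quality, entity


def _toy_eqs(quality: OntologyGraph, entity: OntologyGraph):
    qualities = sorted((c for c in quality.terms if c.local_id != "AB"), key=str)
    entities = sorted(entity.terms, key=str)
    abnormal = Curie("T", "AB")
    return [
        EQDefinition(quality=q, bearer=EntityExpression(e), bearer_mode=mode, modifier=abnormal)
        for q, e, mode in itertools.product(qualities, entities, (CO, COPO))
    ]


@pytest.fixture(scope="module")
def frefs():
    return make_reference_fixture(42)


@pytest.fixture(scope="module")
def fidx(frefs):
    return SubsumptionIndex(frefs)


class TestEqSubsumes:
    def test_worked_inference_leaflet_thickness_under_heart_morphology(self, fidx):
        """Increased leaflet thickness falls under heart morphology because
        thickness ⊑ morphology and the leaflet is (transitively) part of the
        heart."""
        sub = EQDefinition(
            quality=INCREASED_THICKNESS,
            bearer=EntityExpression(AORTIC_VALVE_LEAFLET),
            bearer_mode=CO,
            modifier=ABNORMAL,
        )
        sup = EQDefinition(
            quality=MORPHOLOGY,
            bearer=EntityExpression(HEART),
            bearer_mode=COPO,
            modifier=ABNORMAL,
        )
        assert eq_subsumes(sub, sup, fidx)
        assert not eq_subsumes(sup, sub, fidx)

    def test_reflexive_on_fixture_eqs(self, pipeline, fidx):
        for eq in pipeline.generated.eqs.values():
            assert eq_subsumes(eq, eq, fidx)

    def test_plain_mode_superclass_does_not_absorb_part_of_subclass(self, fidx):
        sub = EQDefinition(
            quality=MORPHOLOGY, bearer=EntityExpression(HEART), bearer_mode=COPO
        )
        sup = EQDefinition(
            quality=MORPHOLOGY, bearer=EntityExpression(HEART), bearer_mode=CO
        )
        assert eq_subsumes(sup, sub, fidx)  # co is a special case of copo
        assert not eq_subsumes(sub, sup, fidx)

    def test_agrees_with_model_enumeration_on_toy_universe(self):
        refs, quality, entity = _toy_universe()
        idx = SubsumptionIndex(refs)
        q_isa, e_isa, e_po = _graphs_to_dicts(quality, entity)
        eqs = _toy_eqs(quality, entity)
        assert len(eqs) == 5 * 6 * 2
        for sub in eqs:
            for sup in eqs:
                structural = eq_subsumes(sub, sup, idx)
                semantic = semantic_subsumes(
                    _eq_tuple(sub), _eq_tuple(sup), q_isa, e_isa, e_po
                )
                assert structural == semantic, (sub, sup)

    def test_transitive_on_random_triples(self):
        refs, quality, entity = _toy_universe()
        idx = SubsumptionIndex(refs)
        eqs = _toy_eqs(quality, entity)
        rng = random.Random(17)
        for _ in range(2000):
            a, b, c = (rng.choice(eqs) for _ in range(3))
            if eq_subsumes(a, b, idx) and eq_subsumes(b, c, idx):
                assert eq_subsumes(a, c, idx)

    def test_monotone_under_reference_edge_addition(self):
        refs, quality, entity = _toy_universe()
        idx = SubsumptionIndex(refs)
        eqs = _toy_eqs(quality, entity)
        held = [(a, b) for a in eqs for b in eqs if eq_subsumes(a, b, idx)]
        entity.add_edge(Curie("T", "E5"), PART_OF, Curie("T", "E2"))  # kidney part_of heart
        refs.invalidate()
        idx2 = SubsumptionIndex(refs)
        for a, b in held:
            assert eq_subsumes(a, b, idx2)


def _random_instance(seed: int):
    """A random reference universe plus 30 random EQ definitions."""
    rng = random.Random(seed)
    quality = OntologyGraph("rq")
    n_q = 8
    for i in range(n_q):
        quality.add_term(OntologyTerm(Curie("Q", str(i)), f"q{i}"))
        if i:
            quality.add_edge(Curie("Q", str(i)), IS_A, Curie("Q", str(rng.randrange(i))))
    quality.add_term(OntologyTerm(Curie("Q", "AB"), "abnormal"))
    quality.add_term(OntologyTerm(Curie("Q", "ABX"), "severely abnormal"))
    quality.add_edge(Curie("Q", "ABX"), IS_A, Curie("Q", "AB"))
    entity = OntologyGraph("re")
    n_e = 10
    for i in range(n_e):
        entity.add_term(OntologyTerm(Curie("E", str(i)), f"e{i}"))
        if i:
            entity.add_edge(Curie("E", str(i)), IS_A, Curie("E", str(rng.randrange(i))))
            if rng.random() < 0.4:
                entity.add_edge(Curie("E", str(i)), PART_OF, Curie("E", str(rng.randrange(i))))
    refs = References(quality=quality, entity_graphs={"e": entity})
    qualities = [Curie("Q", str(i)) for i in range(n_q)]
    entities = [Curie("E", str(i)) for i in range(n_e)]
    modifiers = [Curie("Q", "AB"), Curie("Q", "ABX")]
    eqs = []
    for _ in range(30):
        eqs.append(
            EQDefinition(
                quality=rng.choice(qualities),
                bearer=EntityExpression(
                    rng.choice(entities),
                    occurs_in=rng.choice(entities) if rng.random() < 0.25 else None,
                    towards=rng.choice(entities) if rng.random() < 0.25 else None,
                    role=rng.choice(entities) if rng.random() < 0.15 else None,
                ),
                bearer_mode=rng.choice([CO, COPO]),
                modifier=rng.choice(modifiers),
            )
        )
    return refs, quality, entity, eqs


class TestRandomInstanceOracle:
    @pytest.mark.parametrize("batch", range(10))
    def test_agrees_with_semantic_oracle(self, batch):
        """100 random 30-term universes, split in 10 batches: no divergence
        between the structural decision and the canonical-model oracle."""
        for k in range(10):
            seed = 1000 + batch * 10 + k
            refs, quality, entity, eqs = _random_instance(seed)
            idx = SubsumptionIndex(refs)
            q_isa, e_isa, e_po = _graphs_to_dicts(quality, entity)
            for sub in eqs:
                for sup in eqs:
                    assert eq_subsumes(sub, sup, idx) == semantic_subsumes(
                        _eq_tuple(sub), _eq_tuple(sup), q_isa, e_isa, e_po
                    ), (seed, sub, sup)


class TestClassify:
    def test_single_term_sits_under_root(self, fidx):
        eq = EQDefinition(quality=MORPHOLOGY, bearer=EntityExpression(HEART))
        h = classify({Curie.parse("EX:X1"): eq}, fidx)
        assert h.parents("EX:X1") == [h.root]

    def test_eqless_term_flagged_as_orphan(self, fidx):
        h = classify({Curie.parse("EX:X1"): None}, fidx)
        assert h.orphans == [Curie.parse("EX:X1")]
        assert h.parents("EX:X1") == [h.root]

    def test_heart_trio_groups_under_neutral_term(self, pipeline):
        """Species terms sharing the increased-size-of-heart definition sit
        under the species-neutral grouping class, which descends from the
        size-of-heart grouping."""
        h = pipeline.hierarchy
        neutral = Curie.parse("UPHENO:0001471")
        assert set(h.children(neutral)) == {
            Curie.parse("HP:0001640"),
            Curie.parse("MP:0000274"),
            Curie.parse("ZP:0000532"),
        }
        assert Curie.parse("UPHENO:0075162") in h.ancestors(neutral, reflexive=False)

    def test_direct_parents_equal_reachability_reduction_oracle(self):
        """Inferred direct-parent edges equal Floyd-Warshall reachability
        followed by independent transitive reduction (distinct EQs only)."""
        refs, quality, entity, eqs = _random_instance(4242)
        idx = SubsumptionIndex(refs)
        distinct = []
        for eq in eqs:
            if eq not in distinct:
                distinct.append(eq)
        terms = {Curie("X", str(i)): eq for i, eq in enumerate(distinct)}
        # drop mutually-subsuming distinct definitions: keep a canonical one
        ids = sorted(terms, key=str)
        keep = []
        for i, a in enumerate(ids):
            if not any(
                eq_subsumes(terms[a], terms[b], idx) and eq_subsumes(terms[b], terms[a], idx)
                for b in keep
            ):
                keep.append(a)
        terms = {c: terms[c] for c in keep}
        h = classify(terms, idx)
        raw_edges = [
            (a, b)
            for a in terms
            for b in terms
            if a != b and eq_subsumes(terms[a], terms[b], idx)
        ]
        expected = transitive_reduction_oracle(sorted(terms, key=str), raw_edges)
        actual = {
            (c, p) for c, p, prov in h.edges if prov == "inferred" and p != h.root
        }
        assert actual == expected

    def test_asserted_edges_carry_provenance(self, fidx):
        h = classify(
            {Curie.parse("EX:X1"): None},
            fidx,
            asserted=[("EX:X1", "EX:X2")],
        )
        assert (Curie.parse("EX:X1"), Curie.parse("EX:X2"), "asserted") in h.edges
        assert h.orphans == []

    def test_cyclic_asserted_edges_rejected(self, fidx):
        with pytest.raises(ValidationError, match="cycle"):
            classify(
                {},
                fidx,
                asserted=[("EX:X1", "EX:X2"), ("EX:X2", "EX:X1")],
            )


class TestQueryDescendants:
    def test_heart_morphology_covers_heart_size_terms(self, pipeline):
        h = pipeline.hierarchy
        descendants = query_descendants(h, "UPHENO:0076810")
        for term in ("UPHENO:0001471", "UPHENO:0075162", "HP:0001640", "UPHENO:0047922"):
            assert Curie.parse(term) in descendants

    def test_leaf_has_no_descendants(self, pipeline):
        assert query_descendants(pipeline.hierarchy, "ZP:0000532") == set()

    def test_class_expression_query_equals_exhaustive_filter(self, pipeline):
        h, idx = pipeline.hierarchy, pipeline.idx
        query = EQDefinition(
            quality=MORPHOLOGY, bearer=EntityExpression(HEART), bearer_mode=COPO
        )
        result = query_descendants(h, query, idx)
        expected = {c for c, eq in h.eqs.items() if eq_subsumes(eq, query, idx)}
        assert result == expected
        assert Curie.parse("UPHENO:0047922") in result


class TestConformance:
    def test_constructed_split_reported_exactly(self, frefs):
        library = make_template_library()
        species = make_species_fixture(
            seed=42, sizes=10, conformant_fraction=0.6, eq_fraction=0.3,
            include_examples=False,
        )
        for name, ontology in species.items():
            bridged = {
                c: (None if eq is None else apply_bridges(eq, ontology.bridge))
                for c, eq in ontology.eqs.items()
            }
            report = conformance_report(bridged, library, frefs)
            assert report.counts == {CONFORMANT: 6, EQ_NOT_CONFORMANT: 3, NO_EQ: 1}
            assert report.fractions == {CONFORMANT: 0.6, EQ_NOT_CONFORMANT: 0.3, NO_EQ: 0.1}

    def test_no_logical_definitions_is_all_no_eq(self, frefs):
        library = make_template_library()
        eqs = {Curie("EX", f"N{i}"): None for i in range(5)}
        report = conformance_report(eqs, library, frefs)
        assert report.counts[NO_EQ] == 5
        assert report.fractions[NO_EQ] == 1.0

    def test_categories_match_bruteforce_template_matching(self, frefs, pipeline):
        """Category assignment equals exhaustive (term, template) shape
        matching over the filler cross-product."""
        from .oracles import bruteforce_conformant

        library = make_template_library()
        species = pipeline.bundle.species
        for name, ontology in species.items():
            bridged = {
                c: (None if eq is None else apply_bridges(eq, ontology.bridge))
                for c, eq in ontology.eqs.items()
            }
            report = conformance_report(bridged, library, frefs)
            for term_id, eq in bridged.items():
                if eq is None:
                    assert report.categories[term_id] == NO_EQ
                else:
                    expected = (
                        CONFORMANT
                        if bruteforce_conformant(eq, library, frefs)
                        else EQ_NOT_CONFORMANT
                    )
                    assert report.categories[term_id] == expected
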