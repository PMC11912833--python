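"""Template loading, filler binding, and term instantiation."""

import itertools
import random

import pytest

from phenokit.errors import ValidationError
from phenokit.fixtures import (
    ABNORMAL,
    HEART,
    INCREASED_SIZE,
    PATTERN_BASE,
    QUALITY_ROOT,
    make_filler_tables,
    make_minter,
    make_reference_fixture,
    make_template_library,
)
from phenokit.ontology_io import IS_A, Curie
from phenokit.pattern_engine import (
    FillerTable,
    IdMinter,
    bind,
    dump_template,
    instantiate,
    instantiate_all,
    load_template,
)


@pytest.fixture(scope="module")
def frefs():
    return make_reference_fixture(42)


@pytest.fixture(scope="module")
def library():
    return make_template_library()


@pytest.fixture(scope="module")
def tables():
    return make_filler_tables()


def by_name(library, name):
    return next(t for t in library if t.pattern_id == PATTERN_BASE + name + ".yaml")


ABNORMAL_ANATOMICAL_ENTITY_YAML = """\
pattern_iri: https://example.org/patterns/abnormalAnatomicalEntity.yaml
description: Any abnormality of an anatomical entity.
contributors:
  - https://orcid.org/0000-0000-0000-0001
classes:
  quality: EX:Q0000001
  abnormal: PATO:0000460
  anatomical entity: UBERON:0001062
relations:
  has part: BFO:0000051
  characteristic of part of: RO:0002314
  has modifier: RO:0002573
vars:
  anatomical_entity: "'anatomical entity'"
name:
  text: abnormal %s
  vars: [anatomical_entity]
def:
  text: Any abnormality of %s.
  vars: [anatomical_entity]
equivalentTo:
  text: "'has part' some (quality and 'characteristic of part of' some %s and 'has modifier' some abnormal)"
  vars: [anatomical_entity]
"""


class TestLoadTemplate:
    def test_abnormal_anatomical_entity_pattern(self):
        template = load_template(ABNORMAL_ANATOMICAL_ENTITY_YAML)
        assert template.vars == {"anatomical_entity": Curie.parse("UBERON:0001062")}
        assert template.contributors == ("https://orcid.org/0000-0000-0000-0001",)
        assert template.name_template.text == "abnormal %s"

    def test_undeclared_slot_rejected(self):
        bad = ABNORMAL_ANATOMICAL_ENTITY_YAML.replace(
            "vars: [anatomical_entity]", "vars: [mystery_var]", 1
        )
        with pytest.raises(ValidationError, match="mystery_var"):
            load_template(bad)

    def test_var_range_must_resolve(self):
        bad = ABNORMAL_ANATOMICAL_ENTITY_YAML.replace(
            'anatomical_entity: "\'anatomical entity\'"',
            'anatomical_entity: "\'no such class\'"',
        )
        with pytest.raises(ValidationError, match="no such class"):
            load_template(bad)

    def test_library_loads_and_is_a_dump_fixed_point(self, library):
        assert len(library) == 15
        for template in library:
            dumped = dump_template(template)
            assert load_template(dumped) == template
            assert load_template(dump_template(load_template(dumped))) == template


class TestBind:
    def test_in_range_filler_accepted(self, library, frefs):
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        table = FillerTable(rows=[{"anatomical_entity": HEART}], columns=("anatomical_entity",))
        result = bind(template, table, frefs)
        assert result.accepted == [{"anatomical_entity": HEART}]
        assert result.rejected == []

    def test_quality_filler_rejected_with_range_reason(self, library, frefs):
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        table = FillerTable(
            rows=[{"anatomical_entity": INCREASED_SIZE}], columns=("anatomical_entity",)
        )
        result = bind(template, table, frefs)
        assert result.accepted == []
        assert "range" in result.rejected[0][1]

    def test_header_mismatch_is_table_level_error(self, library, frefs):
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        table = FillerTable(rows=[], columns=("wrong_column",))
        with pytest.raises(ValidationError, match="columns"):
            bind(template, table, frefs)

    def test_acceptance_matches_bruteforce_closure_on_random_rows(self, library, frefs):
        """Row acceptance equals direct reflexive-is_a closure membership."""
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        rng = random.Random(5)
        all_ids = sorted(
            itertools.chain.from_iterable(g.terms for g in frefs.all_graphs()), key=str
        )
        rows = [{"anatomical_entity": rng.choice(all_ids)} for _ in range(100)]
        # duplicates allowed for this check
        table = FillerTable.__new__(FillerTable)
        table.rows, table.columns, table.source = rows, ("anatomical_entity",), "random"
        result = bind(template, table, frefs)
        accepted = {str(r["anatomical_entity"]) for r in result.accepted}
        for row in rows:
            filler = row["anatomical_entity"]
            graph = next((g for g in frefs.all_graphs() if filler in g), None)
            expected = (
                graph is not None
                and template.vars["anatomical_entity"] in graph.closure(filler, [IS_A])
            )
            assert (str(filler) in accepted) == expected


class TestInstantiate:
    def test_increased_size_of_heart(self, library, frefs):
        """The flagship worked example: filler heart into the increased-size
        pattern yields the canonical label and EQ."""
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        term = instantiate(template, {"anatomical_entity": HEART}, frefs, make_minter())
        assert term.label == "increased size of the heart"
        assert term.eq.quality == INCREASED_SIZE
        assert term.eq.bearer.entity == HEART
        assert term.eq.modifier == ABNORMAL
        assert term.id == Curie.parse("UPHENO:0001471")

    def test_abnormal_anatomical_entity_uses_quality_root(self, library, frefs):
        template = by_name(library, "abnormalAnatomicalEntity")
        term = instantiate(template, {"anatomical_entity": HEART}, frefs, make_minter())
        assert term.label == "abnormal heart"
        assert term.eq.quality == QUALITY_ROOT
        assert term.eq.modifier == ABNORMAL

    def test_instantiation_is_deterministic(self, library, frefs):
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        a = instantiate(template, {"anatomical_entity": HEART}, frefs, make_minter())
        b = instantiate(template, {"anatomical_entity": HEART}, frefs, make_minter())
        assert a == b

    def test_provenance_carried(self, library, frefs):
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        term = instantiate(template, {"anatomical_entity": HEART}, frefs, make_minter())
        assert term.pattern_id == template.pattern_id
        assert term.contributors == template.contributors
        assert dict(term.binding) == {"anatomical_entity": str(HEART)}


class TestInstantiateAll:
    def test_empty_table_empty_fragment(self, library, frefs):
        template = by_name(library, "increasedSizeOfAnatomicalEntity")
        table = FillerTable(rows=[], columns=("anatomical_entity",))
        result = instantiate_all(template, table, frefs, make_minter())
        assert result.terms == []
        assert len(result.fragment()) == 0

    def test_twelve_fillers_give_twelve_distinct_ids(self, library, frefs):
        template = by_name(library, "decreasedSizeOfAnatomicalEntity")
        anatomy = frefs.entity_graphs["anatomy"]
        fillers = sorted(
            (c for c in anatomy.terms if c != Curie.parse("UBERON:0001062")), key=str
        )[:12]
        table = FillerTable(
            rows=[{"anatomical_entity": f} for f in fillers], columns=("anatomical_entity",)
        )
        result = instantiate_all(template, table, frefs, make_minter())
        assert len(result.terms) == 12
        assert len({t.id for t in result.terms}) == 12

    def test_labels_equal_independent_substitution_oracle(self, library, frefs, tables):
        """Generated labels match a hand-written string substitution."""
        for name in ("increasedSizeOfAnatomicalEntity", "abnormalAnatomicalEntityMorphology"):
            template = by_name(library, name)
            result = instantiate_all(template, tables[name], frefs, make_minter())
            for term, row in zip(result.terms, tables[name].rows):
                filler_label = frefs.label(row["anatomical_entity"])
                expected = template.name_template.text.replace("%s", filler_label)
                assert term.label == expected

    def test_eq_filler_matches_label_filler(self, library, frefs, tables):
        """The filler id in the EQ is the one whose label appears in the term
        label, for every generated term of the library."""
        minter = make_minter()
        for template in library:
            name = template.pattern_id.rsplit("/", 1)[-1].removesuffix(".yaml")
            result = instantiate_all(template, tables[name], frefs, minter)
            for term in result.terms:
                binding = dict(term.binding)
                first_var = template.name_template.vars[0]
                filler = Curie.parse(binding[first_var])
                assert frefs.label(filler) in term.label
                assert filler in term.eq.atoms()


class TestMinting:
    def test_injective_over_fixture_cross_product(self, library, frefs):
        """No id collisions over every (pattern, in-range anatomy filler)."""
        minter = make_minter()
        anatomy = frefs.entity_graphs["anatomy"]
        seen = {}
        for template in library:
            if list(template.vars.values()) != [Curie.parse("UBERON:0001062")]:
                continue
            for filler in sorted(anatomy.terms, key=str):
                curie = minter.mint(template.pattern_id, {"anatomical_entity": filler})
                key = (template.pattern_id, str(filler))
                assert curie not in {v for k, v in seen.items() if k != key}
                seen[key] = curie

    def test_ledger_round_trip_preserves_assignments(self):
        minter = IdMinter(prefix="EX", base=100, span=50, pad=4)
        a = minter.mint("p1", {"x": Curie.parse("EX:1")})
        reloaded = IdMinter.from_ledger_json(
            minter.ledger_json(), prefix="EX", base=100, span=50, pad=4
        )
        assert reloaded.mint("p1", {"x": Curie.parse("EX:1")}) == a

    def test_probing_resolves_collisions(self):
        minter = IdMinter(prefix="EX", base=0, span=2, pad=2)
        ids = {str(minter.mint("p", {"x": Curie("EX", str(i))})) for i in range(2)}
        assert len(ids) == 2
        with pytest.raises(ValidationError, match="exhausted"):
            minter.mint("p", {"x": Curie("EX", "99")})
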