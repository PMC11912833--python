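"""Structural subsumption and hierarchy construction for EQ-defined terms.

For the EQ fragment used here, class subsumption can be decided structurally
from reference-ontology closures instead of running a general OWL reasoner:
``sub ⊑ sup`` iff the sub's quality, bearer, modifier and optional clauses
are each at least as specific as the sup's, where "specific" means ancestry
in the appropriate closure — is_a for qualities and modifiers, is_a+part_of
for bearers under ``characteristic_of_part_of`` (part-of mode in the
superclass subsumes plain mode in the subclass, not vice versa), and
is_a+part_of for ``occurs_in`` locations (occurs_in composes with part_of).

``classify`` turns a set of EQ-defined terms (plus optional manually
asserted child/parent edges) into a DAG of direct parents: the transitive
reduction of the inferred subsumption preorder, with mutually-subsuming
terms kept as distinct nodes grouped under a class representative and
reported as equivalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import UnknownTermError, ValidationError
from .eq_model import EQDefinition
from .ontology_io import IS_A, PART_OF, Curie, OntologyGraph, as_curie
from .pattern_engine import PatternTemplate
from .references import References

__all__ = [
    "SubsumptionIndex",
    "PhenotypeHierarchy",
    "eq_subsumes",
    "classify",
    "query_descendants",
    "conformance_report",
    "ConformanceReport",
    "CONFORMANT",
    "EQ_NOT_CONFORMANT",
    "NO_EQ",
]


class SubsumptionIndex:
    """Per-reference-graph closure caches backing ``eq_subsumes``.

    Quality and modifier ancestry use is_a only (within the quality graph);
    entity ancestry is cached both as is_a-only and is_a+part_of over the
    merged entity graph.
    """

    def __init__(self, refs: References):
        self.refs = refs
        self.entity_graph = refs.merged_entity_graph()
        self._quality_anc: dict[Curie, set[Curie]] = {}
        self._entity_anc_isa: dict[Curie, set[Curie]] = {}
        self._entity_anc_iapo: dict[Curie, set[Curie]] = {}

    def quality_ancestors(self, c: str | Curie) -> set[Curie]:
        c = as_curie(c)
        if c not in self._quality_anc:
            self._quality_anc[c] = self.refs.quality.closure(c, [IS_A], reflexive=True)
        return self._quality_anc[c]

    modifier_ancestors = quality_ancestors  # modifiers live in the quality graph

    def entity_ancestors(self, c: str | Curie, with_part_of: bool = True) -> set[Curie]:
        c = as_curie(c)
        cache = self._entity_anc_iapo if with_part_of else self._entity_anc_isa
        if c not in cache:
            preds = [IS_A, PART_OF] if with_part_of else [IS_A]
            cache[c] = self.entity_graph.closure(c, preds, reflexive=True)
        return cache[c]


def eq_subsumes(sub: EQDefinition, sup: EQDefinition, idx: SubsumptionIndex) -> bool:
    """True iff every instance of ``sub`` is an instance of ``sup``.

    The decision is purely structural:

    a. sup.quality is an is_a ancestor-or-self of sub.quality;
    b. bearer compatibility — under ``characteristic_of_part_of`` in the
       superclass, sup's bearer must be in the is_a+part_of ancestry of
       sub's bearer (either mode in the subclass qualifies); under plain
       ``characteristic_of`` the subclass must also use plain mode and the
       ancestry is is_a only.  When the superclass bearer itself carries an
       ``occurs_in`` or ``role`` clause, the bearer-entity ancestry is
       restricted to is_a even under part-of mode: the located (or
       role-bearing) witness is the bearer individual itself, and its
       whole-of ancestors do not inherit those clauses;
    c. sub.modifier equals or is an is_a descendant of sup.modifier;
    d. sup.towards absent, or sub.towards present and within is_a ancestry
       of sup.towards;
    e. sup.occurs_in absent, or sub.occurs_in present and within is_a+part_of
       ancestry of sup.occurs_in;
    f. sup.role absent, or sub.role present and within is_a ancestry of
       sup.role.
    """
    if sup.quality not in idx.quality_ancestors(sub.quality):
        return False
    if sup.bearer_mode == "characteristic_of_part_of":
        # A located/role-qualified bearer pins the check to the bearer itself.
        composite_sup = sup.bearer.occurs_in is not None or sup.bearer.role is not None
        if sup.bearer.entity not in idx.entity_ancestors(
            sub.bearer.entity, with_part_of=not composite_sup
        ):
            return False
    else:
        if sub.bearer_mode != "characteristic_of":
            return False
        if sup.bearer.entity not in idx.entity_ancestors(sub.bearer.entity, with_part_of=False):
            return False
    if sup.modifier not in idx.modifier_ancestors(sub.modifier):
        return False
    if sup.bearer.towards is not None:
        if sub.bearer.towards is None:
            return False
        if sup.bearer.towards not in idx.entity_ancestors(sub.bearer.towards, with_part_of=False):
            return False
    if sup.bearer.occurs_in is not None:
        if sub.bearer.occurs_in is None:
            return False
        if sup.bearer.occurs_in not in idx.entity_ancestors(sub.bearer.occurs_in, with_part_of=True):
            return False
    if sup.bearer.role is not None:
        if sub.bearer.role is None:
            return False
        if sup.bearer.role not in idx.entity_ancestors(sub.bearer.role, with_part_of=False):
            return False
    return True


# ---------------------------------------------------------------------------
# Hierarchy construction
# ---------------------------------------------------------------------------

INFERRED = "inferred"
ASSERTED = "asserted"


@dataclass
class PhenotypeHierarchy:
    """Direct-parent DAG over phenotype terms, rooted at a single node."""

    root: Curie
    nodes: set[Curie]
    edges: list[tuple[Curie, Curie, str]]  # (child, parent, provenance)
    eqs: dict[Curie, EQDefinition] = field(default_factory=dict)
    equivalence_classes: list[tuple[Curie, ...]] = field(default_factory=list)
    orphans: list[Curie] = field(default_factory=list)
    _nx: nx.DiGraph | None = field(default=None, repr=False, compare=False)

    def graph(self) -> nx.DiGraph:
        if self._nx is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            for child, parent, prov in self.edges:
                g.add_edge(child, parent, provenance=prov)
            self._nx = g
        return self._nx

    def parents(self, node: str | Curie) -> list[Curie]:
        node = self._check(node)
        return sorted(self.graph().successors(node))

    def children(self, node: str | Curie) -> list[Curie]:
        node = self._check(node)
        return sorted(self.graph().predecessors(node))

    def ancestors(self, node: str | Curie, reflexive: bool = True) -> set[Curie]:
        node = self._check(node)
        out = set(nx.descendants(self.graph(), node))  # edges point child->parent
        if reflexive:
            out.add(node)
        return out

    def descendants(self, node: str | Curie, reflexive: bool = False) -> set[Curie]:
        node = self._check(node)
        out = set(nx.ancestors(self.graph(), node))
        if reflexive:
            out.add(node)
        return out

    def _check(self, node: str | Curie) -> Curie:
        node = as_curie(node)
        if node not in self.nodes:
            raise UnknownTermError(f"unknown hierarchy node: {node}")
        return node

    def to_ontology_graph(self, labels: dict[Curie, str] | None = None) -> OntologyGraph:
        from .ontology_io import OntologyTerm

        g = OntologyGraph("phenotype-hierarchy")
        labels = labels or {}
        for node in sorted(self.nodes):
            g.add_term(OntologyTerm(id=node, label=labels.get(node, "")))
        for child, parent, prov in sorted(self.edges, key=lambda e: (str(e[0]), str(e[1]))):
            g.add_edge(child, IS_A, parent)
        return g


def classify(
    terms: dict[Curie, EQDefinition | None],
    idx: SubsumptionIndex,
    asserted: list[tuple[str | Curie, str | Curie]] | None = None,
    root: str | Curie = "EX:0000000",
    grouping_terms: set[Curie] | None = None,
) -> PhenotypeHierarchy:
    """Build the direct-parent hierarchy for a set of phenotype terms.

    ``terms`` maps each term id to its EQ definition (``None`` for terms
    without one; such terms need an asserted parent or are placed under the
    root and flagged).  ``asserted`` supplies manually curated (child,
    parent) edges that supplement inference.  ``grouping_terms`` marks the
    species-neutral ids: within a set of mutually subsuming terms the
    representative is the smallest grouping member when one exists (species
    terms then sit under their species-neutral grouping class), otherwise
    the lexicographically smallest id.
    """
    root = as_curie(root)
    asserted = [(as_curie(a), as_curie(b)) for a, b in (asserted or [])]
    grouping_terms = {as_curie(c) for c in (grouping_terms or set())}
    terms = {as_curie(k): v for k, v in terms.items()}

    with_eq = sorted(c for c, eq in terms.items() if eq is not None)
    # Raw subsumption relation among distinct terms.
    sub_graph = nx.DiGraph()
    sub_graph.add_nodes_from(with_eq)
    for a in with_eq:
        for b in with_eq:
            if a != b and eq_subsumes(terms[a], terms[b], idx):
                sub_graph.add_edge(a, b)  # a ⊑ b

    # Mutually subsuming terms form strongly connected components.
    representative: dict[Curie, Curie] = {}
    equivalence_classes: list[tuple[Curie, ...]] = []
    for comp in nx.strongly_connected_components(sub_graph):
        members = sorted(comp)
        grouped = sorted(m for m in members if m in grouping_terms)
        rep = grouped[0] if grouped else members[0]
        for m in members:
            representative[m] = rep
        if len(members) > 1:
            equivalence_classes.append(tuple(members))
    equivalence_classes.sort()

    # Strict subsumption DAG over representatives, then transitive reduction.
    reps = sorted(set(representative.values()))
    dag = nx.DiGraph()
    dag.add_nodes_from(reps)
    for a, b in sub_graph.edges:
        ra, rb = representative[a], representative[b]
        if ra != rb:
            dag.add_edge(ra, rb)
    if not nx.is_directed_acyclic_graph(dag):  # cannot happen post-SCC; defensive
        raise ValidationError(f"cyclic subsumption after equivalence collapse: {nx.find_cycle(dag)}")
    reduced = nx.transitive_reduction(dag)

    nodes: set[Curie] = set(terms) | {root}
    edges: list[tuple[Curie, Curie, str]] = []
    for a, b in sorted(reduced.edges, key=lambda e: (str(e[0]), str(e[1]))):
        edges.append((a, b, INFERRED))
    # Non-representative members hang directly under their representative.
    for members in equivalence_classes:
        rep = representative[members[0]]
        for m in members:
            if m != rep:
                edges.append((m, rep, INFERRED))
    asserted_children = set()
    for child, parent in asserted:
        nodes.add(child)
        nodes.add(parent)
        edges.append((child, parent, ASSERTED))
        asserted_children.add(child)

    # Attach parentless nodes to the root; flag EQ-less, assertion-less terms.
    orphans: list[Curie] = []
    have_parent = {c for c, _p, _ in edges}
    for node in sorted(nodes):
        if node == root or node in have_parent:
            continue
        edges.append((node, root, INFERRED))
        if node in terms and terms[node] is None and node not in asserted_children:
            orphans.append(node)

    hierarchy = PhenotypeHierarchy(
        root=root,
        nodes=nodes,
        edges=edges,
        eqs={c: eq for c, eq in terms.items() if eq is not None},
        equivalence_classes=equivalence_classes,
        orphans=orphans,
    )
    if not nx.is_directed_acyclic_graph(hierarchy.graph()):
        raise ValidationError(
            f"asserted edges introduce a cycle: {nx.find_cycle(hierarchy.graph())}"
        )
    return hierarchy


def query_descendants(
    hierarchy: PhenotypeHierarchy,
    query: str | Curie | EQDefinition,
    idx: SubsumptionIndex | None = None,
) -> set[Curie]:
    """Descendants of a named term, or — for an EQ class-expression query —
    all terms whose definition is subsumed by the expression."""
    if isinstance(query, EQDefinition):
        if idx is None:
            raise ValidationError("an index is required for class-expression queries")
        return {c for c, eq in hierarchy.eqs.items() if eq_subsumes(eq, query, idx)}
    return hierarchy.descendants(as_curie(query), reflexive=False)


# ---------------------------------------------------------------------------
# Conformance reporting
# ---------------------------------------------------------------------------

CONFORMANT = "upheno_conformant_eq"
EQ_NOT_CONFORMANT = "eq_not_upheno"
NO_EQ = "no_eq"


@dataclass
class ConformanceReport:
    categories: dict[Curie, str]
    counts: dict[str, int]
    fractions: dict[str, float]

    def to_tsv(self) -> str:
        lines = ["term_id\tcategory"]
        for c in sorted(self.categories):
            lines.append(f"{c}\t{self.categories[c]}")
        return "\n".join(lines) + "\n"


def template_shape(template: PatternTemplate, refs: References) -> EQDefinition | None:
    """Parse a template's equivalentTo with sentinel fillers, yielding an EQ
    whose var slots carry sentinel CURIEs ``__VAR__:<name>``."""
    from .eq_model import parse_manchester

    if template.equivalent_to_template is None:
        return None
    tt = template.equivalent_to_template
    sentinel_labels = {v: f"__var_{v}__" for v in tt.vars}
    label_to_id: dict[str, Curie] = dict(template.declared_classes)
    for v, lbl in sentinel_labels.items():
        label_to_id[lbl] = Curie("__VAR__", v)
    try:
        return parse_manchester(tt.fill(sentinel_labels), label_to_id)
    except Exception:
        return None


def _match_template(
    eq: EQDefinition,
    template: PatternTemplate,
    shape: EQDefinition | None,
    refs: References,
) -> bool:
    """Does ``eq`` instantiate the template's shape with in-range fillers?"""
    if shape is None:
        return False
    binding: dict[str, Curie] = {}

    def unify(pattern_val: Curie | None, value: Curie | None) -> bool:
        if pattern_val is None or value is None:
            return pattern_val is None and value is None
        if pattern_val.prefix == "__VAR__":
            var = pattern_val.local_id
            if var in binding:
                return binding[var] == value
            binding[var] = value
            return True
        return pattern_val == value

    if shape.bearer_mode != eq.bearer_mode:
        return False
    checks = [
        unify(shape.quality, eq.quality),
        unify(shape.bearer.entity, eq.bearer.entity),
        unify(shape.bearer.occurs_in, eq.bearer.occurs_in),
        unify(shape.bearer.towards, eq.bearer.towards),
        unify(shape.bearer.role, eq.bearer.role),
        unify(shape.modifier, eq.modifier),
    ]
    if not all(checks):
        return False
    # Range check each bound filler (is_a only, as in bind()).
    for var, filler in binding.items():
        rng = template.vars.get(var)
        if rng is None:
            return False
        if filler not in refs:
            return False
        graph = next(g for g in refs.all_graphs() if filler in g)
        if rng not in graph or rng not in graph.closure(filler, [IS_A], reflexive=True):
            return False
    return True


def conformance_report(
    species_eqs: dict[Curie, EQDefinition | None],
    templates: list[PatternTemplate],
    refs: References,
) -> ConformanceReport:
    """Label every term of a species ontology as pattern-conformant EQ,
    EQ-but-not-pattern-conformant, or lacking a logical definition, and
    report counts and fractions per category."""
    shapes = [(t, template_shape(t, refs)) for t in templates]
    categories: dict[Curie, str] = {}
    for term_id, eq in species_eqs.items():
        term_id = as_curie(term_id)
        if eq is None:
            categories[term_id] = NO_EQ
        elif any(_match_template(eq, t, shape, refs) for t, shape in shapes):
            categories[term_id] = CONFORMANT
        else:
            categories[term_id] = EQ_NOT_CONFORMANT
    counts = {cat: 0 for cat in (CONFORMANT, EQ_NOT_CONFORMANT, NO_EQ)}
    for cat in categories.values():
        counts[cat] += 1
    total = len(categories)
    fractions = {cat: (n / total if total else 0.0) for cat, n in counts.items()}
    return ConformanceReport(categories=categories, counts=counts, fractions=fractions)
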