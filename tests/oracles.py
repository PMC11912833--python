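"""Independent oracles used by the test-suite.

Everything here is deliberately written with naive, first-principles
algorithms (fixpoint loops, boolean matrices, exhaustive enumeration) and
avoids the package's own closure / reasoning code paths, so a test comparing
the implementation against an oracle is a genuine dual-route check.
"""

from __future__ import annotations

import itertools

import numpy as np


def stanza_count(obo_text: str) -> int:
    """Line-level count of [Term] stanza headers."""
    return sum(1 for line in obo_text.splitlines() if line.strip() == "[Term]")


def matrix_closure(n_nodes: int, edges: list[tuple[int, int]], reflexive: bool = True) -> np.ndarray:
    """Reachability by repeated squaring of the boolean adjacency matrix."""
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for a, b in edges:
        adj[a, b] = True
    reach = adj.copy()
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    if reflexive:
        reach |= np.eye(n_nodes, dtype=bool)
    return reach


def floyd_warshall_reachability(nodes: list, edges: list[tuple]) -> dict[tuple, bool]:
    """All-pairs reachability via the classic triple loop."""
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for a, b in edges:
        reach[index[a]][index[b]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                row_k = reach[k]
                row_i = reach[i]
                for j in range(n):
                    if row_k[j]:
                        row_i[j] = True
    return {(a, b): reach[index[a]][index[b]] for a in nodes for b in nodes}


def transitive_reduction_oracle(nodes: list, edges: list[tuple]) -> set[tuple]:
    """Minimal edge set of a DAG with the same reachability: keep (a, b) iff
    no intermediate c with a->*c and c->*b."""
    reach = floyd_warshall_reachability(nodes, edges)
    reduced = set()
    closure_pairs = {(a, b) for (a, b), ok in reach.items() if ok and a != b}
    for a, b in closure_pairs:
        if not any(
            reach[(a, c)] and reach[(c, b)] for c in nodes if c not in (a, b)
        ):
            reduced.add((a, b))
    return reduced


# ---------------------------------------------------------------------------
# Reflexive-transitive ancestry by naive fixpoint (single and mixed chains)
# ---------------------------------------------------------------------------


def fixpoint_ancestors(direct: dict, start) -> set:
    """Reflexive-transitive ancestors over one edge map child -> {parents}."""
    out = {start}
    changed = True
    while changed:
        changed = False
        for node in list(out):
            for parent in direct.get(node, ()):
                if parent not in out:
                    out.add(parent)
                    changed = True
    return out


def part_whole_targets(isa: dict, po: dict, start) -> set:
    """All d such that `start` is entailed to be part of some d: mixed
    is_a/part_of chains containing at least one part_of step."""
    # States: (node, seen_part_of)
    seen = {(start, False)}
    frontier = [(start, False)]
    while frontier:
        node, seen_po = frontier.pop()
        for parent in isa.get(node, ()):
            state = (parent, seen_po)
            if state not in seen:
                seen.add(state)
                frontier.append(state)
        for parent in po.get(node, ()):
            state = (parent, True)
            if state not in seen:
                seen.add(state)
                frontier.append(state)
    return {node for node, seen_po in seen if seen_po}


# ---------------------------------------------------------------------------
# Model-enumeration (canonical model) oracle for EQ subsumption
# ---------------------------------------------------------------------------


class EqTuple:
    """Plain record of an EQ definition for the oracle (strings throughout)."""

    def __init__(self, quality, entity, mode, modifier, occurs_in=None, towards=None, role=None):
        self.quality = quality
        self.entity = entity
        self.mode = mode  # 'co' | 'copo'
        self.modifier = modifier
        self.occurs_in = occurs_in
        self.towards = towards
        self.role = role


def semantic_subsumes(
    sub: EqTuple,
    sup: EqTuple,
    quality_isa: dict,
    entity_isa: dict,
    entity_po: dict,
) -> bool:
    """Canonical-model check: build the witness individuals of ``sub``'s
    definition, saturate role edges under co ⊑ copo and copo∘part_of ⊑
    copo (and occurs_in∘part_of ⊑ occurs_in), then test whether the witness
    satisfies ``sup``'s class expression.
    """
    q_anc = fixpoint_ancestors(quality_isa, sub.quality)
    if sup.quality not in q_anc:
        return False
    if sup.modifier not in fixpoint_ancestors(quality_isa, sub.modifier):
        return False
    if sup.towards is not None:
        if sub.towards is None:
            return False
        if sup.towards not in fixpoint_ancestors(entity_isa, sub.towards):
            return False

    # The bearer witness z: an instance of sub.entity carrying sub's
    # occurs_in / role edges.  The quality witness y reaches z via the sub's
    # mode; under copo saturation it also reaches the canonical individuals
    # of every whole that z is entailed to be part of — but those carry no
    # occurs_in / role edges of their own.
    copo_targets = [("z", True)] + [
        (d, False) for d in sorted(part_whole_targets(entity_isa, entity_po, sub.entity))
    ]
    co_targets = [("z", True)] if sub.mode == "co" else []
    targets = co_targets if sup.mode == "co" else copo_targets

    def satisfies(w, is_witness) -> bool:
        entity_class = sub.entity if is_witness else w
        if sup.entity not in fixpoint_ancestors(entity_isa, entity_class):
            return False
        if sup.occurs_in is not None:
            if not is_witness or sub.occurs_in is None:
                return False
            reach = fixpoint_ancestors(entity_isa, sub.occurs_in) | part_whole_targets(
                entity_isa, entity_po, sub.occurs_in
            )
            if sup.occurs_in not in reach:
                return False
        if sup.role is not None:
            if not is_witness or sub.role is None:
                return False
            if sup.role not in fixpoint_ancestors(entity_isa, sub.role):
                return False
        return True

    return any(satisfies(w, is_witness) for w, is_witness in targets)


# ---------------------------------------------------------------------------
# Exhaustive template matching (conformance oracle)
# ---------------------------------------------------------------------------


def bruteforce_conformant(eq, templates, refs) -> bool:
    """Does any template instantiate to exactly this EQ for some in-range
    filler combination?  Exhaustive enumeration over the filler cross
    product (uses only primitive graph data, not the matcher under test)."""
    from phenokit.eq_model import parse_manchester
    from phenokit.ontology_io import IS_A

    for template in templates:
        tt = template.equivalent_to_template
        if tt is None:
            continue
        # Candidate fillers per var: all reflexive is_a descendants of the range.
        candidates = {}
        feasible = True
        for var, rng in template.vars.items():
            graph = next((g for g in refs.all_graphs() if rng in g), None)
            if graph is None:
                feasible = False
                break
            candidates[var] = sorted(graph.descendants(rng, [IS_A], reflexive=True), key=str)
        if not feasible:
            continue
        var_names = list(tt.vars)
        for combo in itertools.product(*(candidates[v] for v in var_names)):
            label_to_id = dict(template.declared_classes)
            sub_labels = {}
            for var, filler in zip(var_names, combo):
                sentinel = f"__{var}__"
                sub_labels[var] = f"'{sentinel}'"
                label_to_id[sentinel] = filler
            try:
                candidate_eq = parse_manchester(tt.fill(sub_labels), label_to_id)
            except Exception:
                continue
            if candidate_eq == eq:
                return True
    return False
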