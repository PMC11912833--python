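"""Bundle of reference ontology graphs (quality, anatomy, process, ...).

Phenotype logical definitions draw their atoms from several reference
hierarchies: qualities from a PATO-like graph, bearers from anatomy /
process / cell / chemical graphs, and the abnormal/normal modifier from a
modifier branch of the quality graph.  This container keeps the graphs
separate (each keeps its own root) but offers combined lookup and a merged
entity graph for ancestry queries that may cross reference ontologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownTermError
from .ontology_io import Curie, OntologyGraph, OntologyTerm, as_curie


@dataclass
class References:
    quality: OntologyGraph
    entity_graphs: dict[str, OntologyGraph] = field(default_factory=dict)
    quality_root: Curie | None = None
    modifier_root: Curie | None = None
    process_root: Curie | None = None
    _merged: OntologyGraph | None = field(default=None, repr=False, compare=False)

    def all_graphs(self) -> list[OntologyGraph]:
        return [self.quality] + [self.entity_graphs[k] for k in sorted(self.entity_graphs)]

    def resolve(self, curie: str | Curie) -> OntologyTerm:
        c = as_curie(curie)
        for g in self.all_graphs():
            if c in g:
                return g.terms[c]
        raise UnknownTermError(f"unknown term id: {c}")

    def __contains__(self, curie: str | Curie) -> bool:
        c = as_curie(curie)
        return any(c in g for g in self.all_graphs())

    def label(self, curie: str | Curie) -> str:
        return self.resolve(curie).label

    def label_map(self) -> dict[Curie, str]:
        out: dict[Curie, str] = {}
        for g in self.all_graphs():
            out.update(g.label_map())
        return out

    def merged_entity_graph(self) -> OntologyGraph:
        """Union of all non-quality graphs (cached)."""
        if self._merged is None:
            merged = OntologyGraph("merged-entities")
            for key in sorted(self.entity_graphs):
                merged.update(self.entity_graphs[key])
            self._merged = merged
        return self._merged

    def invalidate(self) -> None:
        self._merged = None
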