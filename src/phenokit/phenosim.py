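"""Information content and cross-species semantic similarity.

Information content (IC) of a phenotype term is computed from a
gene-to-phenotype annotation corpus with ancestor propagation:
``IC(t) = -log2(n(t)/N)`` in bits, where ``n(t)`` counts distinct genes
annotated to ``t`` or any of its hierarchy descendants and ``N`` is the gene
count at the root (so ``IC(root) = 0`` and IC grows monotonically along
descent).  Terms with no propagated annotation inherit the IC of their
least-frequent annotated ancestor and are flagged rather than silently
patched.

Pairwise similarity combines ancestor-set Jaccard over the classified
hierarchy with the IC of the most informative common ancestor (MICA) in a
PhenoDigm-style geometric mean, ``sqrt(jaccard * IC(mica)/IC_max)``; profile
similarity is the symmetric best-match average of that score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import PhenokitError, UnknownTermError, ValidationError
from .eq_reasoner import PhenotypeHierarchy
from .ontology_io import Curie, as_curie

__all__ = [
    "AnnotationCorpus",
    "SimilarityResult",
    "ICIndex",
    "information_content",
    "jaccard",
    "mica",
    "phenodigm_score",
    "profile_similarity",
    "similarity_table",
]


@dataclass
class AnnotationCorpus:
    """Deduplicated gene-to-phenotype associations."""

    associations: list[tuple[Curie, Curie]]  # (gene, phenotype)
    propagation: bool = True

    def __post_init__(self):
        seen = set()
        deduped = []
        for g, p in self.associations:
            pair = (as_curie(g), as_curie(p))
            if pair not in seen:
                seen.add(pair)
                deduped.append(pair)
        self.associations = deduped

    @property
    def genes(self) -> set[Curie]:
        return {g for g, _ in self.associations}

    @classmethod
    def from_tsv(cls, text: str) -> "AnnotationCorpus":
        pairs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0] in ("gene_id", "gene"):
                continue
            if len(cells) < 2:
                raise PhenokitError(f"corpus line {lineno}: expected 2 columns")
            pairs.append((cells[0], cells[1]))
        return cls(associations=pairs)

    def to_tsv(self) -> str:
        lines = ["gene_id\tphenotype_id"]
        for g, p in self.associations:
            lines.append(f"{g}\t{p}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SimilarityResult:
    term_a: Curie
    term_b: Curie
    jaccard: float
    mica: Curie
    ic_mica: float
    score: float


class ICIndex:
    """Precomputed IC for every hierarchy term under a corpus.

    Annotations propagate upward: each association contributes its gene to
    the annotated term and all its hierarchy ancestors.
    """

    def __init__(self, hierarchy: PhenotypeHierarchy, corpus: AnnotationCorpus):
        if not corpus.associations:
            raise ValidationError("annotation corpus is empty")
        self.hierarchy = hierarchy
        self.corpus = corpus
        gene_sets: dict[Curie, set[Curie]] = {t: set() for t in hierarchy.nodes}
        for gene, phenotype in corpus.associations:
            if phenotype not in hierarchy.nodes:
                raise UnknownTermError(
                    f"corpus annotates unknown phenotype id: {phenotype}"
                )
            if corpus.propagation:
                for anc in hierarchy.ancestors(phenotype, reflexive=True):
                    gene_sets[anc].add(gene)
            else:
                gene_sets[phenotype].add(gene)
        self.n_genes: dict[Curie, int] = {t: len(gs) for t, gs in gene_sets.items()}
        self.total = self.n_genes[hierarchy.root]
        if self.total == 0:
            raise ValidationError("no annotations reach the hierarchy root")
        self._ic: dict[Curie, float] = {}
        self.fallback_terms: set[Curie] = set()
        for t in hierarchy.nodes:
            n = self.n_genes[t]
            if n > 0:
                self._ic[t] = 0.0 if n == self.total else -math.log2(n / self.total)
        # Unannotated terms inherit the least-frequent annotated ancestor's IC.
        for t in hierarchy.nodes:
            if t in self._ic:
                continue
            annotated_anc = [
                a for a in self.hierarchy.ancestors(t, reflexive=False) if self.n_genes[a] > 0
            ]
            if not annotated_anc:
                self._ic[t] = 0.0
            else:
                self._ic[t] = max(self._ic[a] for a in annotated_anc)
            self.fallback_terms.add(t)
        self.ic_max = max(self._ic.values()) if self._ic else 0.0

    def ic(self, term: str | Curie) -> float:
        term = as_curie(term)
        if term not in self._ic:
            raise UnknownTermError(f"unknown hierarchy term: {term}")
        return self._ic[term]

    def is_fallback(self, term: str | Curie) -> bool:
        return as_curie(term) in self.fallback_terms

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "term_id": str(t),
                "n_genes": self.n_genes[t],
                "ic_bits": self._ic[t],
                "ic_fallback": t in self.fallback_terms,
            }
            for t in sorted(self.hierarchy.nodes)
        ]
        return pd.DataFrame(rows, columns=["term_id", "n_genes", "ic_bits", "ic_fallback"])


def information_content(
    corpus: AnnotationCorpus, hierarchy: PhenotypeHierarchy, term: str | Curie
) -> float:
    """IC of one term in bits (convenience wrapper over :class:`ICIndex`)."""
    return ICIndex(hierarchy, corpus).ic(term)


def jaccard(a: str | Curie, b: str | Curie, hierarchy: PhenotypeHierarchy) -> float:
    """Ancestor-set Jaccard over the classified hierarchy (reflexive sets)."""
    anc_a = hierarchy.ancestors(a, reflexive=True)
    anc_b = hierarchy.ancestors(b, reflexive=True)
    union = anc_a | anc_b
    if not union:
        return 0.0
    return len(anc_a & anc_b) / len(union)


def mica(a: str | Curie, b: str | Curie, hierarchy: PhenotypeHierarchy, ic_index: ICIndex) -> Curie:
    """Most informative common ancestor (reflexive); IC ties break to the
    lexicographically smallest id."""
    common = hierarchy.ancestors(a, reflexive=True) & hierarchy.ancestors(b, reflexive=True)
    if not common:
        raise UnknownTermError(f"no common ancestor for {a} and {b}")
    return min(common, key=lambda t: (-ic_index.ic(t), str(t)))


def phenodigm_score(
    a: str | Curie, b: str | Curie, hierarchy: PhenotypeHierarchy, ic_index: ICIndex
) -> SimilarityResult:
    """Combined PhenoDigm-style score: sqrt(jaccard × IC(mica)/IC_max)."""
    a, b = as_curie(a), as_curie(b)
    j = jaccard(a, b, hierarchy)
    m = mica(a, b, hierarchy, ic_index)
    ic_m = ic_index.ic(m)
    if ic_index.ic_max <= 0:
        score = 0.0
    else:
        score = math.sqrt(max(0.0, j * (ic_m / ic_index.ic_max)))
    return SimilarityResult(term_a=a, term_b=b, jaccard=j, mica=m, ic_mica=ic_m, score=score)


def profile_similarity(
    profile_a,
    profile_b,
    hierarchy: PhenotypeHierarchy,
    ic_index: ICIndex,
) -> float:
    """Symmetric best-match average of the PhenoDigm-style score.

    Mean over both directions of the maximum pairwise score; an empty
    profile yields 0.
    """
    profile_a = [as_curie(t) for t in profile_a]
    profile_b = [as_curie(t) for t in profile_b]
    if not profile_a or not profile_b:
        return 0.0
    scores = {
        (a, b): phenodigm_score(a, b, hierarchy, ic_index).score
        for a in profile_a
        for b in profile_b
    }
    forward = sum(max(scores[(a, b)] for b in profile_b) for a in profile_a) / len(profile_a)
    backward = sum(max(scores[(a, b)] for a in profile_a) for b in profile_b) / len(profile_b)
    return (forward + backward) / 2.0


def similarity_table(
    terms_a,
    terms_b,
    hierarchy: PhenotypeHierarchy,
    ic_index: ICIndex,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """All cross-ontology pairs scoring at least ``threshold``, sorted by
    subject then descending score."""
    rows = []
    for a in sorted((as_curie(t) for t in terms_a), key=str):
        for b in sorted((as_curie(t) for t in terms_b), key=str):
            res = phenodigm_score(a, b, hierarchy, ic_index)
            if res.score >= threshold:
                rows.append(
                    {
                        "subject_id": str(a),
                        "object_id": str(b),
                        "jaccard": res.jaccard,
                        "ic_mica": res.ic_mica,
                        "score": res.score,
                    }
                )
    frame = pd.DataFrame(rows, columns=["subject_id", "object_id", "jaccard", "ic_mica", "score"])
    if not frame.empty:
        frame = frame.sort_values(
            ["subject_id", "score", "object_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return frame
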