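"""Information content and similarity scoring."""

import itertools
import math

import pytest

from phenokit.errors import UnknownTermError, ValidationError
from phenokit.eq_reasoner import PhenotypeHierarchy
from phenokit.fixtures import make_corpus
from phenokit.ontology_io import Curie
from phenokit.phenosim import (
    AnnotationCorpus,
    ICIndex,
    jaccard,
    mica,
    phenodigm_score,
    profile_similarity,
    similarity_table,
)


def _toy_hierarchy() -> PhenotypeHierarchy:
    """Small DAG:  root <- a <- {c, d};  root <- b <- d;  c <- e."""
    c = Curie.parse
    nodes = {c("T:root"), c("T:a"), c("T:b"), c("T:c"), c("T:d"), c("T:e")}
    edges = [
        (c("T:a"), c("T:root"), "inferred"),
        (c("T:b"), c("T:root"), "inferred"),
        (c("T:c"), c("T:a"), "inferred"),
        (c("T:d"), c("T:a"), "inferred"),
        (c("T:d"), c("T:b"), "inferred"),
        (c("T:e"), c("T:c"), "inferred"),
    ]
    return PhenotypeHierarchy(root=c("T:root"), nodes=nodes, edges=edges)


def _toy_corpus() -> AnnotationCorpus:
    """20 genes: 10 on e, 5 on d, 4 on c, 1 on b."""
    pairs = []
    g = 0
    for term, count in [("T:e", 10), ("T:d", 5), ("T:c", 4), ("T:b", 1)]:
        for _ in range(count):
            pairs.append((Curie("G", str(g)), Curie.parse(term)))
            g += 1
    return AnnotationCorpus(associations=pairs)


@pytest.fixture(scope="module")
def toy():
    h = _toy_hierarchy()
    return h, ICIndex(h, _toy_corpus())


class TestInformationContent:
    def test_root_is_zero_bits(self, toy):
        h, ic = toy
        assert ic.ic("T:root") == 0.0

    def test_half_the_genes_is_one_bit(self, toy):
        h, ic = toy
        # T:e carries 10 of 20 genes
        assert ic.ic("T:e") == pytest.approx(1.0)

    def test_matches_bruteforce_descendant_counting(self, toy):
        """IC equals explicit enumeration of descendant gene sets."""
        h, ic = toy
        corpus = _toy_corpus()
        for term in h.nodes:
            genes = {
                g
                for g, p in corpus.associations
                if p in h.descendants(term, reflexive=True)
            }
            if genes:
                assert ic.ic(term) == pytest.approx(-math.log2(len(genes) / 20))

    def test_unannotated_term_inherits_least_frequent_ancestor_flagged(self):
        h = _toy_hierarchy()
        pairs = [(Curie("G", str(i)), Curie.parse("T:c")) for i in range(4)]
        pairs += [(Curie("G", str(i + 10)), Curie.parse("T:b")) for i in range(4)]
        ic = ICIndex(h, AnnotationCorpus(associations=pairs))
        # T:d has no annotations; its annotated ancestors are root, a, b
        assert ic.is_fallback("T:d")
        assert ic.ic("T:d") == max(ic.ic("T:a"), ic.ic("T:b"))

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            ICIndex(_toy_hierarchy(), AnnotationCorpus(associations=[]))

    def test_monotone_non_decreasing_along_descent(self, pipeline):
        h, ic = pipeline.hierarchy, pipeline.ic_index
        for child, parent, _ in h.edges:
            assert ic.ic(child) >= ic.ic(parent) - 1e-12


class TestJaccard:
    def test_self_similarity_is_one(self, toy):
        h, _ = toy
        assert jaccard("T:e", "T:e", h) == 1.0

    def test_distinct_roots_forced_by_set_sizes(self, toy):
        h, _ = toy
        # a and b share only the root: |{root}| / |{root,a,b}|
        assert jaccard("T:a", "T:b", h) == pytest.approx(1 / 3)

    def test_values_equal_hand_enumerated_ancestor_sets(self, toy):
        h, _ = toy
        anc = {
            "T:root": {"T:root"},
            "T:a": {"T:a", "T:root"},
            "T:b": {"T:b", "T:root"},
            "T:c": {"T:c", "T:a", "T:root"},
            "T:d": {"T:d", "T:a", "T:b", "T:root"},
            "T:e": {"T:e", "T:c", "T:a", "T:root"},
        }
        for a, b in itertools.combinations(anc, 2):
            expected = len(anc[a] & anc[b]) / len(anc[a] | anc[b])
            assert jaccard(a, b, h) == pytest.approx(expected)

    def test_unknown_term_is_error(self, toy):
        h, _ = toy
        with pytest.raises(UnknownTermError):
            jaccard("T:nope", "T:a", h)

    def test_symmetry_on_pipeline_terms(self, pipeline):
        h = pipeline.hierarchy
        nodes = sorted(h.nodes, key=str)[:12]
        for a, b in itertools.combinations(nodes, 2):
            assert jaccard(a, b, h) == pytest.approx(jaccard(b, a, h))


class TestMica:
    def test_self_mica_is_self(self, toy):
        h, ic = toy
        assert mica("T:e", "T:e", h, ic) == Curie.parse("T:e")

    def test_sibling_mica_is_parent(self, toy):
        h, ic = toy
        assert mica("T:c", "T:d", h, ic) == Curie.parse("T:a")

    def test_equals_bruteforce_argmax(self, toy):
        h, ic = toy
        for a in h.nodes:
            for b in h.nodes:
                common = h.ancestors(a) & h.ancestors(b)
                best_ic = max(ic.ic(t) for t in common)
                candidates = sorted(t for t in common if ic.ic(t) == best_ic)
                assert mica(a, b, h, ic) == candidates[0]


class TestPhenodigmScore:
    def test_self_at_ic_max_scores_one(self, toy):
        h, ic = toy
        top = max(h.nodes, key=lambda t: (ic.ic(t), str(t)))
        assert phenodigm_score(top, top, h, ic).score == pytest.approx(1.0)

    def test_root_only_common_ancestor_scores_zero(self, toy):
        h, ic = toy
        res = phenodigm_score("T:a", "T:b", h, ic)
        # mica is the root with IC 0
        assert res.ic_mica == 0.0
        assert res.score == 0.0

    def test_equals_composition_of_jaccard_and_ic_oracles(self, toy):
        h, ic = toy
        for a in sorted(h.nodes, key=str):
            for b in sorted(h.nodes, key=str):
                res = phenodigm_score(a, b, h, ic)
                expected = math.sqrt(
                    jaccard(a, b, h) * ic.ic(mica(a, b, h, ic)) / ic.ic_max
                )
                assert res.score == pytest.approx(expected)

    def test_symmetric_and_bounded(self, toy):
        h, ic = toy
        for a in h.nodes:
            for b in h.nodes:
                r1, r2 = phenodigm_score(a, b, h, ic), phenodigm_score(b, a, h, ic)
                assert r1.score == pytest.approx(r2.score)
                assert 0.0 <= r1.score <= 1.0
                assert 0.0 <= r1.jaccard <= 1.0
                assert r1.ic_mica >= 0.0

    def test_heart_trio_outranks_unrelated_kidney_phenotype(self, pipeline):
        """Cross-species grouping effect: the three enlarged-heart terms are
        mutually closer than any of them is to a kidney phenotype."""
        h, ic = pipeline.hierarchy, pipeline.ic_index
        trio = [Curie.parse(t) for t in ("HP:0001640", "MP:0000274", "ZP:0000532")]
        kidney = next(
            c for c, label in pipeline.labels.items()
            if label == "increased size of the kidney"
        )
        within = [
            phenodigm_score(a, b, h, ic).score
            for a, b in itertools.combinations(trio, 2)
        ]
        across = [phenodigm_score(a, kidney, h, ic).score for a in trio]
        assert min(within) > max(across)


class TestProfileSimilarity:
    def test_identical_ic_max_profiles_score_one(self, toy):
        h, ic = toy
        top = max(h.nodes, key=lambda t: (ic.ic(t), str(t)))
        assert profile_similarity([top], [top], h, ic) == pytest.approx(1.0)

    def test_empty_profile_scores_zero(self, toy):
        h, ic = toy
        assert profile_similarity([], ["T:a"], h, ic) == 0.0

    def test_equals_bruteforce_best_match_average(self, toy):
        h, ic = toy
        nodes = sorted(h.nodes, key=str)
        profile_a, profile_b = nodes[:5], nodes[1:6]
        scores = {
            (a, b): phenodigm_score(a, b, h, ic).score
            for a in profile_a for b in profile_b
        }
        fwd = sum(max(scores[(a, b)] for b in profile_b) for a in profile_a) / 5
        bwd = sum(max(scores[(a, b)] for a in profile_a) for b in profile_b) / 5
        assert profile_similarity(profile_a, profile_b, h, ic) == pytest.approx(
            (fwd + bwd) / 2
        )


class TestSimilarityTable:
    def test_threshold_above_one_is_empty(self, toy):
        h, ic = toy
        table = similarity_table(["T:c"], ["T:d"], h, ic, threshold=1.0 + 1e-9)
        assert table.empty

    def test_threshold_zero_gives_full_cross_product(self, toy):
        h, ic = toy
        table = similarity_table(["T:c", "T:d"], ["T:a", "T:b", "T:e"], h, ic, threshold=0.0)
        assert len(table) == 6

    def test_rows_equal_per_pair_recomputation(self, toy):
        h, ic = toy
        table = similarity_table(["T:c", "T:d"], ["T:a", "T:e"], h, ic, threshold=0.0)
        for row in table.itertuples():
            res = phenodigm_score(row.subject_id, row.object_id, h, ic)
            assert row.jaccard == pytest.approx(res.jaccard)
            assert row.ic_mica == pytest.approx(res.ic_mica)
            assert row.score == pytest.approx(res.score)

    def test_sorted_by_subject_then_descending_score(self, pipeline):
        table = pipeline.similarity
        for _, group in table.groupby("subject_id"):
            scores = list(group["score"])
            assert scores == sorted(scores, reverse=True)


class TestMakeCorpus:
    def test_zero_genes_is_error(self, pipeline):
        with pytest.raises(ValidationError):
            make_corpus(1, 0, 1.2, pipeline.hierarchy)

    def test_deterministic_for_fixed_seed(self, pipeline):
        a = make_corpus(7, 30, 1.2, pipeline.hierarchy)
        b = make_corpus(7, 30, 1.2, pipeline.hierarchy)
        assert a.associations == b.associations

    def test_frequencies_match_sampling_oracle_within_3_sigma(self, pipeline):
        """Leaf draw frequencies agree with the Zipf weights multinomially."""
        h = pipeline.hierarchy
        # one draw per gene: distinct genes cannot collapse under
        # association deduplication, so draw counts are a clean multinomial
        n_genes, k = 5000, 1
        corpus = make_corpus(11, n_genes, 1.2, h, annotations_per_gene=k,
                             ensure_coverage=False)
        leaves = sorted(
            (n for n in h.nodes if not h.children(n) and n != h.root), key=str
        )
        weights = [1.0 / (r ** 1.2) for r in range(1, len(leaves) + 1)]
        total_w = sum(weights)
        counts = {leaf: 0 for leaf in leaves}
        for _, p in corpus.associations:
            counts[p] += 1
        n_draws = n_genes * k
        for leaf, w in zip(leaves, weights):
            p = w / total_w
            sigma = math.sqrt(n_draws * p * (1 - p))
            assert abs(counts[leaf] - n_draws * p) <= 3 * sigma + 1e-9
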