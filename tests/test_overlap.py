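import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigportrait import (
    QuadrantResult,
    build_composite,
    combine_treatments,
    congruence_score,
    gene_list_overlap,
    hypergeom_overlap,
    quadrant_analysis,
    rank_treatments,
    reversed_genes,
    top_lists,
    treatment_score,
)
from sigportrait.overlap import ReversalSets
from tests.conftest import make_scores


def enumerate_upper_tail(N, K, n, k):
    """Brute-force P(X >= k): enumerate every n-subset of an N-universe
    against a fixed K-subset and count overlaps."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def overlapping_lists(N, K, n, k):
    """Gene lists over an N-universe with |l1|=K, |l2|=n, |l1 & l2|=k."""
    universe = [f"g{i}" for i in range(N)]
    l1 = universe[:K]
    l2 = universe[:k] + universe[K:K + n - k]
    return l1, l2, universe


class TestHypergeomOverlap:
    def test_two_by_two_over_four(self):
        l1, l2, u = overlapping_lists(4, 2, 2, 2)
        result = hypergeom_overlap(l1, l2, u)
        assert result.p == pytest.approx(1 / 6, rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        l1, l2, u = overlapping_lists(10, 3, 3, 0)
        result = hypergeom_overlap(l1, l2, u)
        assert result.p == 1.0
        assert result.nlp == 0.0

    def test_three_vs_four_over_ten(self):
        l1, l2, u = overlapping_lists(10, 3, 4, 3)
        result = hypergeom_overlap(l1, l2, u)
        assert result.p == pytest.approx(1 / 30, rel=1e-12)
        assert result.nlp == pytest.approx(-math.log10(1 / 30), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_overlap(["a"], ["a"], [])

    def test_genes_outside_universe_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="not in universe"):
            result = hypergeom_overlap(["a", "zzz"], ["a"], ["a", "b", "c"])
        assert result.n1 == 1
        assert result.k == 1

    def test_common_genes_reported(self):
        result = hypergeom_overlap(["a", "b"], ["b", "c"], ["a", "b", "c", "d"])
        assert result.common == frozenset({"b"})

    @given(
        N=st.integers(1, 12),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        l1, l2, u = overlapping_lists(N, K, n, k)
        result = hypergeom_overlap(l1, l2, u)
        expected = enumerate_upper_tail(N, K, n, k)
        assert result.p == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_symmetry(self):
        l1, l2, u = overlapping_lists(20, 6, 9, 4)
        a = hypergeom_overlap(l1, l2, u)
        b = hypergeom_overlap(l2, l1, u)
        assert a.p == pytest.approx(b.p, rel=1e-12)
        assert a.nlp == pytest.approx(b.nlp, rel=1e-12)

    def test_nlp_monotone_in_k(self):
        N, K, n = 40, 10, 12
        nlps = []
        for k in range(0, 11):
            l1, l2, u = overlapping_lists(N, K, n, k)
            nlps.append(hypergeom_overlap(l1, l2, u).nlp)
        assert all(b >= a for a, b in zip(nlps, nlps[1:]))


class TestTopLists:
    def test_truncation_to_available(self):
        sig = make_scores({f"U{i}": float(i + 1) for i in range(600)})
        up, down = top_lists(sig, n=1000)
        assert len(up) == 600
        assert down == []

    def test_n_one(self):
        sig = make_scores({"A": 3.0, "B": 1.0, "C": -5.0, "D": -1.0})
        up, down = top_lists(sig, n=1)
        assert up == ["A"] and down == ["C"]

    def test_portrait_input_ordered_by_abs_score(self):
        tables = [
            make_scores({"A": 3.0, "B": -6.0, "C": 1.0}, "d1"),
            make_scores({"A": 2.0, "B": -5.0, "C": 0.5}, "d2"),
        ]
        portrait = build_composite(tables)
        up, down = top_lists(portrait, n=10)
        assert up == ["A", "C"]
        assert down == ["B"]


class TestQuadrantAnalysis:
    def test_self_comparison(self):
        sig = make_scores({"A": 3.0, "B": 1.0, "C": -5.0, "D": -1.0, "E": 0.0})
        q = quadrant_analysis(sig, sig, n=10, shared_gene_threshold=1)
        assert (q.A, q.B, q.C, q.D) == (2, 0, 0, 2)

    def test_exact_sign_flip(self):
        sig = make_scores({"A": 3.0, "B": 1.0, "C": -5.0, "D": -1.0})
        flip = make_scores({"A": -3.0, "B": -1.0, "C": 5.0, "D": 1.0}, "flip")
        q = quadrant_analysis(sig, flip, n=10, shared_gene_threshold=1)
        assert (q.A, q.B, q.C, q.D) == (0, 2, 2, 0)

    def test_eight_gene_derived_example(self, eight_gene_pair):
        sig1, sig2 = eight_gene_pair
        q = quadrant_analysis(sig1, sig2, n=2, shared_gene_threshold=1)
        assert (q.A, q.B, q.C, q.D) == (0, 1, 1, 0)
        assert q.pB == pytest.approx(13 / 28, rel=1e-12)
        assert q.pC == pytest.approx(13 / 28, rel=1e-12)
        assert q.universe_size == 8

    def test_incompatible_pair_flagged_not_excluded(self):
        sig = make_scores({"A": 1.0, "B": -1.0})
        q = quadrant_analysis(sig, sig, n=2, shared_gene_threshold=5000)
        assert q.compatible is False
        assert q.A == 1  # computation proceeded

    def test_no_shared_genes_rejected(self):
        a = make_scores({"A": 1.0})
        b = make_scores({"B": 1.0}, "other")
        with pytest.raises(ValueError, match="share no genes"):
            quadrant_analysis(a, b)


def random_quadrant(rng):
    nlps = rng.uniform(0, 50, 4)
    ps = 10.0 ** -nlps
    return QuadrantResult(
        A=1, B=1, C=1, D=1,
        pA=ps[0], pB=ps[1], pC=ps[2], pD=ps[3],
        nlpA=nlps[0], nlpB=nlps[1], nlpC=nlps[2], nlpD=nlps[3],
        universe_size=1000, list_sizes=(10, 10, 10, 10),
    )


class TestScores:
    def test_congruence_on_derived_example(self, eight_gene_pair):
        q = quadrant_analysis(*eight_gene_pair, n=2, shared_gene_threshold=1)
        expected = -2 * (-math.log10(13 / 28))
        assert congruence_score(q) == pytest.approx(expected, rel=1e-9)
        assert treatment_score(q) == pytest.approx(-expected, rel=1e-9)
        assert treatment_score(q) == pytest.approx(0.6664, abs=5e-4)

    def test_all_p_one_scores_zero(self):
        q = QuadrantResult(0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0, 100, (5, 5, 5, 5))
        assert congruence_score(q) == 0.0
        assert treatment_score(q) == 0.0

    def test_self_comparison_congruence_maximal(self):
        sig = make_scores({"A": 3.0, "B": 1.0, "C": -5.0, "D": -1.0})
        q = quadrant_analysis(sig, sig, n=10, shared_gene_threshold=1)
        assert congruence_score(q) == pytest.approx(q.nlpA + q.nlpD)
        assert congruence_score(q) > 0

    def test_treatment_is_negated_congruence(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            q = random_quadrant(rng)
            assert treatment_score(q) == pytest.approx(-congruence_score(q), rel=1e-12)


class TestReversedGenes:
    def test_sign_flip_has_no_same_direction(self):
        sig = make_scores({"A": 3.0, "B": 1.0, "C": -5.0, "D": -1.0})
        flip = make_scores({"A": -3.0, "B": -1.0, "C": 5.0, "D": 1.0}, "flip")
        rev = reversed_genes(sig, flip, n=10, shared_gene_threshold=1)
        assert rev.same_direction == frozenset()
        assert rev.up_reversed == frozenset({"A", "B"})
        assert rev.down_reversed == frozenset({"C", "D"})

    def test_eight_gene_example(self, eight_gene_pair):
        sig1, sig2 = eight_gene_pair
        rev = reversed_genes(sig1, sig2, n=2, shared_gene_threshold=1)
        assert rev.down_reversed == frozenset({"G3"})
        assert rev.up_reversed == frozenset({"G1"})

    def test_counts_match_quadrants(self, eight_gene_pair):
        rev = reversed_genes(*eight_gene_pair, n=2, shared_gene_threshold=1)
        assert len(rev.up_reversed) == rev.quadrants.B
        assert len(rev.down_reversed) == rev.quadrants.C

    def test_sets_pairwise_disjoint(self, eight_gene_pair):
        rev = reversed_genes(*eight_gene_pair, n=2, shared_gene_threshold=1)
        assert not rev.up_reversed & rev.down_reversed
        assert not rev.reversed_genes & rev.same_direction

    def test_random_overlap_near_hypergeometric_mean(self):
        # unrelated treatment: per-quadrant overlap should hover near n^2/N
        rng = np.random.default_rng(0)
        n_genes, n = 3000, 500
        genes = [f"G{i}" for i in range(n_genes)]
        disease = make_scores(dict(zip(genes, rng.normal(0, 3, n_genes))), "dz")
        counts = []
        for s in range(10):
            r = np.random.default_rng(s)
            trt = make_scores(dict(zip(genes, r.normal(0, 3, n_genes))), f"t{s}")
            rev = reversed_genes(disease, trt, n=n, shared_gene_threshold=1)
            counts.append(len(rev.up_reversed))
        mean = n * n / n_genes  # ~83.3
        assert abs(np.mean(counts) - mean) < 4 * np.sqrt(mean)


class TestCombineTreatments:
    def test_printed_counts_reproduce_union(self):
        # sizes 344 and 249 with a 44-gene intersection -> union 549
        shared = [f"S{i}" for i in range(44)]
        ex_only = [f"E{i}" for i in range(300)]
        fl_only = [f"F{i}" for i in range(205)]
        exercise = (set(shared[:20]) | set(ex_only[:153]),
                    set(shared[20:]) | set(ex_only[153:]))
        fluoxetine = (set(shared[:30]) | set(fl_only[:70]),
                      set(shared[30:]) | set(fl_only[70:]))
        assert len(exercise[0] | exercise[1]) == 344
        assert len(fluoxetine[0] | fluoxetine[1]) == 249
        result = combine_treatments([exercise, fluoxetine])
        assert result.count == 549
        assert result.pairwise_intersections[(0, 1)] == 44

    def test_disjoint_sets_add(self):
        result = combine_treatments([({"A", "B"}, {"C"}), ({"D"}, {"E", "F"})])
        assert result.count == 6
        assert result.pairwise_intersections[(0, 1)] == 0

    def test_identical_sets(self):
        result = combine_treatments([({"A"}, {"B"}), ({"A"}, {"B"})])
        assert result.count == 2

    def test_accepts_reversal_sets(self, eight_gene_pair):
        rev = reversed_genes(*eight_gene_pair, n=2, shared_gene_threshold=1)
        result = combine_treatments([rev, rev])
        assert result.count == rev.n_reversed

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            combine_treatments([({"A"}, {"B"})])


class TestRankTreatments:
    def test_forced_ordering(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(400)]
        values = rng.normal(0, 3, 400)
        disease = make_scores(dict(zip(genes, values)), "disease")
        flip = make_scores(dict(zip(genes, -values)), "flip")
        same = make_scores(dict(zip(genes, values)), "same")
        shuffled_vals = rng.permutation(values)
        shuffled = make_scores(dict(zip(genes, shuffled_vals)), "shuffled")
        ranked = rank_treatments(
            disease, [same, shuffled, flip], n=100, shared_gene_threshold=1
        )
        assert [r.dataset_id for r in ranked] == ["flip", "shuffled", "same"]

    def test_empty_treatment_set(self):
        disease = make_scores({"A": 1.0, "B": -1.0})
        assert rank_treatments(disease, [], n=2, shared_gene_threshold=1) == []

    def test_strict_mode_excludes_incompatible(self):
        disease = make_scores({"A": 1.0, "B": -1.0, "C": 2.0})
        trt = make_scores({"A": -1.0, "B": 1.0}, "small")
        kept = rank_treatments(disease, [trt], n=2, shared_gene_threshold=1)
        dropped = rank_treatments(
            disease, [trt], n=2, shared_gene_threshold=5000, strict=True
        )
        assert len(kept) == 1
        assert dropped == []


class TestGeneListOverlap:
    def test_identical_lists(self):
        u = [f"g{i}" for i in range(50)]
        result = gene_list_overlap(u[:10], u[:10], u)
        assert result.k == 10
        assert result.p < 1e-9

    def test_disjoint_lists(self):
        u = [f"g{i}" for i in range(50)]
        result = gene_list_overlap(u[:10], u[10:20], u)
        assert result.k == 0
        assert result.p == 1.0

    def test_three_vs_four_over_ten(self):
        l1, l2, u = overlapping_lists(10, 3, 4, 3)
        result = gene_list_overlap(l1, l2, u)
        assert result.p == pytest.approx(1 / 30, rel=1e-12)
        assert result.common == frozenset(l1[:3])
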