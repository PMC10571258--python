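import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speakeasy2 import (
    Cover,
    Partition,
    WeightedGraph,
    ari,
    modularity_density,
    modularity_signed,
    multicommunity_f1,
    nmi,
    omega_index,
    overlapping_nmi,
    overlapping_quality,
)
from tests.conftest import clique_edges, random_graph


def part(ids, labels):
    return Partition(tuple(ids), np.asarray(labels))


def two_triangles():
    ids = [f"t{i}" for i in range(6)]
    edges = clique_edges(range(3)) + clique_edges(range(3, 6))
    return WeightedGraph.from_edges(ids, edges), part(ids, [0, 0, 0, 1, 1, 1])


class TestNMI:
    def test_identical_is_one(self):
        p = part("abcd", [0, 0, 1, 1])
        q = part("abcd", [5, 5, 2, 2])
        assert nmi(p, q) == pytest.approx(1.0)

    def test_all_in_one_vs_singletons_is_zero(self):
        p = part("abcd", [0, 0, 0, 0])
        q = part("abcd", [0, 1, 2, 3])
        assert nmi(p, q) == pytest.approx(0.0)

    def test_hand_computed_contingency_value(self):
        # P = {ab|cd}, Q = {abc|d}; MI and entropies from the 2x2 table,
        # normalized by the arithmetic mean of the entropies
        p = part("abcd", [0, 0, 1, 1])
        q = part("abcd", [0, 0, 0, 1])
        nij = {(0, 0): 2, (1, 0): 1, (1, 1): 1}
        a = {0: 2, 1: 2}
        b = {0: 3, 1: 1}
        n = 4
        mi = sum(
            c / n * math.log(n * c / (a[i] * b[j])) for (i, j), c in nij.items()
        )
        h = lambda counts: -sum(c / n * math.log(c / n) for c in counts.values())
        expected = mi / ((h(a) + h(b)) / 2)
        assert nmi(p, q) == pytest.approx(expected, abs=1e-12)
        assert nmi(p, q) == pytest.approx(0.34370, abs=1e-4)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi(part("abc", [0, 0, 1]), part("abd", [0, 0, 1]))


class TestARI:
    def test_identical_and_permuted(self):
        p = part("abcdef", [0, 0, 1, 1, 2, 2])
        q = part("abcdef", [2, 2, 0, 0, 1, 1])
        assert ari(p, p) == pytest.approx(1.0)
        assert ari(p, q) == pytest.approx(1.0)

    def test_hand_pair_counting_gives_zero(self):
        # agreeing pairs = 1 = chance expectation -> ARI 0
        p = part("abcd", [0, 0, 1, 1])
        q = part("abcd", [0, 0, 0, 1])
        assert ari(p, q) == pytest.approx(0.0, abs=1e-12)


class TestModularitySigned:
    def test_single_community_is_zero(self):
        g, _ = two_triangles()
        p = part(g.node_ids, [0] * 6)
        assert modularity_signed(g, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_half(self):
        g, p = two_triangles()
        assert modularity_signed(g, p) == pytest.approx(0.5)

    def test_signed_two_block_toy_hand_value(self):
        # blocks {0,1} and {2,3}: +1 within, -1 between 0-2
        # Q+ = 0.5, Q- = -0.5, weights w+=2, w-=1 -> (2*0.5+1*0.5)/3 = 0.5
        g = WeightedGraph.from_edges(
            "abcd", [(0, 1, 1.0), (2, 3, 1.0), (0, 2, -1.0)]
        )
        p = part("abcd", [0, 0, 1, 1])
        assert modularity_signed(g, p) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_double_loop(self, seed):
        # independent oracle: Q = (1/2w) sum_ij [w_ij - s_i s_j / 2w] delta
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(4, 13)))
        labels = rng.integers(0, 3, g.n_nodes)
        p = part(g.node_ids, labels)
        A = g.offdiag().toarray()
        s = A.sum(axis=1)
        two_w = A.sum()
        q = 0.0
        for i in range(g.n_nodes):
            for j in range(g.n_nodes):
                if p.labels[i] == p.labels[j]:
                    q += (A[i, j] - s[i] * s[j] / two_w) / two_w
        assert modularity_signed(g, p) == pytest.approx(q, abs=1e-12)


class TestModularityDensity:
    def test_two_triangles_half(self):
        g, p = two_triangles()
        assert modularity_density(g, p) == pytest.approx(0.5)

    def test_merging_separate_cliques_scores_lower(self):
        g, p = two_triangles()
        merged = part(g.node_ids, [0] * 6)
        assert modularity_density(g, merged) < modularity_density(g, p)

    def test_isolated_singleton_contributes_nothing(self):
        ids = [f"t{i}" for i in range(7)]
        edges = clique_edges(range(3)) + clique_edges(range(3, 6))
        g = WeightedGraph.from_edges(ids, edges)
        p = part(ids, [0, 0, 0, 1, 1, 1, 2])
        assert modularity_density(g, p) == pytest.approx(0.5)

    def test_empty_community_rejected(self):
        g, p = two_triangles()
        bad = part(g.node_ids, [0, 0, 0, 1, 1, 1])
        object.__setattr__(bad, "labels", np.array([0, 0, 0, 2, 2, 2]))
        with pytest.raises(ValueError):
            modularity_density(g, bad)


def cover_from_sets(ids, sets):
    return Cover(tuple(ids), tuple(frozenset(s) for s in sets))


class TestOmegaIndex:
    def test_identical_is_one(self):
        c = cover_from_sets("abcde", [{0}, {0, 1}, {1}, {1}, {0}])
        assert omega_index(c, c) == pytest.approx(1.0)

    @given(st.integers(0, 49))
    @settings(max_examples=50, deadline=None)
    def test_equals_ari_on_disjoint_covers(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        ids = [f"n{i}" for i in range(n)]
        l1 = rng.integers(0, 3, n)
        l2 = rng.integers(0, 3, n)
        p1, p2 = part(ids, l1), part(ids, l2)
        expected = ari(p1, p2)
        got = omega_index(p1.to_cover(), p2.to_cover())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_five_node_overlap_toy_matches_pair_enumeration(self):
        ids = "abcde"
        c1 = cover_from_sets(ids, [{0}, {0, 1}, {1}, {1, 0}, {1}])
        c2 = cover_from_sets(ids, [{0}, {0}, {1}, {1, 0}, {1}])
        shared = lambda c, i, j: len(
            c.memberships[i] & c.memberships[j]
        )
        t1, t2 = [], []
        for i, j in itertools.combinations(range(5), 2):
            t1.append(shared(c1, i, j))
            t2.append(shared(c2, i, j))
        t1, t2 = np.array(t1), np.array(t2)
        obs = np.mean(t1 == t2)
        exp = sum(
            np.mean(t1 == k) * np.mean(t2 == k)
            for k in set(t1) | set(t2)
        )
        expected = (obs - exp) / (1 - exp)
        assert omega_index(c1, c2) == pytest.approx(expected, abs=1e-12)


class TestOverlappingNMI:
    def test_identical_and_relabeled_covers_score_one(self):
        ids = "abcdef"
        c1 = cover_from_sets(ids, [{0}, {0}, {0, 1}, {1}, {1}, {1}])
        c2 = cover_from_sets(ids, [{7}, {7}, {7, 3}, {3}, {3}, {3}])
        assert overlapping_nmi(c1, c1) == pytest.approx(1.0)
        assert overlapping_nmi(c1, c2) == pytest.approx(1.0)

    def test_shared_node_toy_regression(self):
        # 6-node cover with one shared node vs its disjoint version;
        # value pinned from direct evaluation of the set-matching formula
        ids = "abcdef"
        c_over = cover_from_sets(ids, [{0}, {0}, {0, 1}, {1}, {1}, {1}])
        c_disj = cover_from_sets(ids, [{0}, {0}, {0}, {1}, {1}, {1}])
        # hand evaluation: H(X1|Y)=0 (exact match); H(X2|Y2)=0.3183 nats
        # (table a=2/6, c=1/6, d=3/6), normalized 0.5001; symmetric side
        # 0.2705 -> 1 - (0.2500 + 0.2705)/2
        val = overlapping_nmi(c_over, c_disj)
        assert val == pytest.approx(0.739787, abs=1e-5)

    def test_symmetry(self):
        ids = "abcdef"
        c1 = cover_from_sets(ids, [{0}, {0}, {0, 1}, {1}, {1}, {1}])
        c2 = cover_from_sets(ids, [{0}, {1}, {0}, {1}, {0}, {1}])
        assert overlapping_nmi(c1, c2) == pytest.approx(overlapping_nmi(c2, c1))


class TestOverlappingQuality:
    @pytest.mark.parametrize("seed", range(5))
    def test_reduces_to_disjoint_measures_on_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 10)
        labels = rng.integers(0, 3, g.n_nodes)
        p = part(g.node_ids, labels)
        q_ov, qds_ov = overlapping_quality(g, p.to_cover())
        assert q_ov == pytest.approx(modularity_signed(g, p), abs=1e-12)
        assert qds_ov == pytest.approx(modularity_density(g, p), abs=1e-12)

    def test_butterfly_matches_brute_force_belonging_sums(self, butterfly):
        cover = cover_from_sets(
            butterfly.node_ids, [{0}, {0}, {0, 1}, {1}, {1}]
        )
        A = butterfly.offdiag().toarray()
        s = A.sum(axis=1)
        two_w = A.sum()
        alpha = np.zeros((5, 2))
        for i, mem in enumerate(cover.memberships):
            for c in mem:
                alpha[i, c] = 1 / len(mem)
        q = sum(
            alpha[i, c] * alpha[j, c] * (A[i, j] - s[i] * s[j] / two_w) / two_w
            for i in range(5)
            for j in range(5)
            for c in range(2)
        )
        q_ov, qds_ov = overlapping_quality(butterfly, cover)
        assert q_ov == pytest.approx(q, abs=1e-12)
        # density-weighted version from the definition, effective sizes
        n_eff = alpha.sum(axis=0)
        qds = 0.0
        for c in range(2):
            w_in = sum(
                alpha[i, c] * alpha[j, c] * A[i, j]
                for i in range(5)
                for j in range(5)
            ) / 2
            att = sum(alpha[i, c] * s[i] for i in range(5))
            d_c = 2 * w_in / (n_eff[c] * (n_eff[c] - 1))
            qds += (2 * w_in / two_w) * d_c - ((att / two_w) * d_c) ** 2
            c2 = 1 - c
            w_cc = sum(
                alpha[i, c] * alpha[j, c2] * A[i, j]
                for i in range(5)
                for j in range(5)
            )
            qds -= (w_cc / two_w) * (w_cc / (n_eff[c] * n_eff[c2]))
        assert qds_ov == pytest.approx(qds, abs=1e-12)

    def test_everything_everywhere_is_nonpositive(self, butterfly):
        cover = cover_from_sets(butterfly.node_ids, [{0, 1}] * 5)
        q_ov, _ = overlapping_quality(butterfly, cover)
        assert q_ov <= 1e-12


class TestMulticommunityF1:
    def test_perfect_agreement(self):
        c = cover_from_sets("abcd", [{0}, {0, 1}, {1}, {1}])
        sens, spec, f1, counts = multicommunity_f1(c, c)
        assert (sens, spec, f1) == (1.0, 1.0, 1.0)
        assert counts.n_nodes == 4

    def test_no_calls_at_all(self):
        truth = cover_from_sets("abcd", [{0}, {0, 1}, {1}, {1}])
        inferred = cover_from_sets("abcd", [{0}, {0}, {1}, {1}])
        sens, spec, f1, _ = multicommunity_f1(inferred, truth)
        assert sens == 0.0
        assert spec == 1.0
        assert f1 == 0.0

    def test_confusion_arithmetic(self):
        ids = [f"n{i}" for i in range(10)]
        truth = cover_from_sets(
            ids, [{0, 1}, {0, 1}] + [{0}] * 8
        )
        inferred = cover_from_sets(
            ids, [{0, 1}] + [{0}] + [{0, 1}] + [{0}] * 7
        )
        sens, spec, f1, counts = multicommunity_f1(inferred, truth)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 1, 1, 7)
        assert sens == pytest.approx(0.5)
        assert f1 == pytest.approx(0.5)


class TestMetricInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_measures_are_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        ids = [f"n{i}" for i in range(n)]
        p = part(ids, rng.integers(0, 3, n))
        q = part(ids, rng.integers(0, 4, n))
        assert nmi(p, q) == pytest.approx(nmi(q, p))
        assert ari(p, q) == pytest.approx(ari(q, p))
        assert omega_index(p.to_cover(), q.to_cover()) == pytest.approx(
            omega_index(q.to_cover(), p.to_cover())
        )
        assert 0.0 <= nmi(p, q) <= 1.0
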