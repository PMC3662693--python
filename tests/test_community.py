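"""OTU clustering, cutoff derivation and alpha-diversity estimators."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from _oracles import (
    brute_force_furthest_neighbour,
    diameter_ok,
    monte_carlo_rarefaction,
    random_distance_matrix,
)
from denitcath import community as cm


class TestClusterOtus:
    def test_all_within_cutoff_one_otu(self, rng):
        dm = random_distance_matrix(6, rng, low=0.01, high=0.1)
        assert cm.cluster_otus(dm, 0.2).n_otus == 1

    def test_all_beyond_cutoff_singletons(self, rng):
        dm = random_distance_matrix(6, rng, low=0.5, high=0.9)
        assert cm.cluster_otus(dm, 0.2).n_otus == 6

    def test_two_planted_pairs(self):
        labels = ["a", "b", "c", "d"]
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.05
        d[2, 3] = d[3, 2] = 0.05
        result = cm.cluster_otus(DistanceMatrix(d, ids=labels), 0.2)
        assert set(result.otus) == {frozenset("ab"), frozenset("cd")}

    def test_single_sequence(self):
        dm = DistanceMatrix(np.zeros((1, 1)), ids=["only"])
        assert cm.cluster_otus(dm, 0.2).otus == (frozenset({"only"}),)

    def test_agrees_with_brute_force_search(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 8))
            cutoff = float(rng.uniform(0.05, 0.95))
            dm = random_distance_matrix(n, rng)
            ours = set(cm.cluster_otus(dm, cutoff).otus)
            assert ours == brute_force_furthest_neighbour(dm, cutoff)
            assert diameter_ok(dm, ours, cutoff)

    def test_otu_count_non_increasing_in_cutoff(self, rng):
        dm = random_distance_matrix(10, rng)
        counts = [cm.cluster_otus(dm, c).n_otus for c in np.linspace(0.05, 0.95, 10)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_output_order(self, rng):
        dm = random_distance_matrix(8, rng)
        a = cm.cluster_otus(dm, 0.4)
        b = cm.cluster_otus(dm, 0.4)
        assert a.otus == b.otus
        assert list(a.abundances) == sorted(a.abundances, reverse=True)


class TestDeriveCutoff:
    def test_slope_seven_lands_on_napa_cutoff(self):
        pairs = [(7 * x, x) for x in np.linspace(0.005, 0.14, 15)]
        assert cm.derive_cutoff(pairs, 0.03) == 0.21

    def test_identity_relation(self):
        pairs = [(x, x) for x in np.linspace(0.01, 0.3, 12)]
        assert cm.derive_cutoff(pairs, 0.03) == 0.03

    def test_recovers_noisy_slope(self, rng):
        x = rng.uniform(0.02, 0.3, size=40)
        y = np.clip(2.0 * x + rng.normal(0, 0.005, size=40), 0, 1)
        assert cm.derive_cutoff(list(zip(y, x)), 0.03) == pytest.approx(0.06, abs=0.005)

    def test_requires_enough_pairs(self):
        with pytest.raises(ValueError, match=">= 10"):
            cm.derive_cutoff([(0.1, 0.05)] * 5)

    def test_degenerate_16s_distances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cm.derive_cutoff([(0.1, 0.0)] * 12)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5], 2.0), ([1, 1, 2, 2], 4 + 2 * 1 / (2 * 3)), ([1, 1, 1], 6.0)],
    )
    def test_chao1_hand_values(self, counts, expected):
        assert cm.chao1(counts) == pytest.approx(expected)

    def test_chao1_reduces_to_richness_without_singletons(self, rng):
        counts = rng.integers(2, 30, size=12)
        assert cm.chao1(counts) == pytest.approx(len(counts))

    def test_chao1_never_below_observed(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 10, size=int(rng.integers(1, 20)))
            assert cm.chao1(counts) >= len(counts)

    @pytest.mark.parametrize(
        "counts,expected",
        [([1, 1, 33, 15], 0.96), ([2, 3, 4], 1.0), ([1, 1, 1, 1], 0.0)],
    )
    def test_goods_coverage(self, counts, expected):
        assert cm.goods_coverage(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts,expected",
        [([10, 10, 10, 10], np.log(4)), ([42], 0.0), ([30, 18, 1, 1], 0.8308)],
    )
    def test_shannon_hand_values(self, counts, expected):
        assert cm.shannon(counts).h == pytest.approx(expected, abs=5e-4)

    def test_shannon_ci_brackets_h(self):
        res = cm.shannon([30, 18, 1, 1])
        assert res.ci_low <= res.h <= res.ci_high
        assert res.sd == pytest.approx(np.sqrt(res.variance))

    def test_empty_vector_rejected(self):
        for fn in (cm.chao1, cm.goods_coverage, cm.shannon, cm.diversity_summary):
            with pytest.raises(ValueError):
                fn([])


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        counts = [5, 3, 2, 1, 1]
        assert cm.rarefaction(counts, [12])[0] == pytest.approx(5.0)

    def test_single_draw_yields_one(self):
        assert cm.rarefaction([5, 3, 2], [1])[0] == pytest.approx(1.0)

    def test_two_pairs_at_depth_two(self):
        assert cm.rarefaction([2, 2], [2])[0] == pytest.approx(2 - 2 * 1 / 6)

    def test_depth_beyond_n_rejected(self):
        with pytest.raises(ValueError):
            cm.rarefaction([2, 2], [5])

    def test_monotone_and_concave(self):
        counts = [40, 20, 10, 5, 2, 1, 1, 1]
        n = sum(counts)
        curve = cm.rarefaction(counts, np.arange(1, n + 1))
        diffs = np.diff(curve)
        assert np.all(diffs >= -1e-12)
        assert np.all(np.diff(diffs) <= 1e-12)

    def test_matches_monte_carlo_means(self, rng):
        counts = np.array([25, 12, 6, 3, 2, 1, 1])
        n = counts.sum()
        for depth in (5, 15, 30):
            exact = cm.rarefaction(counts, [depth])[0]
            mc_mean, mc_se = monte_carlo_rarefaction(counts, depth, 10_000, rng)
            assert abs(exact - mc_mean) <= 3 * mc_se


class TestDiversitySummary:
    def test_summary_consistent_with_parts(self):
        counts = [30, 10, 5, 2, 1, 1, 1]
        d = cm.diversity_summary(counts)
        assert d.n == 50
        assert d.s_obs == 7
        assert d.f1 == 3 and d.f2 == 1
        assert d.s_chao1 == pytest.approx(cm.chao1(counts))
        assert d.coverage_pct == pytest.approx(100 * cm.goods_coverage(counts))
        assert d.shannon == pytest.approx(cm.shannon(counts).h)
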