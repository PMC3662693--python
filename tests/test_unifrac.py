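"""Weighted UniFrac against enumeration and library oracles; permutation test."""

import io

import numpy as np
import pytest
from skbio import TreeNode
from skbio.diversity import beta_diversity

from _oracles import naive_weighted_unifrac
from denitcath.synthetic import gen_tip_abundances, gen_tree
from denitcath.unifrac import AbundanceTree, unifrac_significance, weighted_unifrac


def _abundance_tree(newick: str, counts):
    tree = TreeNode.read(io.StringIO(newick))
    return AbundanceTree(tree, counts), tree


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, balanced_four_tip_tree):
        counts = {"A": dict(a=3, b=1, c=2, d=4), "B": dict(a=3, b=1, c=2, d=4)}
        at = AbundanceTree(balanced_four_tip_tree, counts)
        assert weighted_unifrac(at, "A", "B") == pytest.approx(0.0)

    def test_two_tips_fully_segregated_is_one(self):
        at, _ = _abundance_tree(
            "(x:0.7,y:2.3);", {"A": dict(x=5, y=0), "B": dict(x=0, y=5)}
        )
        assert weighted_unifrac(at, "A", "B", normalized=True) == pytest.approx(1.0)

    def test_balanced_tree_matches_enumeration(self, balanced_four_tip_tree):
        counts = {"A": dict(a=2, b=2, c=0, d=0), "B": dict(a=0, b=0, c=2, d=2)}
        at = AbundanceTree(balanced_four_tip_tree, counts)
        for normalized in (True, False):
            assert weighted_unifrac(at, "A", "B", normalized) == pytest.approx(
                naive_weighted_unifrac(
                    balanced_four_tip_tree, counts["A"], counts["B"], normalized
                ),
                abs=1e-15,
            )

    def test_matches_enumeration_oracle_on_random_trees(self, rng):
        for trial in range(30):
            n_tips = int(rng.integers(3, 17))
            newick = gen_tree(n_tips, seed=int(rng.integers(2**31 - 1)))
            counts_df = gen_tip_abundances(
                [f"t{i + 1:02d}" for i in range(n_tips)],
                scenario="mixed", seed=int(rng.integers(2**31 - 1)),
            )
            counts = {c: counts_df[c].to_dict() for c in counts_df.columns}
            at, tree = _abundance_tree(newick, counts)
            for normalized in (True, False):
                ours = weighted_unifrac(at, "A", "B", normalized)
                oracle = naive_weighted_unifrac(
                    tree, counts["A"], counts["B"], normalized
                )
                assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_library_implementation(self, rng):
        """Cross-check against scikit-bio's independent weighted UniFrac."""
        n_tips = 10
        newick = gen_tree(n_tips, seed=77)
        tips = [f"t{i + 1:02d}" for i in range(n_tips)]
        counts_df = gen_tip_abundances(tips, scenario="mixed", seed=78)
        counts = {c: counts_df[c].to_dict() for c in counts_df.columns}
        at, tree = _abundance_tree(newick, counts)
        for normalized in (True, False):
            ref = beta_diversity(
                "weighted_unifrac",
                [list(counts_df["A"]), list(counts_df["B"])],
                ids=["A", "B"], taxa=tips, tree=tree, normalized=normalized,
            )["A", "B"]
            assert weighted_unifrac(at, "A", "B", normalized) == pytest.approx(
                float(ref), abs=1e-10
            )

    def test_invariant_to_scaling_one_sample(self, balanced_four_tip_tree):
        counts = {"A": dict(a=3, b=1, c=2, d=4), "B": dict(a=1, b=1, c=5, d=0)}
        scaled = {"A": counts["A"], "B": {k: 7 * v for k, v in counts["B"].items()}}
        u1 = weighted_unifrac(AbundanceTree(balanced_four_tip_tree, counts), "A", "B")
        u2 = weighted_unifrac(AbundanceTree(balanced_four_tip_tree, scaled), "A", "B")
        assert u1 == pytest.approx(u2)

    def test_symmetry_and_range(self, rng):
        newick = gen_tree(9, seed=5)
        counts_df = gen_tip_abundances(
            [f"t{i + 1:02d}" for i in range(9)], scenario="mixed", seed=6
        )
        counts = {c: counts_df[c].to_dict() for c in counts_df.columns}
        at, _ = _abundance_tree(newick, counts)
        u_ab = weighted_unifrac(at, "A", "B")
        u_ba = weighted_unifrac(at, "B", "A")
        assert u_ab == pytest.approx(u_ba)
        assert 0.0 <= u_ab <= 1.0

    def test_empty_sample_rejected(self, balanced_four_tip_tree):
        counts = {"A": dict(a=1, b=1, c=1, d=1), "B": dict(a=0, b=0, c=0, d=0)}
        at = AbundanceTree(balanced_four_tip_tree, counts)
        with pytest.raises(ValueError, match="total abundance"):
            weighted_unifrac(at, "A", "B")

    def test_missing_tip_entry_rejected(self, balanced_four_tip_tree):
        with pytest.raises(ValueError, match="lacks abundance"):
            AbundanceTree(balanced_four_tip_tree, {"A": dict(a=1, b=1, c=1)})


class TestSignificance:
    def test_identical_samples_p_near_one(self, balanced_four_tip_tree):
        counts = {"A": dict(a=5, b=5, c=5, d=5), "B": dict(a=5, b=5, c=5, d=5)}
        at = AbundanceTree(balanced_four_tip_tree, counts)
        res = unifrac_significance(at, "A", "B", n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1.0, abs=0.02)

    def test_fully_segregated_small_p(self):
        newick = gen_tree(10, seed=21)
        tips = [f"t{i + 1:02d}" for i in range(10)]
        counts_df = gen_tip_abundances(tips, scenario="disjoint", seed=22, total=100)
        counts = {c: counts_df[c].to_dict() for c in counts_df.columns}
        at, _ = _abundance_tree(newick, counts)
        res = unifrac_significance(at, "A", "B", n_permutations=999, seed=23)
        assert res.p_value <= 0.01

    def test_seed_reproducible(self, balanced_four_tip_tree):
        counts = {"A": dict(a=9, b=1, c=2, d=0), "B": dict(a=0, b=3, c=5, d=4)}
        at = AbundanceTree(balanced_four_tip_tree, counts)
        r1 = unifrac_significance(at, "A", "B", n_permutations=299, seed=7)
        r2 = unifrac_significance(at, "A", "B", n_permutations=299, seed=7)
        assert r1.p_value == r2.p_value

    def test_requires_minimum_permutations(self, balanced_four_tip_tree):
        counts = {"A": dict(a=1, b=1, c=1, d=1), "B": dict(a=1, b=1, c=1, d=1)}
        at = AbundanceTree(balanced_four_tip_tree, counts)
        with pytest.raises(ValueError):
            unifrac_significance(at, "A", "B", n_permutations=10)
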