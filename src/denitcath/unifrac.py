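"""Weighted UniFrac distances between communities on a shared rooted tree.

Weighted UniFrac compares two communities placed on the tips of one rooted
phylogeny: each branch contributes its length times the absolute difference
in the fraction of each community's sequences descending through it. The
normalised variant divides by the maximum attainable value (every branch
weighted by the sum of the two descendant fractions), so distances lie in
[0, 1]. Significance is assessed by permuting the community labels of
individual sequences and recomputing the distance.

Trees are consumed as rooted skbio ``TreeNode`` objects with branch lengths;
tip abundances are integer counts per sample. The tree's provenance
(nucleotide or amino-acid phylogeny) is irrelevant to the computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from skbio import TreeNode

__all__ = [
    "AbundanceTree",
    "UnifracResult",
    "weighted_unifrac",
    "unifrac_significance",
    "pairwise_unifrac",
]


@dataclass(frozen=True)
class UnifracResult:
    distance: float
    p_value: Optional[float]
    n_permutations: int


class AbundanceTree:
    """A rooted, branch-length-bearing tree plus per-sample tip counts.

    ``counts`` maps sample id -> {tip name: count}; every tree tip must have
    an entry (zero allowed) for every sample. Internally the tree is
    flattened to a branch table (length vector + tip-membership matrix) so
    distances and permutations are vector operations.
    """

    def __init__(self, tree: TreeNode, counts: Mapping[str, Mapping[str, float]]):
        self.tree = tree
        tips = [t.name for t in tree.tips()]
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip names in tree")
        self.tip_names: list[str] = tips
        self.samples: list[str] = list(counts)
        self._counts: dict[str, np.ndarray] = {}
        for sample, per_tip in counts.items():
            missing = [t for t in tips if t not in per_tip]
            if missing:
                raise ValueError(
                    f"sample {sample!r} lacks abundance entries for tip(s): "
                    + ", ".join(missing[:5])
                )
            vec = np.array([per_tip[t] for t in tips], dtype=float)
            if np.any(vec < 0):
                raise ValueError(f"negative abundance in sample {sample!r}")
            self._counts[sample] = vec
        self._lengths, self._membership = self._branch_table()

    def _branch_table(self) -> tuple[np.ndarray, np.ndarray]:
        tip_index = {name: i for i, name in enumerate(self.tip_names)}
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        for node in self.tree.postorder(include_self=False):
            length = node.length or 0.0
            if length < 0:
                raise ValueError("negative branch length in tree")
            row = np.zeros(len(self.tip_names))
            for tip in node.tips(include_self=True):
                row[tip_index[tip.name]] = 1.0
            lengths.append(length)
            rows.append(row)
        return np.array(lengths), np.array(rows)

    def counts_vector(self, sample: str) -> np.ndarray:
        try:
            return self._counts[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def _distance_from_vectors(
        self, ca: np.ndarray, cb: np.ndarray, normalized: bool
    ) -> float:
        ta, tb = ca.sum(), cb.sum()
        if ta <= 0 or tb <= 0:
            raise ValueError("both samples must have total abundance > 0")
        pa = self._membership @ (ca / ta)
        pb = self._membership @ (cb / tb)
        raw = float(self._lengths @ np.abs(pa - pb))
        if not normalized:
            return raw
        denom = float(self._lengths @ (pa + pb))
        if denom == 0:
            return 0.0
        return raw / denom


def weighted_unifrac(
    tree: AbundanceTree,
    sample_a: str,
    sample_b: str,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two samples on the shared tree.

    Raw form: sum over branches of length * |p_A - p_B| where p_X is the
    fraction of sample X's sequences descending through the branch.
    Normalised form divides by sum of length * (p_A + p_B), the value a
    fully segregated pair would attain, giving a distance in [0, 1].
    """
    return tree._distance_from_vectors(
        tree.counts_vector(sample_a), tree.counts_vector(sample_b), normalized
    )


def unifrac_significance(
    tree: AbundanceTree,
    sample_a: str,
    sample_b: str,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    normalized: bool = True,
) -> UnifracResult:
    """Permutation p-value for the observed weighted UniFrac distance.

    Each sequence keeps its tip but is randomly re-assigned a sample label
    (counts are expanded to individual sequences, labels permuted, counts
    re-aggregated). p = (1 + #{permuted >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    ca = tree.counts_vector(sample_a)
    cb = tree.counts_vector(sample_b)
    if np.any(ca != np.floor(ca)) or np.any(cb != np.floor(cb)):
        raise ValueError("permutation test requires integer sequence counts")
    observed = tree._distance_from_vectors(ca, cb, normalized)
    tips_per_seq = np.repeat(
        np.arange(ca.size), (ca + cb).astype(int)
    )  # tip index of every individual sequence
    n_a = int(ca.sum())
    rng = np.random.default_rng(seed)
    n_tips = ca.size
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(tips_per_seq.size)
        a_tips = tips_per_seq[perm[:n_a]]
        b_tips = tips_per_seq[perm[n_a:]]
        pa = np.bincount(a_tips, minlength=n_tips).astype(float)
        pb = np.bincount(b_tips, minlength=n_tips).astype(float)
        if tree._distance_from_vectors(pa, pb, normalized) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return UnifracResult(distance=observed, p_value=p, n_permutations=n_permutations)


def pairwise_unifrac(
    tree: AbundanceTree,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    normalized: bool = True,
) -> list[tuple[str, str, UnifracResult]]:
    """All pairwise distances (with p-values) among the tree's samples."""
    out = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(tree.samples):
        for b in tree.samples[i + 1 :]:
            sub_seed = int(rng.integers(2**31 - 1))
            out.append(
                (a, b, unifrac_significance(
                    tree, a, b, n_permutations=n_permutations,
                    seed=sub_seed, normalized=normalized,
                ))
            )
    return out
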