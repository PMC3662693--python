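"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by direct enumeration, sharing no code
path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode


def brute_force_furthest_neighbour(
    dm: DistanceMatrix, cutoff: float
) -> set[frozenset[str]]:
    """Furthest-neighbour agglomeration by exhaustive search over cluster
    pairs, recomputing every cluster-pair diameter by full enumeration at
    each step."""
    clusters: list[set[str]] = [{lab} for lab in dm.ids]
    while len(clusters) > 1:
        best_d, best_pair = np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dm[a, b] for a in clusters[i] for b in clusters[j])
                if d < best_d:
                    best_d, best_pair = d, (i, j)
        if best_d > cutoff:
            break
        i, j = best_pair
        clusters[i] |= clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def diameter_ok(dm: DistanceMatrix, blocks, cutoff: float) -> bool:
    """Every block's pairwise distances all within the cutoff."""
    for block in blocks:
        members = sorted(block)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if dm[a, b] > cutoff + 1e-12:
                    return False
    return True


def naive_weighted_unifrac(
    tree: TreeNode,
    counts_a: dict[str, float],
    counts_b: dict[str, float],
    normalized: bool = True,
) -> float:
    """Branch-by-branch enumeration: for every branch, list its descendant
    tips explicitly and accumulate length * |p_A - p_B|."""
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    raw = 0.0
    denom = 0.0
    for node in tree.postorder(include_self=False):
        tips = [t.name for t in node.tips(include_self=True)]
        pa = sum(counts_a[t] for t in tips) / total_a
        pb = sum(counts_b[t] for t in tips) / total_b
        length = node.length or 0.0
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    if not normalized:
        return raw
    return raw / denom if denom else 0.0


def monte_carlo_rarefaction(
    abundances, depth: int, n_draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and SE of observed richness over random subsamples without
    replacement."""
    pool = np.repeat(np.arange(len(abundances)), abundances)
    richness = np.empty(n_draws)
    for k in range(n_draws):
        picked = rng.choice(pool, size=depth, replace=False)
        richness[k] = np.unique(picked).size
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(n_draws))


def random_distance_matrix(
    n: int, rng: np.random.Generator, low: float = 0.0, high: float = 1.0
) -> DistanceMatrix:
    """Symmetric matrix of iid continuous distances (ties probability zero)."""
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(low, high, size=len(iu[0]))
    d[iu] = vals
    d += d.T
    return DistanceMatrix(d, ids=[f"s{i:02d}" for i in range(n)])
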