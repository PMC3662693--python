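"""OTU clustering at gene-specific cutoffs and alpha-diversity estimation.

Functional marker genes evolve at different rates, so the species-level
distance cutoff differs per gene (`GENE_CUTOFFS`). Sequences are grouped
into operational taxonomic units by furthest-neighbour (complete-linkage)
agglomeration: two sequences share an OTU only if every pairwise distance in
their cluster is at or below the cutoff. A cutoff for a new marker can be
derived from paired functional/16S distances via a through-origin
regression scaled to the 16S species cutoff.

Alpha diversity on the resulting abundance vectors: observed richness,
bias-corrected Chao1, Good's coverage, Shannon index (natural log) with its
large-sample variance, and exact (hypergeometric) rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import goods_coverage as _skbio_goods_coverage

__all__ = [
    "GENE_CUTOFFS",
    "OtuAssignment",
    "ShannonResult",
    "DiversitySummary",
    "cluster_otus",
    "derive_cutoff",
    "chao1",
    "goods_coverage",
    "shannon",
    "rarefaction",
    "diversity_summary",
]

#: species-level nucleotide distance cutoffs per denitrification marker
GENE_CUTOFFS: dict[str, float] = {
    "narG": 0.33,
    "napA": 0.21,
    "nirS": 0.18,
    "nirK": 0.17,
    "nosZ": 0.20,
}


@dataclass(frozen=True)
class OtuAssignment:
    """Result of clustering one distance matrix at one cutoff."""

    cutoff: float
    otus: tuple[frozenset[str], ...]  # ordered by decreasing size

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    @property
    def abundances(self) -> np.ndarray:
        return np.array([len(o) for o in self.otus], dtype=int)

    def label_of(self) -> dict[str, int]:
        return {lab: i for i, otu in enumerate(self.otus) for lab in otu}


def _as_distance_matrix(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        return dm
    raise TypeError("expected a skbio DistanceMatrix (see denitcath.io readers)")


def cluster_otus(dm: DistanceMatrix, cutoff: float) -> OtuAssignment:
    """Furthest-neighbour OTU clustering of a pairwise distance matrix.

    Complete-linkage agglomeration cut at ``cutoff``: merge heights in
    complete linkage equal cluster diameters, so every returned OTU has all
    pairwise distances <= cutoff. Labels are processed in lexicographic
    order so ties resolve deterministically; OTUs are returned largest
    first, ties broken by smallest member label.
    """
    dm = _as_distance_matrix(dm)
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    order = np.argsort(np.asarray(dm.ids))
    labels = [dm.ids[i] for i in order]
    data = dm.data[np.ix_(order, order)]
    if len(labels) == 1:
        return OtuAssignment(cutoff=cutoff, otus=(frozenset(labels),))
    z = linkage(squareform(data, checks=False), method="complete")
    flat = fcluster(z, t=cutoff, criterion="distance")
    groups: dict[int, set[str]] = {}
    for lab, cl in zip(labels, flat):
        groups.setdefault(int(cl), set()).add(lab)
    otus = sorted(groups.values(), key=lambda s: (-len(s), min(s)))
    return OtuAssignment(cutoff=cutoff, otus=tuple(frozenset(s) for s in otus))


def derive_cutoff(
    paired: Sequence[tuple[float, float]],
    species_cutoff_16s: float = 0.03,
) -> float:
    """Species-level cutoff for a functional gene from paired distances.

    ``paired`` holds (functional-gene distance, 16S distance) for genome
    pairs. A least-squares line through the origin gives the relative
    divergence rate; the functional cutoff is that slope times the 16S
    species cutoff, rounded to two decimals (the convention cutoff tables
    are printed at).
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired distances must be (d_functional, d_16S) tuples")
    if arr.shape[0] < 10:
        raise ValueError(f"need >= 10 genome pairs, got {arr.shape[0]}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("distances must lie in [0, 1]")
    d_func, d_16s = arr[:, 0], arr[:, 1]
    denom = float(np.dot(d_16s, d_16s))
    if denom == 0:
        raise ValueError("all 16S distances are zero; slope undefined")
    slope = float(np.dot(d_func, d_16s)) / denom
    return round(slope * species_cutoff_16s, 2)


def _counts(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if a.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(a < 1) or np.any(a != np.floor(a)):
        raise ValueError("abundances must be integer counts >= 1 per observed OTU")
    return a


def chao1(abundances) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_skbio_chao1(_counts(abundances).astype(int), bias_corrected=True))


def goods_coverage(abundances) -> float:
    """Good's coverage 1 - F1/n, the chance the next read is a seen OTU."""
    return float(_skbio_goods_coverage(_counts(abundances).astype(int)))


@dataclass(frozen=True)
class ShannonResult:
    h: float
    variance: float
    sd: float
    ci_low: float
    ci_high: float


def shannon(abundances, z: float = 1.96) -> ShannonResult:
    """Shannon index H' = -sum p_i ln p_i with its large-sample variance.

    var(H') = (sum p ln^2 p - H'^2)/n + (S-1)/(2 n^2); the CI is H' +/- z*SE
    clipped below at zero.
    """
    a = _counts(abundances)
    n = a.sum()
    p = a / n
    h = float(-(p * np.log(p)).sum())
    s = a.size
    var = float(((p * np.log(p) ** 2).sum() - h**2) / n + (s - 1) / (2 * n**2))
    var = max(var, 0.0)
    sd = var**0.5
    return ShannonResult(
        h=h, variance=var, sd=sd,
        ci_low=max(h - z * sd, 0.0), ci_high=h + z * sd,
    )


def rarefaction(abundances, depths) -> np.ndarray:
    """Exact expected richness at each subsampling depth.

    E[S_m] = S - sum_i C(n - n_i, m) / C(n, m), evaluated through log-gamma
    for numerical stability.
    """
    a = _counts(abundances)
    n = int(a.sum())
    m = np.atleast_1d(np.asarray(depths, dtype=int))
    if np.any(m < 0) or np.any(m > n):
        raise ValueError(f"depths must lie in [0, n={n}]")
    s = a.size
    out = np.empty(m.shape, dtype=float)
    log_cn = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    for j, mj in enumerate(m):
        rest = n - a  # per-OTU count of sequences outside that OTU
        ok = rest >= mj
        log_c = (
            gammaln(rest[ok] + 1) - gammaln(mj + 1) - gammaln(rest[ok] - mj + 1)
        )
        out[j] = s - float(np.exp(log_c - log_cn[j]).sum())
    return out


@dataclass(frozen=True)
class DiversitySummary:
    """The per-(gene, period) alpha-diversity row of a community table."""

    n: int
    s_obs: int
    s_chao1: float
    coverage_pct: float
    shannon: float
    shannon_sd: float
    f1: int
    f2: int


def diversity_summary(abundances) -> DiversitySummary:
    a = _counts(abundances).astype(int)
    sh = shannon(a)
    return DiversitySummary(
        n=int(a.sum()),
        s_obs=int(a.size),
        s_chao1=chao1(a),
        coverage_pct=100.0 * goods_coverage(a),
        shannon=sh.h,
        shannon_sd=sh.sd,
        f1=int((a == 1).sum()),
        f2=int((a == 2).sum()),
    )
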