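"""Group comparison with a normality gate, and ratio-emission correlation.

Gene abundances and ratios are compared across feeding periods with the
classical decision path: optional log10 transform, Shapiro-Wilk normality
per group and Levene homogeneity of variance at alpha = 0.05; if both hold,
one-way ANOVA with Tukey HSD pairwise letters, otherwise Kruskal-Wallis.
Associations (e.g. the nitrite-to-nitrous-oxide reductase ratio against N2O
accumulation) use the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "CorrelationResult", "compare_periods", "correlate"]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test_used: str  # "anova_tukey" | "kruskal_wallis"
    statistic: float
    p_value: float
    shapiro_p: dict[str, Optional[float]]  # None when a group is untestable
    levene_p: Optional[float]
    letters: Optional[dict[str, str]]  # compact letter display (ANOVA path)
    pairwise_p: Optional[dict[tuple[str, str], float]]
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    r: float
    r2: float
    p_value: float
    n: int


def _compact_letters(
    groups: Sequence[str],
    means: Mapping[str, float],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise p-values."""

    def differs(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))
        return p < alpha

    ordered = sorted(groups, key=lambda g: -means[g])
    classes: list[set[str]] = []
    for g in ordered:
        placed = False
        for cls in classes:
            if all(not differs(g, member) for member in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    # absorb classes fully contained in another
    classes = [
        c for i, c in enumerate(classes)
        if not any(i != j and c < other for j, other in enumerate(classes))
    ]
    letters = {g: "" for g in groups}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def compare_periods(
    values_by_group: Mapping[str, Sequence[float]],
    log_transform: bool = False,
    variable: str = "",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare one variable across feeding periods.

    The parametric path (one-way ANOVA + Tukey HSD) is taken only when every
    group passes Shapiro-Wilk at ``alpha`` and Levene's test finds
    homogeneous variances; otherwise Kruskal-Wallis. Groups too small for
    Shapiro-Wilk (n < 3) or with zero variance route non-parametric, with a
    note recording why.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays: dict[str, np.ndarray] = {}
    for name in names:
        arr = np.asarray(values_by_group[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if log_transform:
            if np.any(arr <= 0):
                raise ValueError(
                    f"group {name!r}: log transform requires positive values"
                )
            arr = np.log10(arr)
        arrays[name] = arr

    notes: list[str] = []
    shapiro_p: dict[str, Optional[float]] = {}
    normal = True
    for name, arr in arrays.items():
        if arr.size < 3:
            shapiro_p[name] = None
            normal = False
            notes.append(f"group {name!r}: n < 3, normality untestable")
        elif np.ptp(arr) == 0:
            shapiro_p[name] = None
            normal = False
            notes.append(f"group {name!r}: zero variance")
        else:
            p = float(stats.shapiro(arr).pvalue)
            shapiro_p[name] = p
            if p < alpha:
                normal = False

    levene_p: Optional[float] = None
    if normal:
        levene_p = float(stats.levene(*arrays.values()).pvalue)
        if np.isnan(levene_p):  # all groups constant and equal
            levene_p = 1.0

    samples = [arrays[n] for n in names]
    if normal and levene_p >= alpha:
        anova = stats.f_oneway(*samples)
        statistic, p_value = float(anova.statistic), float(anova.pvalue)
        if np.isnan(statistic):  # zero between- and within-group variance
            statistic, p_value = 0.0, 1.0
        hsd = stats.tukey_hsd(*samples)
        pairwise = {
            (names[i], names[j]): float(hsd.pvalue[i, j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
        means = {n: float(arrays[n].mean()) for n in names}
        letters = _compact_letters(names, means, pairwise, alpha)
        return ComparisonResult(
            variable=variable, test_used="anova_tukey",
            statistic=statistic, p_value=p_value,
            shapiro_p=shapiro_p, levene_p=levene_p,
            letters=letters, pairwise_p=pairwise, notes=tuple(notes),
        )

    flat = np.concatenate(samples)
    if np.ptp(flat) == 0:  # all observations identical: no evidence of difference
        statistic, p_value = 0.0, 1.0
    else:
        kw = stats.kruskal(*samples)
        statistic, p_value = float(kw.statistic), float(kw.pvalue)
    return ComparisonResult(
        variable=variable, test_used="kruskal_wallis",
        statistic=statistic, p_value=p_value,
        shapiro_p=shapiro_p, levene_p=levene_p,
        letters=None, pairwise_p=None, notes=tuple(notes),
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Pearson correlation of two equally long series (n >= 3)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    res = stats.pearsonr(xa, ya)
    r = float(res.statistic)
    return CorrelationResult(
        x=x_name, y=y_name, r=r, r2=r * r,
        p_value=float(res.pvalue), n=int(xa.size),
    )
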