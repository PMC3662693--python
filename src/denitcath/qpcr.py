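"""qPCR standard-curve calibration, absolute quantification and gene ratios.

Absolute quantification follows the standard-curve method: serial plasmid
dilutions of known copy number give a straight line Ct = a + b*log10(copies),
the amplification efficiency E = 10^(-1/b) - 1 (b = -3.32 cycles/decade at
perfect doubling), and an unknown sample's copy number is read off the line
from its Ct and normalised by template mass.

Community-level interpretation uses ratio proxies: each denitrification
marker gene (narG, napA, nirS, nirK, nosZ) relative to the 16S rRNA gene
(reported x100), and between-step ratios such as (qnirS+qnirK)/qnosZ, the
nitrite-reductase to nitrous-oxide-reductase balance that tracks the
potential for N2O accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StdCurve",
    "Quantification",
    "GeneRatioSet",
    "RATIO_GENES",
    "fit_standard_curve",
    "efficiency_from_slope",
    "quantify",
    "inhibition_shift",
    "average_replicates",
    "gene_ratios",
]

#: genes required by :func:`gene_ratios` (``"16S"`` is the normaliser)
RATIO_GENES = ("narG", "napA", "nirS", "nirK", "nosZ", "16S")

#: standards below r^2 = 0.98 are flagged for inspection but still usable
R2_FLAG_THRESHOLD = 0.98


@dataclass(frozen=True)
class StdCurve:
    """Calibration line Ct = intercept + slope * log10(copies)."""

    gene: str
    slope: float  # cycles per decade; negative for a valid curve
    intercept: float  # Ct at a single copy
    r2: float
    ct_min: float  # calibrated Ct range (Ct at the highest standard)
    ct_max: float  # Ct at the lowest standard

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification gain E, as a fraction (1.0 = doubling)."""
        return efficiency_from_slope(self.slope)

    @property
    def low_r2(self) -> bool:
        return self.r2 < R2_FLAG_THRESHOLD


@dataclass(frozen=True)
class Quantification:
    gene: str
    sample_id: str
    copies_per_ng: float
    ct: float
    out_of_range: bool  # Ct outside the calibrated span of the curve


def efficiency_from_slope(slope: float) -> float:
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    dilution_copies: Sequence[float],
    cts: Sequence[float],
    gene: str = "",
) -> StdCurve:
    """Least-squares calibration of Ct against log10(copies per reaction)."""
    copies = np.asarray(dilution_copies, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if copies.shape != ct.shape or copies.ndim != 1:
        raise ValueError("dilution copies and Ct values must be equal-length 1-D")
    if copies.size < 3:
        raise ValueError(f"need >= 3 dilution points, got {copies.size}")
    if np.any(copies <= 0):
        raise ValueError("all standard copy numbers must be positive")
    fit = stats.linregress(np.log10(copies), ct)
    if fit.slope >= 0:
        raise ValueError(
            f"invalid standard curve for {gene or 'gene'}: slope "
            f"{fit.slope:.3f} >= 0 (Ct must decrease with template)"
        )
    return StdCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        ct_min=float(ct.min()),
        ct_max=float(ct.max()),
    )


def quantify(
    ct: float,
    curve: StdCurve,
    dna_ng: float,
    sample_id: str = "",
) -> Quantification:
    """Copies per ng template DNA read off the standard curve.

    A Ct outside the calibrated range is extrapolated but flagged.
    """
    if dna_ng <= 0:
        raise ValueError(f"template mass must be positive, got {dna_ng} ng")
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    out = not (curve.ct_min <= ct <= curve.ct_max)
    return Quantification(
        gene=curve.gene,
        sample_id=sample_id,
        copies_per_ng=copies / dna_ng,
        ct=float(ct),
        out_of_range=out,
    )


def inhibition_shift(
    ct_plasmid_alone: float,
    ct_plasmid_mixed: float,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Ct shift of a spiked plasmid when co-amplified with sample DNA.

    Returns ``(shift, flagged)``; a shift beyond ``threshold`` cycles marks
    probable PCR inhibition by the sample matrix.
    """
    if ct_plasmid_alone <= 0 or ct_plasmid_mixed <= 0:
        raise ValueError("Ct values must be positive")
    shift = ct_plasmid_mixed - ct_plasmid_alone
    return shift, abs(shift) > threshold


def average_replicates(cts: Sequence[float]) -> tuple[float, float]:
    """Mean and SD of replicate Ct values (SD 0.0 for a single replicate)."""
    ct = np.asarray(cts, dtype=float)
    if ct.size == 0:
        raise ValueError("no replicate Ct values supplied")
    sd = float(ct.std(ddof=1)) if ct.size > 1 else 0.0
    return float(ct.mean()), sd


@dataclass(frozen=True)
class GeneRatioSet:
    """The eight abundance-ratio proxies for one sample/period.

    The five per-16S ratios carry the x100 reporting convention; the three
    gene-to-gene ratios are plain.
    """

    narg_16s: float
    napa_16s: float
    nirs_16s: float
    nirk_16s: float
    nosz_16s: float
    nar_nap_over_nosz: float
    nar_nap_over_nir: float
    nir_over_nosz: float

    def as_dict(self) -> dict[str, float]:
        return {
            "qnarG/q16S (x100)": self.narg_16s,
            "qnapA/q16S (x100)": self.napa_16s,
            "qnirS/q16S (x100)": self.nirs_16s,
            "qnirK/q16S (x100)": self.nirk_16s,
            "qnosZ/q16S (x100)": self.nosz_16s,
            "(qnarG+qnapA)/qnosZ": self.nar_nap_over_nosz,
            "(qnarG+qnapA)/(qnirS+qnirK)": self.nar_nap_over_nir,
            "(qnirK+qnirS)/qnosZ": self.nir_over_nosz,
        }


def gene_ratios(abundances: Mapping[str, float]) -> GeneRatioSet:
    """Ratio proxies from per-gene copy numbers (any common unit).

    Requires all of narG, napA, nirS, nirK, nosZ and 16S at positive
    abundance; ratios are invariant to rescaling all genes by one factor.
    """
    missing = [g for g in RATIO_GENES if g not in abundances]
    if missing:
        raise ValueError("missing gene abundance(s): " + ", ".join(missing))
    bad = [g for g in RATIO_GENES if not abundances[g] > 0]
    if bad:
        raise ValueError("non-positive gene abundance(s): " + ", ".join(bad))
    narg, napa = abundances["narG"], abundances["napA"]
    nirs, nirk = abundances["nirS"], abundances["nirK"]
    nosz, sixteen_s = abundances["nosZ"], abundances["16S"]
    return GeneRatioSet(
        narg_16s=100.0 * narg / sixteen_s,
        napa_16s=100.0 * napa / sixteen_s,
        nirs_16s=100.0 * nirs / sixteen_s,
        nirk_16s=100.0 * nirk / sixteen_s,
        nosz_16s=100.0 * nosz / sixteen_s,
        nar_nap_over_nosz=(narg + napa) / nosz,
        nar_nap_over_nir=(narg + napa) / (nirs + nirk),
        nir_over_nosz=(nirk + nirs) / nosz,
    )
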