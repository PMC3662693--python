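"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input class the analysis consumes can be generated here, seeded and
byte-reproducible:

* chemistry tables — Gaussian steady-state operating chemistry (truncated at
  zero) around per-period means and SDs; the defaults are the three feeding
  regimes of the study system (autotrophic nitrate, heterotrophic nitrate,
  autotrophic nitrite);
* qPCR run tables — standard-curve dilution series (1e2..1e9 copies per
  reaction) and sample wells, with Ct values from a log-linear curve at a
  chosen amplification efficiency plus Gaussian Ct noise;
* planted communities — multinomial OTU abundance vectors (including the
  strongly dominant regime seen for nosZ, ~90% of sequences in one OTU)
  with companion distance matrices built so furthest-neighbour clustering
  at the gene cutoff recovers the planted partition exactly;
* random rooted trees with exponential branch lengths and per-sample tip
  counts, feeding the UniFrac stage.

Distance matrices are generated directly from a two-regime distance model
(within-OTU below the cutoff, between-OTU above it) rather than by
simulating sequence evolution: the clustering operation, not the distance
estimator, is the unit under test downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import GENE_CUTOFFS

__all__ = [
    "PeriodSpec",
    "STUDY_PERIODS",
    "DEFAULT_GENE_ABUNDANCES",
    "DEFAULT_COMMUNITY_FREQS",
    "PlantedCommunity",
    "gen_chemistry",
    "gen_community",
    "gen_qpcr",
    "gen_tree",
    "gen_tip_abundances",
    "simulate_fixture_set",
]


@dataclass(frozen=True)
class PeriodSpec:
    """Mean/SD operating chemistry for one feeding regime.

    Each chemistry field is ``(mean, sd)`` in mg/L (flow in L/day, current
    density in A/m^3 NCC); ``None`` encodes a species not detected in that
    regime.
    """

    period_id: str
    regime: str
    flow: tuple[float, float]
    cod_in: Optional[tuple[float, float]]
    cod_out: Optional[tuple[float, float]]
    no3_in: tuple[float, float]
    no3_out: tuple[float, float]
    no2_in: tuple[float, float]
    no2_out: tuple[float, float]
    n2o_out: tuple[float, float]
    current_density: tuple[float, float]
    ncc_volume: float = 145e-6


#: the three steady-state feeding regimes of the study system
STUDY_PERIODS: tuple[PeriodSpec, ...] = (
    PeriodSpec(
        period_id="period1", regime="autotrophic_nitrate",
        flow=(2.0, 0.3), cod_in=None, cod_out=None,
        no3_in=(26.6, 1.3), no3_out=(22.6, 0.3),
        no2_in=(0.3, 0.2), no2_out=(0.2, 0.1),
        n2o_out=(0.6, 0.2), current_density=(15.0, 2.3),
    ),
    PeriodSpec(
        period_id="period2", regime="heterotrophic_nitrate",
        flow=(1.4, 0.5), cod_in=(64.0, 21.0), cod_out=(31.0, 22.0),
        no3_in=(29.6, 5.3), no3_out=(20.7, 4.8),
        no2_in=(1.0, 0.4), no2_out=(2.1, 3.4),
        n2o_out=(4.0, 1.9), current_density=(11.0, 7.0),
    ),
    PeriodSpec(
        period_id="period3", regime="autotrophic_nitrite",
        flow=(1.2, 0.2), cod_in=None, cod_out=None,
        no3_in=(2.9, 4.7), no3_out=(0.0, 0.2),
        no2_in=(20.3, 1.7), no2_out=(4.6, 4.8),
        n2o_out=(13.0, 5.9), current_density=(14.1, 8.2),
    ),
)

#: per-period true copies/ng for the qPCR fixture: 16S at the observed
#: order of magnitude, marker genes set from the reported ratio proxies
DEFAULT_GENE_ABUNDANCES: dict[str, dict[str, float]] = {
    "period1": {
        "16S": 3.5e6, "narG": 1.4e4, "napA": 1.75e4,
        "nirS": 1.47e6, "nirK": 1.75e4, "nosZ": 1.89e5,
    },
    "period2": {
        "16S": 2.0e6, "narG": 4.0e3, "napA": 8.0e3,
        "nirS": 1.80e6, "nirK": 2.0e4, "nosZ": 5.6e4,
    },
    "period3": {
        "16S": 4.0e6, "narG": 4.0e3, "napA": 4.0e3,
        "nirS": 2.09e6, "nirK": 1.2e4, "nosZ": 1.68e5,
    },
}

#: planted OTU frequency vectors per (gene, period); richness and evenness
#: chosen to mimic the observed communities (nosZ ~90% in one OTU, nirS the
#: richest and most even, narG few OTUs with one or two dominants)
DEFAULT_COMMUNITY_FREQS: dict[str, dict[str, tuple[float, ...]]] = {
    "narG": {
        "period1": (0.72, 0.14, 0.08, 0.06),
        "period2": (0.45, 0.30, 0.15, 0.06, 0.04),
        "period3": (0.80, 0.10, 0.06, 0.04),
    },
    "napA": {
        "period1": (0.4, 0.25, 0.15, 0.1, 0.1),
        "period2": (0.5, 0.3, 0.1, 0.1),
        "period3": (0.6, 0.25, 0.15),
    },
    "nirS": {
        "period1": (0.18, 0.15, 0.12, 0.10, 0.09, 0.08, 0.07, 0.05,
                    0.05, 0.04, 0.03, 0.02, 0.005, 0.005, 0.005, 0.005),
        "period2": (0.20, 0.16, 0.13, 0.11, 0.09, 0.08, 0.07, 0.05,
                    0.04, 0.03, 0.02, 0.01, 0.005, 0.005),
        "period3": (0.16, 0.14, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05,
                    0.04, 0.03, 0.02, 0.01, 0.01, 0.005, 0.005, 0.005, 0.005),
    },
    "nirK": {
        "period1": (0.40, 0.30, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01, 0.01),
        "period2": (0.18, 0.14, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05,
                    0.04, 0.03, 0.02, 0.01, 0.01),
        "period3": (0.45, 0.35, 0.06, 0.05, 0.04, 0.03, 0.02),
    },
    "nosZ": {
        "period1": (0.90, 0.05, 0.03, 0.02),
        "period2": (0.88, 0.06, 0.03, 0.02, 0.01),
        "period3": (0.90, 0.06, 0.04),
    },
}

CHEMISTRY_COLUMNS = [
    "period_id", "regime", "flow_l_per_d", "cod_in", "cod_out",
    "no3_in", "no3_out", "no2_in", "no2_out", "n2o_out", "n2_out",
    "current_density_a_per_m3", "ncc_volume_m3",
]

QPCR_COLUMNS = ["gene", "sample_id", "role", "copies", "ct", "dna_ng"]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gaussian draws redrawn until non-negative (concentrations, flows)."""
    if sd < 0:
        raise ValueError("SD must be >= 0")
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    while np.any(out < 0):
        bad = out < 0
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def gen_chemistry(
    specs: Sequence[PeriodSpec] = STUDY_PERIODS,
    n_samples: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw steady-state chemistry rows for each period spec.

    Returns one row per (period, replicate sample) in the canonical
    chemistry schema; undetected species stay missing (NaN, written as
    "n.d." by the CSV writer). With ``n_samples=1`` the table is a direct
    stand-in for a per-period operating table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        draws: dict[str, np.ndarray] = {}
        for name in ("flow", "no3_in", "no3_out", "no2_in", "no2_out",
                     "n2o_out", "cod_in", "cod_out", "current_density"):
            pair = getattr(spec, name)
            draws[name] = (
                np.full(n_samples, np.nan) if pair is None
                else _truncated_normal(rng, pair[0], pair[1], n_samples)
            )
        for k in range(n_samples):
            rows.append({
                "period_id": spec.period_id if n_samples == 1
                else f"{spec.period_id}_s{k + 1:03d}",
                "regime": spec.regime,
                "flow_l_per_d": draws["flow"][k],
                "cod_in": draws["cod_in"][k],
                "cod_out": draws["cod_out"][k],
                "no3_in": draws["no3_in"][k],
                "no3_out": draws["no3_out"][k],
                "no2_in": draws["no2_in"][k],
                "no2_out": draws["no2_out"][k],
                "n2o_out": draws["n2o_out"][k],
                "n2_out": np.nan,
                "current_density_a_per_m3": draws["current_density"][k],
                "ncc_volume_m3": spec.ncc_volume,
            })
    return pd.DataFrame(rows, columns=CHEMISTRY_COLUMNS)


@dataclass(frozen=True)
class PlantedCommunity:
    """A multinomial community draw plus a distance matrix that encodes it."""

    gene: str
    cutoff: float
    counts: np.ndarray  # per planted OTU, zeros dropped
    distance_matrix: DistanceMatrix
    assignment: dict[str, int]  # sequence label -> planted OTU index


def gen_community(
    otu_freqs: Sequence[float],
    n_seqs: int,
    seed: Optional[int] = None,
    cutoff: float = 0.20,
    gene: str = "",
    label_prefix: str = "seq",
) -> PlantedCommunity:
    """Multinomial community and a matching two-regime distance matrix.

    Within-OTU distances are drawn in (0.1, 0.8) x cutoff and between-OTU
    distances in (1.3, 2.4) x cutoff (capped at 1), so complete-linkage
    clustering at ``cutoff`` provably returns the planted partition.
    """
    freqs = np.asarray(otu_freqs, dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError(f"OTU frequencies must sum to 1, got {freqs.sum():.4f}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_seqs, freqs)
    otu_of = np.repeat(np.arange(freqs.size), counts)
    n = int(otu_of.size)
    labels = [f"{label_prefix}{i + 1:04d}" for i in range(n)]
    d = np.zeros((n, n))
    lo_w, hi_w = 0.1 * cutoff, 0.8 * cutoff
    lo_b, hi_b = 1.3 * cutoff, min(2.4 * cutoff, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            same = otu_of[i] == otu_of[j]
            d[i, j] = d[j, i] = (
                rng.uniform(lo_w, hi_w) if same else rng.uniform(lo_b, hi_b)
            )
    dm = DistanceMatrix(d, ids=labels)
    return PlantedCommunity(
        gene=gene,
        cutoff=cutoff,
        counts=counts[counts > 0],
        distance_matrix=dm,
        assignment={lab: int(o) for lab, o in zip(labels, otu_of)},
    )


def slope_from_efficiency(efficiency: float) -> float:
    """Standard-curve slope (cycles per decade) at amplification gain E."""
    if not 0.5 < efficiency <= 1.2:
        raise ValueError(f"efficiency outside plausible range: {efficiency}")
    return -1.0 / np.log10(1.0 + efficiency)


def gen_qpcr(
    sample_copies: Mapping[str, Mapping[str, float]],
    efficiency: float = 1.0,
    sigma_ct: float = 0.1,
    seed: Optional[int] = None,
    dilutions: Sequence[float] = tuple(10.0**k for k in range(2, 10)),
    intercept: float = 38.0,
    dna_ng: float = 10.0,
    replicates: int = 2,
) -> pd.DataFrame:
    """qPCR run table: standards per gene plus replicated sample wells.

    ``sample_copies`` maps gene -> {sample_id: true copies per ng}. Ct values
    follow Ct = intercept + slope * log10(copies per reaction) + N(0, sigma)
    with slope fixed by the amplification efficiency. Includes an
    inhibition-test pair per sample (plasmid alone vs spiked into sample).
    """
    rng = np.random.default_rng(seed)
    slope = slope_from_efficiency(efficiency)

    def ct_of(copies: float) -> float:
        return intercept + slope * np.log10(copies) + rng.normal(0.0, sigma_ct)

    rows = []
    sample_ids = sorted({s for per in sample_copies.values() for s in per})
    for gene in sorted(sample_copies):
        for copies in dilutions:
            rows.append({
                "gene": gene, "sample_id": "std", "role": "standard",
                "copies": copies, "ct": ct_of(copies), "dna_ng": np.nan,
            })
        for sample_id in sorted(sample_copies[gene]):
            per_ng = sample_copies[gene][sample_id]
            for _ in range(replicates):
                rows.append({
                    "gene": gene, "sample_id": sample_id, "role": "sample",
                    "copies": np.nan, "ct": ct_of(per_ng * dna_ng),
                    "dna_ng": dna_ng,
                })
    plasmid_copies = 1e5
    for sample_id in sample_ids:
        base = ct_of(plasmid_copies)
        rows.append({
            "gene": "plasmid", "sample_id": sample_id,
            "role": "inhibition_alone", "copies": plasmid_copies,
            "ct": base, "dna_ng": np.nan,
        })
        rows.append({
            "gene": "plasmid", "sample_id": sample_id,
            "role": "inhibition_mixed", "copies": plasmid_copies,
            "ct": base + rng.normal(0.08, 0.05), "dna_ng": dna_ng,
        })
    return pd.DataFrame(rows, columns=QPCR_COLUMNS)


def gen_tree(n_tips: int, seed: Optional[int] = None) -> str:
    """Random rooted bifurcating tree as a newick string.

    Built by random pairwise joining with Exp(1) branch lengths; tip names
    t01, t02, ... Deterministic for a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_tips)))
    subtrees = [f"t{i + 1:0{width}d}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl_l, bl_r = rng.exponential(1.0, size=2)
        subtrees.append(f"({left}:{bl_l:.6f},{right}:{bl_r:.6f})")
    return subtrees[0] + ";"


def gen_tip_abundances(
    tip_names: Sequence[str],
    scenario: str,
    seed: Optional[int] = None,
    total: int = 50,
) -> pd.DataFrame:
    """Two-sample tip count table under a named scenario.

    ``identical``: both samples share one multinomial draw (distance 0);
    ``disjoint``: the samples occupy complementary halves of the tips
    (maximal segregation); ``mixed``: independent draws from independent
    Dirichlet tip frequencies.
    """
    tips = list(tip_names)
    rng = np.random.default_rng(seed)
    n = len(tips)
    if scenario == "identical":
        counts = rng.multinomial(total, np.full(n, 1.0 / n))
        a, b = counts, counts.copy()
    elif scenario == "disjoint":
        half = n // 2
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:half] = rng.multinomial(total, np.full(half, 1.0 / half))
        b[half:] = rng.multinomial(total, np.full(n - half, 1.0 / (n - half)))
    elif scenario == "mixed":
        a = rng.multinomial(total, rng.dirichlet(np.ones(n)))
        b = rng.multinomial(total, rng.dirichlet(np.ones(n)))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return pd.DataFrame({"A": a, "B": b}, index=pd.Index(tips, name="tip"))


def simulate_fixture_set(
    outdir,
    seed: int,
    n_chem_samples: int = 1,
    n_seqs: int = 50,
    tree_tips: int = 12,
    genes: Sequence[str] = ("narG", "napA", "nirS", "nirK", "nosZ"),
) -> dict[str, object]:
    """Write a complete, self-consistent input set for the whole pipeline.

    One master seed spawns independent, deterministic substreams per file:
    chemistry CSV, qPCR CSV, one distance matrix per (gene, period), and one
    tree + per-period tip-count table per gene. Returns the manifest of
    written paths.
    """
    from pathlib import Path

    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(4)
    chem_seed, qpcr_seed, comm_ss, tree_ss = (
        int(streams[0].generate_state(1)[0] % (2**31 - 1)),
        int(streams[1].generate_state(1)[0] % (2**31 - 1)),
        streams[2], streams[3],
    )
    manifest: dict[str, object] = {"seed": seed}

    chem = gen_chemistry(STUDY_PERIODS, n_samples=n_chem_samples, seed=chem_seed)
    chem_path = outdir / "chemistry.csv"
    dio.write_chemistry(chem, chem_path)
    manifest["chemistry"] = chem_path

    qpcr = gen_qpcr(
        {g: {p: DEFAULT_GENE_ABUNDANCES[p][g] for p in DEFAULT_GENE_ABUNDANCES}
         for g in list(genes) + ["16S"]},
        efficiency=0.95, sigma_ct=0.05, seed=qpcr_seed,
    )
    qpcr_path = outdir / "qpcr_runs.csv"
    qpcr.to_csv(qpcr_path, index=False, float_format="%.6f")
    manifest["qpcr"] = qpcr_path

    periods = [s.period_id for s in STUDY_PERIODS]
    comm_streams = iter(comm_ss.spawn(len(genes) * len(periods)))
    dist_paths: dict[tuple[str, str], object] = {}
    for gene in genes:
        for period in periods:
            sub = int(next(comm_streams).generate_state(1)[0] % (2**31 - 1))
            planted = gen_community(
                DEFAULT_COMMUNITY_FREQS[gene][period], n_seqs, seed=sub,
                cutoff=GENE_CUTOFFS[gene], gene=gene,
                label_prefix=f"{gene}_{period}_",
            )
            path = outdir / f"{gene}_{period}.dist"
            dio.write_distance_matrix(planted.distance_matrix, path)
            dist_paths[(gene, period)] = path
    manifest["distances"] = dist_paths

    tree_streams = iter(tree_ss.spawn(2 * len(genes)))
    tree_paths: dict[str, object] = {}
    counts_paths: dict[str, object] = {}
    for gene in genes:
        t_seed = int(next(tree_streams).generate_state(1)[0] % (2**31 - 1))
        a_seed = int(next(tree_streams).generate_state(1)[0] % (2**31 - 1))
        newick = gen_tree(tree_tips, seed=t_seed)
        tree_path = outdir / f"{gene}.nwk"
        tree_path.write_text(newick + "\n")
        rng = np.random.default_rng(a_seed)
        width = max(2, len(str(tree_tips)))
        tips = [f"t{i + 1:0{width}d}" for i in range(tree_tips)]
        counts = pd.DataFrame(index=pd.Index(tips, name="tip"))
        for period in periods:
            counts[period] = rng.multinomial(
                n_seqs, rng.dirichlet(np.ones(tree_tips))
            )
        counts_path = outdir / f"{gene}_counts.tsv"
        counts.to_csv(counts_path, sep="\t")
        tree_paths[gene] = tree_path
        counts_paths[gene] = counts_path
    manifest["trees"] = tree_paths
    manifest["tip_counts"] = counts_paths
    return manifest
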