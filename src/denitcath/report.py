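"""Umbrella pipeline: one call from raw inputs to the four summary tables.

The `report` stage mirrors how the study system is summarised: a per-period
performance/balance table (loads, N2O/N2 split by closure, Coulombic
efficiency, shares), a gene-ratio table from the qPCR runs, an alpha
diversity table per (gene, period) community, and a pairwise weighted
UniFrac table per gene. Each stage failure is re-raised naming the stage.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import qpcr as dq
from . import stoichiometry as st
from .community import GENE_CUTOFFS, cluster_otus, diversity_summary
from .io import RunConfig
from .unifrac import AbundanceTree, pairwise_unifrac

__all__ = [
    "StageError",
    "config_from_manifest",
    "balance_table",
    "ratio_table",
    "diversity_table",
    "unifrac_table",
    "report",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def config_from_manifest(
    manifest: dict,
    outdir,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RunConfig:
    """Build a RunConfig from a ``simulate_fixture_set`` manifest."""
    genes = sorted({g for g, _ in manifest.get("distances", {})})
    return RunConfig(
        chemistry=str(manifest["chemistry"]),
        qpcr=str(manifest["qpcr"]) if "qpcr" in manifest else None,
        distances={
            g: {
                p: str(v)
                for (gg, p), v in manifest["distances"].items()
                if gg == g
            }
            for g in genes
        },
        trees={g: str(v) for g, v in manifest.get("trees", {}).items()},
        tip_counts={g: str(v) for g, v in manifest.get("tip_counts", {}).items()},
        n_permutations=n_permutations,
        seed=seed,
        outdir=str(outdir),
    )


def balance_table(periods: Sequence[st.OperatingPeriod]) -> pd.DataFrame:
    """Per-period nitrogen loads, closure-based N2O/N2 split, CE and shares.

    Noisy replicate chemistry can be momentarily inconsistent (drawn N2O
    above the removed nitrogen, or no net removal at all); such rows keep
    their loads but report a capped N2O (flagged) or NaN gas columns rather
    than aborting the whole table.
    """
    rows = []
    for p in periods:
        partial = st.nitrogen_removed(p)
        removed_conc = partial.removed_concentration
        n2o = p.n2o_out if p.n2o_out is not None else 0.0
        n2o_capped = False
        gas_cols = {
            "n2o_mg_n_per_l": np.nan, "n2_mg_n_per_l": np.nan,
            "n2o_share_removed_pct": np.nan, "n2o_share_gas_pct": np.nan,
            "electron_supply_mol_per_d": np.nan,
            "electron_demand_mol_per_d": np.nan,
            "coulombic_efficiency_pct": np.nan,
        }
        if removed_conc > 0:
            if n2o > removed_conc:
                n2o, n2o_capped = removed_conc, True
            balance = st.close_balance(p, n2o)
            gas = balance.delta_n2o + balance.delta_n2
            gas_cols["n2o_mg_n_per_l"] = n2o
            gas_cols["n2_mg_n_per_l"] = balance.delta_n2 / p.flow
            gas_cols["n2o_share_removed_pct"] = st.n2o_share(
                balance.delta_n2o, balance.removed_n
            )
            gas_cols["n2o_share_gas_pct"] = (
                100.0 * balance.delta_n2o / gas if gas > 0 else 0.0
            )
            if p.current_density is not None:
                supply = st.electron_supply(
                    st.current_from_density(p.current_density, p.ncc_volume)
                )
                demand = sum(st.electron_demand(balance).values())
                gas_cols["electron_supply_mol_per_d"] = supply
                gas_cols["electron_demand_mol_per_d"] = demand
                if demand > 0:
                    gas_cols["coulombic_efficiency_pct"] = (
                        st.coulombic_efficiency(supply, demand)
                    )
        rows.append({
            "period_id": p.period_id,
            "regime": p.regime,
            "flow_l_per_d": p.flow,
            "delta_no3_mg_n_per_d": partial.delta_no3,
            "delta_no2_mg_n_per_d": partial.delta_no2,
            "removed_mg_n_per_d": partial.removed_n,
            "removed_mg_n_per_l": removed_conc,
            **gas_cols,
            "n2o_capped": n2o_capped,
            "current_density_a_per_m3": p.current_density,
        })
    return pd.DataFrame(rows)


def ratio_table(qpcr_runs: pd.DataFrame) -> pd.DataFrame:
    """Standard curves -> absolute abundances -> the eight ratio proxies.

    Replicate sample Cts are averaged before quantification. Returns one
    row per sample with per-gene copies/ng, the ratios, curve efficiencies
    and the inhibition-test flag.
    """
    curves: dict[str, dq.StdCurve] = {}
    standards = qpcr_runs[qpcr_runs["role"] == "standard"]
    for gene, grp in standards.groupby("gene"):
        curves[gene] = dq.fit_standard_curve(
            grp["copies"].to_numpy(), grp["ct"].to_numpy(), gene=gene
        )
    samples = qpcr_runs[qpcr_runs["role"] == "sample"]
    rows = []
    for sample_id, per_sample in samples.groupby("sample_id"):
        abundances: dict[str, float] = {}
        record: dict[str, object] = {"sample_id": sample_id}
        for gene, grp in per_sample.groupby("gene"):
            if gene not in curves:
                raise ValueError(f"no standard curve for gene {gene!r}")
            mean_ct, sd_ct = dq.average_replicates(grp["ct"].to_numpy())
            dna = float(grp["dna_ng"].iloc[0])
            q = dq.quantify(mean_ct, curves[gene], dna, sample_id=str(sample_id))
            abundances[gene] = q.copies_per_ng
            record[f"{gene}_copies_per_ng"] = q.copies_per_ng
            record[f"{gene}_ct_sd"] = sd_ct
        if set(dq.RATIO_GENES) <= set(abundances):
            record.update(dq.gene_ratios(abundances).as_dict())
        alone = qpcr_runs[
            (qpcr_runs["role"] == "inhibition_alone")
            & (qpcr_runs["sample_id"] == sample_id)
        ]
        mixed = qpcr_runs[
            (qpcr_runs["role"] == "inhibition_mixed")
            & (qpcr_runs["sample_id"] == sample_id)
        ]
        if len(alone) and len(mixed):
            shift, flag = dq.inhibition_shift(
                float(alone["ct"].mean()), float(mixed["ct"].mean())
            )
            record["inhibition_shift_ct"] = shift
            record["inhibition_flag"] = flag
        rows.append(record)
    out = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    for gene, curve in curves.items():
        out[f"{gene}_efficiency_pct"] = 100.0 * curve.efficiency
    return out


def diversity_table(
    distance_paths: dict[str, dict[str, str]],
    gene_cutoffs: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Cluster each (gene, period) distance matrix and summarise diversity."""
    cutoffs = dict(GENE_CUTOFFS)
    cutoffs.update(gene_cutoffs or {})
    rows = []
    for gene in sorted(distance_paths):
        if gene not in cutoffs:
            raise ValueError(f"no OTU cutoff known for gene {gene!r}")
        for period in sorted(distance_paths[gene]):
            dm = dio.read_distance_matrix(distance_paths[gene][period])
            assignment = cluster_otus(dm, cutoffs[gene])
            d = diversity_summary(assignment.abundances)
            rows.append({
                "gene": gene, "period": period, "cutoff": cutoffs[gene],
                "n": d.n, "s_obs": d.s_obs, "s_chao1": d.s_chao1,
                "coverage_pct": d.coverage_pct,
                "shannon": d.shannon, "shannon_sd": d.shannon_sd,
            })
    return pd.DataFrame(rows)


def unifrac_table(
    tree_paths: dict[str, str],
    count_paths: dict[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise normalised weighted UniFrac (with permutation p) per gene."""
    rows = []
    for gene in sorted(tree_paths):
        if gene not in count_paths:
            raise ValueError(f"no tip-count table for gene {gene!r}")
        tree = dio.read_tree(tree_paths[gene])
        counts = dio.read_tip_counts(count_paths[gene])
        atree = AbundanceTree(
            tree, {c: counts[c].to_dict() for c in counts.columns}
        )
        # stable per-gene stream: str hash() is salted per process, sha256 is not
        gene_tag = int.from_bytes(hashlib.sha256(gene.encode()).digest()[:4], "big")
        gene_seed = int(
            np.random.SeedSequence([seed, gene_tag]).generate_state(1)[0]
            % (2**31 - 1)
        )
        for a, b, res in pairwise_unifrac(
            atree, n_permutations=n_permutations, seed=gene_seed
        ):
            rows.append({
                "gene": gene, "sample_a": a, "sample_b": b,
                "unifrac": res.distance, "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            })
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="n.d.")


def report(config: RunConfig) -> dict[str, Path]:
    """Run every configured stage and write the summary tables + log.

    Returns the mapping of table name to written path. The log records the
    seed, a config hash and per-stage row counts (no timestamps, so a fixed
    seed reproduces the output byte for byte).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_lines = []
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    log_lines.append(f"seed: {config.seed}")
    log_lines.append(f"config_sha256: {cfg_hash}")

    try:
        periods = dio.read_chemistry(config.chemistry)
        balance = balance_table(periods)
    except Exception as exc:
        raise StageError("balance", exc) from exc
    path = outdir / "balance.tsv"
    _write_tsv(balance, path)
    written["balance"] = path
    log_lines.append(f"balance: {len(balance)} period(s)")

    if config.qpcr:
        try:
            ratios = ratio_table(dio.read_qpcr_runs(config.qpcr))
        except Exception as exc:
            raise StageError("qpcr", exc) from exc
        path = outdir / "gene_ratios.tsv"
        _write_tsv(ratios, path)
        written["gene_ratios"] = path
        log_lines.append(f"qpcr: {len(ratios)} sample(s)")

    if config.distances:
        try:
            diversity = diversity_table(config.distances, config.gene_cutoffs)
        except Exception as exc:
            raise StageError("diversity", exc) from exc
        path = outdir / "diversity.tsv"
        _write_tsv(diversity, path)
        written["diversity"] = path
        log_lines.append(f"diversity: {len(diversity)} communities")

    if config.trees:
        try:
            uf = unifrac_table(
                config.trees, config.tip_counts,
                n_permutations=config.n_permutations, seed=config.seed,
            )
        except Exception as exc:
            raise StageError("unifrac", exc) from exc
        path = outdir / "unifrac.tsv"
        _write_tsv(uf, path)
        written["unifrac"] = path
        log_lines.append(f"unifrac: {len(uf)} pair(s)")

    log_path = outdir / "report.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    written["log"] = log_path
    return written
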