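"""Readers and writers for the pipeline's plain-text formats.

Canonical formats: CSV for chemistry and qPCR run tables ("n.d." marks a
species not detected), phylip square or lower-triangle dialect for pairwise
distance matrices (auto-detected), newick for rooted trees, and TSV for tip
counts and OTU tables. Every writer emits files its paired reader parses
back to equal values.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from .stoichiometry import OperatingPeriod
from .synthetic import CHEMISTRY_COLUMNS, QPCR_COLUMNS

__all__ = [
    "read_chemistry",
    "write_chemistry",
    "read_qpcr_runs",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_tree",
    "read_tip_counts",
    "reference_periods_path",
    "load_reference_periods",
    "RunConfig",
    "load_config",
    "save_config",
]

_MISSING_TOKENS = {"", "n.d.", "nd", "na", "nan"}


def _parse_cell(token: str, column: str, line_no: int):
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"line {line_no}: non-numeric value {token!r} in column {column!r}"
        ) from None


def read_chemistry(path) -> list[OperatingPeriod]:
    """Parse a per-period chemistry CSV into operating periods.

    "n.d." (any case), "na" or an empty cell mean missing. Malformed rows
    raise with their line number; invariant violations (non-positive flow,
    negative concentrations) surface through OperatingPeriod validation.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        return []
    header = [h.strip() for h in lines[0].split(",")]
    unknown = set(header) - set(CHEMISTRY_COLUMNS)
    if unknown:
        raise ValueError(f"unknown chemistry column(s): {sorted(unknown)}")
    for required in ("period_id", "flow_l_per_d"):
        if required not in header:
            raise ValueError(f"chemistry file missing required column {required!r}")
    periods = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(header):
            raise ValueError(
                f"line {line_no}: expected {len(header)} cells, got {len(cells)}"
            )
        row = dict(zip(header, cells))
        flow = _parse_cell(row["flow_l_per_d"], "flow_l_per_d", line_no)
        if flow is None:
            raise ValueError(f"line {line_no}: flow_l_per_d is required")
        ncc = _parse_cell(row.get("ncc_volume_m3", ""), "ncc_volume_m3", line_no)

        def num(col: str) -> Optional[float]:
            return _parse_cell(row.get(col, ""), col, line_no)

        try:
            periods.append(OperatingPeriod(
                period_id=row["period_id"].strip(),
                regime=row.get("regime", "").strip(),
                flow=flow,
                cod_in=num("cod_in"), cod_out=num("cod_out"),
                no3_in=num("no3_in"), no3_out=num("no3_out"),
                no2_in=num("no2_in"), no2_out=num("no2_out"),
                n2o_out=num("n2o_out"), n2_out=num("n2_out"),
                current_density=num("current_density_a_per_m3"),
                ncc_volume=ncc if ncc is not None else 145e-6,
            ))
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from None
    return periods


def write_chemistry(table, path) -> None:
    """Write periods (DataFrame in canonical schema, or OperatingPeriod list)."""
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame([
            {
                "period_id": p.period_id, "regime": p.regime,
                "flow_l_per_d": p.flow, "cod_in": p.cod_in, "cod_out": p.cod_out,
                "no3_in": p.no3_in, "no3_out": p.no3_out,
                "no2_in": p.no2_in, "no2_out": p.no2_out,
                "n2o_out": p.n2o_out, "n2_out": p.n2_out,
                "current_density_a_per_m3": p.current_density,
                "ncc_volume_m3": p.ncc_volume,
            }
            for p in table
        ], columns=CHEMISTRY_COLUMNS)
    out_lines = [",".join(df.columns)]
    for _, row in df.iterrows():
        cells = []
        for col in df.columns:
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                cells.append("n.d.")
            elif isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(str(v))
        out_lines.append(",".join(cells))
    Path(path).write_text("\n".join(out_lines) + "\n")


def read_qpcr_runs(path) -> pd.DataFrame:
    """qPCR run table with columns gene, sample_id, role, copies, ct, dna_ng."""
    df = pd.read_csv(path)
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing column(s): {sorted(missing)}")
    valid_roles = {"standard", "sample", "inhibition_alone", "inhibition_mixed"}
    bad = set(df["role"].unique()) - valid_roles
    if bad:
        raise ValueError(f"unknown role(s) in qPCR table: {sorted(bad)}")
    return df


def read_distance_matrix(path, atol: float = 1e-9) -> DistanceMatrix:
    """Phylip-dialect pairwise distance matrix, square or lower triangle.

    The dialect is auto-detected from the token count of the first data
    line. Square input must be symmetric to within ``atol``.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty distance file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ValueError(f"{path}: first line must hold the sequence count") from None
    if len(lines) != n + 1:
        raise ValueError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    first_row_values = len(lines[1].split()) - 1
    if n == 1:
        square = first_row_values == 1
    elif first_row_values == n:
        square = True
    elif first_row_values == 0:
        square = False
    else:
        raise ValueError(
            f"{path}: row 1 has {first_row_values} values; expected {n} "
            "(square) or 0 (lower triangle)"
        )
    labels: list[str] = []
    data = np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        tokens = line.split()
        labels.append(tokens[0])
        expected = n if square else i
        values = tokens[1:]
        if len(values) != expected:
            raise ValueError(
                f"{path}: row for {tokens[0]!r} has {len(values)} values, "
                f"expected {expected}"
            )
        for j, tok in enumerate(values):
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric distance {tok!r} at row "
                    f"{tokens[0]!r}, column {j + 1}"
                ) from None
            data[i, j] = v
            if not square:
                data[j, i] = v
    if square:
        if np.max(np.abs(data - data.T)) > atol:
            raise ValueError(f"{path}: square matrix asymmetric beyond {atol}")
        data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=labels)


def write_distance_matrix(dm: DistanceMatrix, path, dialect: str = "square") -> None:
    n = len(dm.ids)
    lines = [f"\t{n}"]
    for i, label in enumerate(dm.ids):
        stop = n if dialect == "square" else i
        row = "\t".join(f"{dm.data[i, j]:.6f}" for j in range(stop))
        lines.append(f"{label}\t{row}".rstrip("\t"))
    if dialect not in {"square", "lower"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path) -> TreeNode:
    """Rooted newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise ValueError(f"{path}: branch without length (node {node.name!r})")
    return tree


def read_tip_counts(path) -> pd.DataFrame:
    """Tip abundance TSV: first column tip label, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty tip-count table")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative tip counts")
    return df


_PKG_DATA = Path(__file__).parent / "data"


def reference_periods_path() -> Path:
    """Packaged per-period operating table of the reference biocathode study."""
    return _PKG_DATA / "periods.csv"


def load_reference_periods() -> list[OperatingPeriod]:
    return read_chemistry(reference_periods_path())


@dataclass
class RunConfig:
    """Configuration for the umbrella `report` pipeline.

    Paths are resolved relative to the config file's directory when loaded
    from disk. Unknown keys are rejected; round-trips are lossless.
    """

    chemistry: str
    qpcr: Optional[str] = None
    distances: dict[str, dict[str, str]] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)
    tip_counts: dict[str, str] = field(default_factory=dict)
    gene_cutoffs: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 1000
    seed: int = 0
    outdir: str = "report_out"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "chemistry" not in raw:
        raise ValueError(f"{path}: config requires a 'chemistry' path")
    cfg = RunConfig(**raw)
    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    cfg.chemistry = resolve(cfg.chemistry)
    if cfg.qpcr:
        cfg.qpcr = resolve(cfg.qpcr)
    cfg.distances = {
        g: {p: resolve(v) for p, v in per.items()}
        for g, per in cfg.distances.items()
    }
    cfg.trees = {g: resolve(v) for g, v in cfg.trees.items()}
    cfg.tip_counts = {g: resolve(v) for g, v in cfg.tip_counts.items()}
    cfg.outdir = resolve(cfg.outdir)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
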