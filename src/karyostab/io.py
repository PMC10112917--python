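"""Readers and writers for the pipeline's plain-text formats.

Tables are TSV with headers, intervals are BED (0-based half-open), and run
configuration is a flat YAML mapping.  Every writer's output round-trips
through its paired reader.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .competition import ProportionTrajectory
from .growth import GrowthCurve

__all__ = [
    "RunConfig",
    "read_bed",
    "read_growth_curves",
    "write_growth_curves",
    "read_trajectory",
    "write_trajectory",
    "read_counts_matrix",
    "write_counts_matrix",
    "read_chrom_sizes",
    "read_flow_events",
    "read_config",
]


@dataclass
class RunConfig:
    """Resolved run parameters; defaults match the analysis conventions."""

    alpha: float = 0.05
    lfc_min: float = 1.1
    bin_size: int = 1_000_000
    prior_count: float = 0.5
    passage_interval_h: float = 24.0
    seed: int = 0


def read_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file into (chrom, start, end), validating lines.

    Comment (#), ``track`` and ``browser`` lines are skipped; an interval with
    ``end <= start`` raises with its line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """TSV with columns condition, replicate, time_h, count."""
    df = pd.read_csv(path, sep="\t")
    curves = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(),
                counts=grp["count"].to_numpy(),
                replicate=str(rep),
                condition=str(cond),
            )
        )
    return curves


def write_growth_curves(curves: list[GrowthCurve], path: str | Path) -> None:
    rows = [
        {"condition": c.condition, "replicate": c.replicate, "time_h": t, "count": n}
        for c in curves
        for t, n in zip(c.times, c.counts)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_trajectory(traj: ProportionTrajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False)


def read_trajectory(path: str | Path, label: str = "") -> ProportionTrajectory:
    return ProportionTrajectory.from_frame(pd.read_csv(path, sep="\t"), label=label)


def write_counts_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    """Bin-by-sample counts, rows indexed ``chrom:start-end``."""
    counts.to_csv(path, sep="\t", index_label="bin")


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="bin")


def read_flow_events(path: str | Path) -> pd.DataFrame:
    """TSV/CSV with columns sample_id, gfp, mcherry and time_h or passage."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    needed = {"sample_id", "gfp", "mcherry"}
    if not needed.issubset(df.columns):
        raise ValueError(f"flow table needs columns {sorted(needed)}")
    if "time_h" not in df.columns and "passage" not in df.columns:
        raise ValueError("flow table needs a time_h or passage column")
    return df
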