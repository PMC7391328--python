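"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain CSV; pattern and envelope files carry ``#``-prefixed
header comments recording the observation window and run settings, so a
file is self-describing and a run is reproducible from its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .nullmodels import EnvelopeResult, NullModelSpec
from .ppcore import PointPattern, RGrid, SummaryFunction, Window
from .replicates import PairedComparison

__all__ = [
    "read_control_points",
    "read_digitized_points",
    "write_pattern",
    "read_pattern",
    "write_summary",
    "read_summary",
    "write_envelope",
    "read_envelope",
    "write_paired_comparison",
    "write_run_metadata",
]

CONTROL_COLUMNS = ["subblock_row", "subblock_col", "corner_id", "u_px", "v_px", "x_m", "y_m"]
DIGITIZED_COLUMNS = ["plot_id", "subblock_row", "subblock_col", "species", "mark_id", "u_px", "v_px"]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_control_points(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CONTROL_COLUMNS)


def read_digitized_points(path: str | Path) -> pd.DataFrame:
    return _read_table(path, DIGITIZED_COLUMNS)


def write_pattern(p: PointPattern, path: str | Path) -> None:
    """Assembled-pattern file: ``species, x_m, y_m`` with the window extent
    recorded in a header comment."""
    w = p.window
    with open(path, "w") as fh:
        fh.write(f"# window: {w.x_min} {w.y_min} {w.x_max} {w.y_max}\n")
        fh.write("species,x_m,y_m\n")
        for x, y in p.points:
            fh.write(f"{p.label},{x:.9g},{y:.9g}\n")


def read_pattern(path: str | Path, species: str | None = None) -> PointPattern:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# window:"):
        raise ValueError(f"{path}: missing '# window:' header")
    x0, y0, x1, y1 = (float(v) for v in first.split(":")[1].split())
    df = _read_table(path, ["species", "x_m", "y_m"])
    label = species if species is not None else (df["species"].iloc[0] if len(df) else "")
    if species is not None:
        df = df[df["species"] == species]
    return PointPattern(df[["x_m", "y_m"]].to_numpy(float), Window(x0, y0, x1, y1), label=str(label))


def write_summary(s: SummaryFunction, path: str | Path) -> None:
    pd.DataFrame(
        {"r": s.rgrid.values, "value": s.values, "n": s.n, "statistic": s.statistic}
    ).to_csv(path, index=False)


def read_summary(path: str | Path) -> SummaryFunction:
    df = _read_table(path, ["r", "value", "n", "statistic"])
    r = df["r"].to_numpy(float)
    dr = r[0] if len(r) == 1 else float(np.diff(r).mean())
    return SummaryFunction(
        str(df["statistic"].iloc[0]), RGrid(r, dr), df["value"].to_numpy(float), int(df["n"].iloc[0])
    )


def write_envelope(e: EnvelopeResult, path: str | Path) -> None:
    """Envelope file: ``r, g_obs, g_lo, g_hi, label`` plus a metadata
    header with the null-model settings."""
    with open(path, "w") as fh:
        fh.write(
            f"# null: kind={e.spec.kind} nsim={e.nsim} seed={e.spec.seed} "
            f"bandwidth={e.spec.bandwidth} n={e.n}\n"
        )
        fh.write("r,g_obs,g_lo,g_hi,label\n")
        for r, o, lo, hi, lab in zip(e.rgrid.values, e.observed, e.lower, e.upper, e.labels):
            fh.write(f"{r:.9g},{o:.9g},{lo:.9g},{hi:.9g},{lab}\n")


def read_envelope(path: str | Path) -> EnvelopeResult:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# null:"):
        raise ValueError(f"{path}: missing '# null:' header")
    meta = dict(tok.split("=") for tok in first.split(":", 1)[1].split())
    df = _read_table(path, ["r", "g_obs", "g_lo", "g_hi", "label"])
    r = df["r"].to_numpy(float)
    dr = r[0] if len(r) == 1 else float(np.diff(r).mean())
    spec = NullModelSpec(
        kind=meta["kind"],
        nsim=int(meta["nsim"]),
        bandwidth=float(meta["bandwidth"]),
        seed=int(meta["seed"]),
    )
    return EnvelopeResult(
        RGrid(r, dr),
        df["g_obs"].to_numpy(float),
        df["g_lo"].to_numpy(float),
        df["g_hi"].to_numpy(float),
        tuple(df["label"]),
        spec.nsim,
        spec,
        n=int(meta.get("n", 0)),
    )


def write_paired_comparison(
    comparisons: dict[str, PairedComparison], path: str | Path
) -> None:
    """Reliability-table file mirroring the paired t summary columns."""
    rows = []
    for name, c in comparisons.items():
        rows.append(
            {
                "comparison": name,
                "mean": c.mean,
                "std_deviation": c.sd,
                "std_error_mean": c.se,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "degenerate": c.infinite,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_metadata(path: str | Path, **settings) -> None:
    """JSON sidecar recording the settings of a command invocation."""
    from . import __version__

    payload = {"quadpat_version": __version__, **settings}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
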