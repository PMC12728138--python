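"""Delimited-text I/O for ERP matrices and latency tables.

The native on-disk format is a transparent, diffable delimited matrix:
the header row holds the time axis in ms (first cell is the id column
name), each following row one subject/condition waveform in μV, NaN for
missing samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .signal_model import GridError, SampledSignal, GRID_TOL

__all__ = [
    "read_erp_matrix",
    "write_erp_matrix",
    "LATENCY_COLUMNS",
    "latency_table",
    "remove_group_outliers",
]

logger = logging.getLogger("erplatency")

LATENCY_COLUMNS = [
    "id",
    "condition",
    "method",
    "latency_ms",
    "a_opt",
    "b_opt",
    "fit_r",
    "valid",
    "reject_reason",
]


def read_erp_matrix(path, sep: str = ",") -> tuple[list[str], list[SampledSignal]]:
    """Read a delimited ERP matrix; returns (ids, signals).

    The first header cell names the id column; the remaining header cells
    are the time axis in ms, which must be uniform and contain t = 0.
    NaN cells become invalid samples.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise GridError("ERP matrix needs an id column and at least 2 time columns")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise GridError(f"non-numeric time header: {exc}") from exc
    steps = np.diff(times)
    bad = np.flatnonzero(np.abs(steps - steps[0]) > GRID_TOL)
    if bad.size:
        # +1 for the id column, +1 for 1-based counting, +1 for the step's
        # right endpoint
        raise GridError(f"non-uniform time grid at column {int(bad[0]) + 3}")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GridError(f"duplicate ids: {dupes}")
    signals = [
        SampledSignal(times, row) for row in df.iloc[:, 1:].to_numpy(dtype=float)
    ]
    return ids, signals


def write_erp_matrix(
    path, ids, signals: list[SampledSignal], sep: str = ",", id_name: str = "id"
) -> None:
    """Write waveforms as a delimited matrix (lossless round trip)."""
    if len(ids) != len(signals):
        raise ValueError("ids and signals must have equal lengths")
    times = signals[0].times
    for s in signals[1:]:
        if not signals[0].same_grid(s):
            raise GridError("all signals must share the same time grid")
    rows = [np.where(s.valid_mask, s.values, np.nan) for s in signals]
    df = pd.DataFrame(rows, columns=[repr(float(t)) for t in times])
    df.insert(0, id_name, list(ids))
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def latency_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a latency table with the canonical column order."""
    df = pd.DataFrame(rows)
    for col in LATENCY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[LATENCY_COLUMNS]


def remove_group_outliers(
    table: pd.DataFrame,
    sd_threshold: float = 3.0,
    group_cols: tuple[str, ...] = ("condition", "method"),
) -> pd.DataFrame:
    """Flag latencies more than ``sd_threshold`` SD from their group mean.

    Groups are condition × method; flagged rows keep their latency for
    audit but get ``valid=False`` and ``reject_reason='outlier'``.  Groups
    with fewer than 3 valid latencies, or zero spread, are left untouched.
    Single pass (non-iterative).
    """
    out = table.copy()
    for key, idx in out.groupby(list(group_cols)).groups.items():
        sub = out.loc[idx]
        ok = sub["valid"].astype(bool) & np.isfinite(sub["latency_ms"].astype(float))
        vals = sub.loc[ok, "latency_ms"].astype(float)
        if vals.size < 3:
            logger.warning("group %s has fewer than 3 valid latencies; skipped", key)
            continue
        sd = vals.std(ddof=0)
        if sd == 0:
            continue
        z = (vals - vals.mean()).abs() / sd
        flag = z.index[z > sd_threshold]
        for i in flag:
            logger.info(
                "outlier: id=%s group=%s latency=%.1f ms |z|=%.2f",
                out.at[i, "id"], key, out.at[i, "latency_ms"], z[i],
            )
        out.loc[flag, "valid"] = False
        out.loc[flag, "reject_reason"] = "outlier"
    return out
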