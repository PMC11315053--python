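"""CSV readers and writers for all pipeline schemas.

All tabular outputs use millimetres for lengths and milliseconds for
times. Each reader validates the expected columns and reports missing ones
by name; writers fix the column order so that a read/write round trip is
byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    DIFF_TABLE_COLUMNS,
    LANDMARKS,
    LandmarkSignal,
    StrideSet,
    SUMMARY_COLUMNS,
)

PathLike = Union[str, Path]

SIGNAL_COLUMNS = ("time_s", "head_mm", "withers_mm", "pelvis_mm")
SIGNAL_ACC_COLUMNS = ("head_acc_ms2", "withers_acc_ms2", "pelvis_acc_ms2")
STRIDE_COLUMNS = (
    "stride_idx",
    "start_sample",
    "mid_sample",
    "end_sample",
    "first_half_label",
)


class SchemaError(ValueError):
    """A CSV file does not match the documented schema."""


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )


# --- signals ---------------------------------------------------------------


def write_signals(
    path: PathLike,
    signals: Dict[str, LandmarkSignal],
    accelerations: Optional[Dict[str, LandmarkSignal]] = None,
) -> None:
    """Write per-landmark displacement (and optional acceleration) traces."""
    lengths = {len(s) for s in signals.values()}
    if len(lengths) != 1:
        raise ValueError("all landmark signals must have equal length")
    fs = {s.fs for s in signals.values()}.pop()
    n = lengths.pop()
    out = {"time_s": np.arange(n) / fs}
    for lm in LANDMARKS:
        if lm not in signals:
            raise ValueError(f"missing landmark {lm!r}")
        out[f"{lm}_mm"] = signals[lm].samples
    if accelerations is not None:
        for lm in LANDMARKS:
            out[f"{lm}_acc_ms2"] = accelerations[lm].samples
    pd.DataFrame(out).to_csv(path, index=False)


def read_signals(path: PathLike) -> Dict[str, LandmarkSignal]:
    """Read a signal CSV; returns displacement signals keyed by landmark."""
    df = pd.read_csv(path, float_precision='round_trip')
    _check_columns(df, SIGNAL_COLUMNS, f"signal file {path}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise SchemaError(f"signal file {path}: need at least two samples")
    fs = round(1.0 / float(np.median(np.diff(t))), 6)
    return {
        lm: LandmarkSignal(df[f"{lm}_mm"].to_numpy(), fs, lm, "displacement")
        for lm in LANDMARKS
    }


def read_accelerations(path: PathLike) -> Dict[str, LandmarkSignal]:
    """Read the acceleration columns of a signal CSV (m/s^2)."""
    df = pd.read_csv(path, float_precision='round_trip')
    _check_columns(
        df, ("time_s",) + SIGNAL_ACC_COLUMNS, f"acceleration file {path}"
    )
    t = df["time_s"].to_numpy()
    fs = round(1.0 / float(np.median(np.diff(t))), 6)
    return {
        lm: LandmarkSignal(
            df[f"{lm}_acc_ms2"].to_numpy(), fs, lm, "acceleration"
        )
        for lm in LANDMARKS
    }


# --- stride sets -----------------------------------------------------------


def write_strides(path: PathLike, strides: StrideSet) -> None:
    pd.DataFrame(
        {
            "stride_idx": np.arange(strides.n_strides),
            "start_sample": strides.starts,
            "mid_sample": strides.mids,
            "end_sample": strides.ends,
            "first_half_label": strides.first_half_label or "",
        }
    ).to_csv(path, index=False)


def read_strides(path: PathLike, fs: float) -> StrideSet:
    df = pd.read_csv(path, keep_default_na=False, float_precision='round_trip')
    _check_columns(df, STRIDE_COLUMNS, f"stride file {path}")
    label = str(df["first_half_label"].iloc[0]) if len(df) else ""
    return StrideSet(
        starts=df["start_sample"].to_numpy(),
        mids=df["mid_sample"].to_numpy(),
        ends=df["end_sample"].to_numpy(),
        fs=fs,
        first_half_label=label if label in ("left", "right") else None,
    )


# --- condition summaries and normalized differences ------------------------


def write_condition_summaries(path: PathLike, summaries: pd.DataFrame) -> None:
    _check_columns(summaries, SUMMARY_COLUMNS, "condition summaries")
    summaries[list(SUMMARY_COLUMNS)].to_csv(path, index=False)


def read_condition_summaries(
    path: PathLike, column_map: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Read per-condition summaries.

    ``column_map`` renames external column names onto the package schema,
    serving as a thin adapter for externally deposited datasets.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    _check_columns(df, SUMMARY_COLUMNS, f"condition summary file {path}")
    return df[list(SUMMARY_COLUMNS)]


def write_normalized_diffs(path: PathLike, diffs: pd.DataFrame) -> None:
    _check_columns(diffs, DIFF_TABLE_COLUMNS, "normalized differences")
    diffs[list(DIFF_TABLE_COLUMNS)].to_csv(path, index=False)


def read_normalized_diffs(
    path: PathLike, column_map: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    _check_columns(df, DIFF_TABLE_COLUMNS, f"normalized difference file {path}")
    return df[list(DIFF_TABLE_COLUMNS)]


# --- analysis report -------------------------------------------------------


def write_report(path: PathLike, report: pd.DataFrame) -> None:
    report.to_csv(path, index=False)


def read_report(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
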