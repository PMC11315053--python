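"""Per-stride movement symmetry metrics and per-condition summaries.

For each stride, the two half-cycles are compared:

* ``Dmin`` — minimum of the left-labelled half minus minimum of the
  right-labelled half (weight-bearing asymmetry proxy);
* ``Dmax`` — analogous difference of the half maxima (push-off proxy);
* ``Dup`` — difference of the upward amplitudes, the rise from each half's
  minimum to its following maximum (push-off proxy);
* ``ROM`` — global range of vertical motion within the stride.

Negative asymmetry values indicate left asymmetry under this convention.
A condition is summarised by the component-wise median across strides.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .segmentation import label_halves, segment_strides
from .types import (
    LANDMARK_PREFIX,
    LandmarkSignal,
    StrideSet,
    SUMMARY_COLUMNS,
)

logger = logging.getLogger(__name__)

#: strides-per-condition level below which a warning is emitted
MIN_STRIDES_WARN = 25


class EmptyConditionError(RuntimeError):
    """Raised when a condition contains no valid stride."""


def stride_metrics(signal: LandmarkSignal, strides: StrideSet) -> pd.DataFrame:
    """Per-stride Dmin, Dmax, Dup and ROM (mm) for one landmark.

    Strides are anchored at displacement minima, so each half's minimum is
    its starting boundary sample; the half maximum is searched between the
    boundaries (earliest sample on ties). A stride whose half has no
    interior maximum (e.g. a monotonic half) is excluded and logged.
    """
    if strides.first_half_label is None:
        raise ValueError("stride halves must be labelled before computing metrics")
    x = signal.samples
    first_left = strides.first_half_label == "left"
    rows = []
    for i in range(strides.n_strides):
        s, m, e = strides.starts[i], strides.mids[i], strides.ends[i]
        h1, h2 = x[s + 1 : m], x[m + 1 : e]
        if h1.size < 3 or h2.size < 3:
            logger.info("stride %d excluded: half-cycle too short", i)
            continue
        i1, i2 = int(np.argmax(h1)), int(np.argmax(h2))
        if i1 in (0, h1.size - 1) or i2 in (0, h2.size - 1):
            logger.info("stride %d excluded: half without interior maximum", i)
            continue
        fmin, fmax = float(x[s]), float(h1[i1])
        smin, smax = float(x[m]), float(h2[i2])
        if first_left:
            min1, max1, min2, max2 = fmin, fmax, smin, smax
        else:
            min1, max1, min2, max2 = smin, smax, fmin, fmax
        rows.append(
            {
                "stride_idx": i,
                "Dmin": min1 - min2,
                "Dmax": max1 - max2,
                "Dup": (max1 - min1) - (max2 - min2),
                "ROM": max(max1, max2) - min(min1, min2),
                "stride_time_ms": (e - s) / strides.fs * 1000.0,
                # temporal-order half extrema, for diagnostics and testing
                "first_min": fmin,
                "first_max": fmax,
                "second_min": smin,
                "second_max": smax,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stride_idx",
            "Dmin",
            "Dmax",
            "Dup",
            "ROM",
            "stride_time_ms",
            "first_min",
            "first_max",
            "second_min",
            "second_max",
        ],
    )


def summarize_condition(
    metrics: Mapping[str, pd.DataFrame],
    meta: Mapping[str, object],
    min_strides_warn: int = MIN_STRIDES_WARN,
) -> pd.Series:
    """Median metrics across strides for one horse/session/condition.

    Parameters
    ----------
    metrics : mapping
        Landmark name -> per-stride metrics frame from :func:`stride_metrics`.
    meta : mapping
        Must provide ``horse_id``, ``session``, ``surface``, ``condition``
        and ``reshod_limb``.
    """
    counts = {lm: len(df) for lm, df in metrics.items()}
    if not counts or min(counts.values()) == 0:
        raise EmptyConditionError(
            f"no valid strides for {dict(meta)} (per-landmark counts: {counts})"
        )
    n_strides = int(min(counts.values()))
    if n_strides < min_strides_warn:
        logger.warning(
            "only %d valid strides for %s; below the %d-stride target",
            n_strides,
            dict(meta),
            min_strides_warn,
        )
    anchor = "pelvis" if "pelvis" in metrics else next(iter(metrics))
    row = {
        "horse_id": meta["horse_id"],
        "session": meta["session"],
        "surface": meta["surface"],
        "condition": meta["condition"],
        "reshod_limb": meta["reshod_limb"],
        "stride_time_ms": float(metrics[anchor]["stride_time_ms"].median()),
        "n_strides": n_strides,
    }
    for lm, df in metrics.items():
        p = LANDMARK_PREFIX[lm]
        med = df[["Dmin", "Dmax", "Dup", "ROM"]].median()
        for m in ("Dmin", "Dmax", "Dup", "ROM"):
            row[f"{p}{m}"] = float(med[m])
    return pd.Series(row).reindex(
        [c for c in SUMMARY_COLUMNS if c in row]
    )


def analyze_trial(
    signals: Mapping[str, LandmarkSignal],
    meta: Mapping[str, object],
    label_reference="first_half_is_left",
    anchor: str = "pelvis",
    strides: Optional[StrideSet] = None,
    outlier_frac: float = 0.25,
) -> pd.Series:
    """Full single-trial pipeline: segment, label, measure, summarise.

    The anchor landmark (pelvis by default) provides the stride clock for
    all landmarks of the trial; trot is symmetric in timing across the
    upper-body landmarks, so one clock suffices.
    """
    if strides is None:
        anchor_lm = anchor if anchor in signals else next(iter(signals))
        strides = segment_strides(signals[anchor_lm], outlier_frac=outlier_frac)
    if strides.first_half_label is None:
        strides = label_halves(strides, label_reference)
    metrics: Dict[str, pd.DataFrame] = {
        lm: stride_metrics(sig, strides) for lm, sig in signals.items()
    }
    return summarize_condition(metrics, meta)
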