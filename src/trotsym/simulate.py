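"""Synthetic trot signals and full synthetic re-shoeing studies.

The generator produces the vertical displacement of one landmark as a
piecewise-cosine curve through four extrema per stride (two oscillations per
stride, as in trot), with configurable per-stride extremum jitter,
measurement noise, slow baseline drift and extremum-time jitter. Ground
truth (extrema, boundaries, per-stride and per-condition metrics) is
returned alongside every simulated object so that each downstream stage of
the pipeline can be tested against known values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    ASYMMETRY_DIFF_COLUMNS,
    DIFF_COLUMNS,
    DIFF_TABLE_COLUMNS,
    EffectTable,
    LANDMARKS,
    LANDMARK_PREFIX,
    LandmarkSignal,
    LIMBS,
    NoiseModel,
    StrideShape,
    StudyDesign,
    SUMMARY_COLUMNS,
    VariableEffect,
)

logger = logging.getLogger(__name__)

#: default noise-free range of motion (mm) per landmark, close to the
#: baseline values observed for sound sport horses in trot.
DEFAULT_ROM_MM = {"head": 80.0, "withers": 100.0, "pelvis": 100.0}


def shape_from_metrics(
    dmin: float,
    dmax: float,
    rom: float,
    stride_time_ms: float = 720.0,
    phases: tuple = (0.0, 0.25, 0.5, 0.75),
) -> StrideShape:
    """Construct stride extrema realising given Dmin, Dmax and ROM.

    The two maxima are placed symmetrically about ``+A`` and the two minima
    about ``-A`` with ``A`` chosen so the global range equals ``rom``. With
    the half-cycle pairing used throughout the package, the upward-amplitude
    difference is then implied: ``Dup = Dmax - Dmin``.
    """
    a = (rom - (abs(dmax) + abs(dmin)) / 2.0) / 2.0
    if a <= 0:
        raise ValueError("rom too small for the requested asymmetries")
    return StrideShape(
        min1=-a + dmin / 2.0,
        max1=a + dmax / 2.0,
        min2=-a - dmin / 2.0,
        max2=a - dmax / 2.0,
        stride_time_ms=stride_time_ms,
        phases=phases,
    )


@dataclass
class StrideTruth:
    """Ground truth of one simulated recording."""

    start_samples: np.ndarray
    mid_samples: np.ndarray
    end_samples: np.ndarray
    extrema: np.ndarray  # (n_strides, 4): min1, max1, min2, max2
    metrics: pd.DataFrame  # per stride: Dmin, Dmax, Dup, ROM (first half = left)
    first_half_label: str = "left"

    def metric_medians(self) -> pd.Series:
        return self.metrics[["Dmin", "Dmax", "Dup", "ROM"]].median()


@dataclass
class SimulatedTrial:
    """A simulated landmark recording with its ground truth."""

    signal: LandmarkSignal
    acceleration: LandmarkSignal
    truth: StrideTruth


def _stride_metrics_from_extrema(extrema: np.ndarray) -> pd.DataFrame:
    """Closed-form per-stride metrics from (n, 4) extrema (first half left)."""
    min1, max1, min2, max2 = extrema.T
    return pd.DataFrame(
        {
            "Dmin": min1 - min2,
            "Dmax": max1 - max2,
            "Dup": (max1 - min1) - (max2 - min2),
            "ROM": np.maximum(max1, max2) - np.minimum(min1, min2),
        }
    )


def simulate_stride_signal(
    shape: StrideShape,
    n_strides: int,
    noise: Optional[NoiseModel] = None,
    fs: float = 100.0,
    landmark: str = "pelvis",
    first_half_label: str = "left",
    rng: Optional[np.random.Generator] = None,
) -> SimulatedTrial:
    """Simulate a continuous displacement recording of ``n_strides`` strides.

    The noiseless curve interpolates the stride extrema with cosine
    half-waves, so its extrema equal the :class:`StrideShape` values exactly
    and occur at the stated phases. An acceleration trace (m/s^2), obtained
    by twofold numerical differentiation of the noise-free displacement, is
    emitted alongside.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be at least 1")
    noise = noise or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    t_stride = shape.stride_time_ms / 1000.0
    if fs <= 4.0 / t_stride:
        raise ValueError(
            "sampling rate must exceed twice the oscillation frequency "
            f"(fs={fs} Hz, stride time {shape.stride_time_ms} ms)"
        )

    phases = np.asarray(shape.phases)
    base_vals = shape.extrema
    # one extra stride's extrema to close the final cosine segment
    n_ev = (n_strides + 1) * 4
    stride_idx = np.repeat(np.arange(n_strides + 1), 4)
    ev_times = (stride_idx + np.tile(phases, n_strides + 1)) * t_stride
    ev_vals = np.tile(base_vals, n_strides + 1)
    if noise.sigma_stride > 0:
        ev_vals = ev_vals + rng.normal(0.0, noise.sigma_stride, n_ev)
    if noise.time_jitter > 0:
        jit = rng.normal(0.0, noise.time_jitter * t_stride, n_ev)
        min_gap = np.min(np.diff((stride_idx + np.tile(phases, n_strides + 1))))
        np.clip(jit, -0.45 * min_gap * t_stride, 0.45 * min_gap * t_stride, out=jit)
        ev_times = ev_times + jit

    n_samples = int(round(n_strides * t_stride * fs))
    t = np.arange(n_samples) / fs
    seg = np.clip(np.searchsorted(ev_times, t, side="right") - 1, 0, n_ev - 2)
    t0, t1 = ev_times[seg], ev_times[seg + 1]
    v0, v1 = ev_vals[seg], ev_vals[seg + 1]
    u = (t - t0) / (t1 - t0)
    clean = v0 + (v1 - v0) * (1.0 - np.cos(np.pi * u)) / 2.0

    samples = clean.copy()
    if noise.drift_amp > 0:
        samples = samples + noise.drift_amp * np.sin(
            2.0 * np.pi * t / noise.drift_period_s
        )
    if noise.sigma_meas > 0:
        samples = samples + rng.normal(0.0, noise.sigma_meas, n_samples)

    # acceleration from the noise-free curve: mm -> m, twofold differentiation
    vel = np.gradient(clean / 1000.0, 1.0 / fs)
    acc = np.gradient(vel, 1.0 / fs)

    stride_ext = ev_vals[: n_strides * 4].reshape(n_strides, 4)
    metrics = _stride_metrics_from_extrema(stride_ext)
    if first_half_label == "right":
        metrics[["Dmin", "Dmax", "Dup"]] *= -1.0
    starts = np.round(ev_times[0 : n_strides * 4 : 4] * fs).astype(int)
    mids = np.round(ev_times[2 : n_strides * 4 : 4] * fs).astype(int)
    ends = np.round(ev_times[4 : (n_strides + 1) * 4 : 4] * fs).astype(int)
    metrics["stride_time_ms"] = (ends - starts) / fs * 1000.0

    truth = StrideTruth(
        start_samples=starts,
        mid_samples=mids,
        end_samples=np.minimum(ends, n_samples),
        extrema=stride_ext,
        metrics=metrics,
        first_half_label=first_half_label,
    )
    return SimulatedTrial(
        signal=LandmarkSignal(samples, fs, landmark, "displacement"),
        acceleration=LandmarkSignal(acc, fs, landmark, "acceleration"),
        truth=truth,
    )


def label_reference_from_truth(truth: StrideTruth, strides) -> str:
    """Labelling reference consistent with a recording's ground truth.

    Detected stride boundaries may start on either of the two half-cycles;
    this maps the first detected boundary onto the simulator's boundary
    grid and returns the ``label_halves`` reference that reproduces the
    true limb attribution.
    """
    first = int(strides.starts[0])
    grid = np.concatenate([truth.start_samples, truth.mid_samples])
    is_start = np.concatenate(
        [np.ones_like(truth.start_samples), np.zeros_like(truth.mid_samples)]
    )
    nearest = int(np.argmin(np.abs(grid - first)))
    if is_start[nearest]:
        label = truth.first_half_label
    else:
        label = "right" if truth.first_half_label == "left" else "left"
    return f"first_half_is_{label}"


# ---------------------------------------------------------------------------
# full study simulation


def _limb_sequence(design: StudyDesign, rng: np.random.Generator) -> Tuple[str, ...]:
    if design.first_limb_assignment is not None:
        return tuple(design.first_limb_assignment)
    # the first re-shod forelimb is chosen by coin toss per horse
    return tuple(rng.choice(LIMBS) for _ in range(design.n_horses))


def _normalized_to_raw(var: str, value: float, limb: str) -> float:
    """Undo the side normalization: the raw effect of re-shoeing ``limb``."""
    if var in ASYMMETRY_DIFF_COLUMNS and limb == "right":
        return -value
    return value


def _direction_of(condition: str, limb: str) -> str:
    if condition == "straight":
        return "straight"
    inner = "left" if condition == "left circle" else "right"
    return "inside" if limb == inner else "outside"


def simulate_normalized_diffs(
    design: StudyDesign,
    effect: VariableEffect,
    rng: np.random.Generator,
    variable: str = "value",
) -> pd.DataFrame:
    """Draw one study's side-normalized differences for a single variable.

    Generates the records directly at the level the mixed model consumes:
    one value per horse x intervention limb x exercise condition, equal to
    the true cell mean plus horse intercept, limb-within-horse intercept and
    residual noise. Used for simulation-based calibration checks of the
    statistical stage.
    """
    rows = []
    for h, horse in enumerate(design.horse_ids):
        u = rng.normal(0.0, effect.sigma_horse) if effect.sigma_horse else 0.0
        for limb in LIMBS:
            w = rng.normal(0.0, effect.sigma_limb) if effect.sigma_limb else 0.0
            for surface, condition in design.conditions:
                d = _direction_of(condition, limb)
                eps = rng.normal(0.0, effect.sigma_res) if effect.sigma_res else 0.0
                rows.append(
                    {
                        "horse_id": horse,
                        "reshod_limb": limb,
                        "surface": surface,
                        "direction": d,
                        variable: effect.cells[(surface, d)] + u + w + eps,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    """Signals plus ground truth for a full limb-by-limb study."""

    design: StudyDesign
    first_limbs: Tuple[str, ...]
    trials: Dict[tuple, Dict[str, SimulatedTrial]] = field(default_factory=dict)
    truth_summaries: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth_diffs: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_study(
    design: StudyDesign,
    effects: Optional[EffectTable] = None,
    noise: Optional[NoiseModel] = None,
    baseline_asym_sd: float = 3.0,
    rom_mm: Optional[Dict[str, float]] = None,
    with_signals: bool = True,
) -> SimulatedStudy:
    """Simulate the full study: 3 sessions x 4 conditions per horse.

    Re-shoeing the first limb shifts every condition measured in the
    'between' and 'post' sessions; re-shoeing the second limb adds a further
    shift visible from 'post' onward, so each adjacent-session difference
    isolates one limb's intervention. The true per-condition metric values
    (and the side-normalized differences they imply) are returned together
    with the signals.

    Within one stride the upward-amplitude difference is determined by the
    extrema differences (Dup = Dmax - Dmin), so the signal-level truth for
    the D*Dup variables follows from the configured D*Dmin / D*Dmax shifts.
    """
    from .types import zero_effect_table

    noise = noise or NoiseModel()
    effects = effects if effects is not None else zero_effect_table()
    rom_mm = rom_mm or dict(DEFAULT_ROM_MM)
    master = np.random.SeedSequence(noise.seed)
    rng_design, rng_effects, rng_baseline, rng_signals = (
        np.random.default_rng(s) for s in master.spawn(4)
    )
    first_limbs = _limb_sequence(design, rng_design)

    # random-effect draws on the normalized-difference scale
    u = {
        (h, v): rng_effects.normal(0.0, effects[v].sigma_horse)
        if effects[v].sigma_horse
        else 0.0
        for h in design.horse_ids
        for v in DIFF_COLUMNS
    }
    w = {
        (h, l, v): rng_effects.normal(0.0, effects[v].sigma_limb)
        if effects[v].sigma_limb
        else 0.0
        for h in design.horse_ids
        for l in LIMBS
        for v in DIFF_COLUMNS
    }

    # per-horse/condition baselines (constant across sessions; cancel in diffs)
    base = {}
    for horse in design.horse_ids:
        for surface, condition in design.conditions:
            vals = {}
            for lm in LANDMARKS:
                p = LANDMARK_PREFIX[lm]
                vals[f"{p}Dmin"] = rng_baseline.normal(0.0, baseline_asym_sd)
                vals[f"{p}Dmax"] = rng_baseline.normal(0.0, baseline_asym_sd)
                vals[f"{p}ROM"] = rom_mm[lm]
                vals[f"{p}Dup"] = vals[f"{p}Dmax"] - vals[f"{p}Dmin"]
            base[(horse, surface, condition)] = vals

    # per-record normalized-scale shifts (effect + random effects + residual)
    shift_norm = {}
    for horse in design.horse_ids:
        for limb in LIMBS:
            for surface, condition in design.conditions:
                d = _direction_of(condition, limb)
                for v in DIFF_COLUMNS:
                    eff = effects[v]
                    eps = (
                        rng_effects.normal(0.0, eff.sigma_res)
                        if eff.sigma_res
                        else 0.0
                    )
                    shift_norm[(horse, limb, surface, condition, v)] = (
                        eff.cells[(surface, d)]
                        + u[(horse, v)]
                        + w[(horse, limb, v)]
                        + eps
                    )

    # session-level true metric values: baseline + cumulated raw shifts
    sum_rows = []
    for horse in design.horse_ids:
        limb1 = first_limbs[design.horse_ids.index(horse)]
        limb2 = "right" if limb1 == "left" else "left"
        for session in design.sessions:
            shod = []
            if session in ("between", "post"):
                shod.append(limb1)
            if session == "post":
                shod.append(limb2)
            reshod = {"pre": "none", "between": limb1, "post": limb2}[session]
            for surface, condition in design.conditions:
                vals = dict(base[(horse, surface, condition)])
                for limb in shod:
                    for p in ("H", "W", "P"):
                        for m in ("Dmin", "Dmax", "ROM"):
                            v = f"D{p}{m}"
                            vals[f"{p}{m}"] += _normalized_to_raw(
                                v,
                                shift_norm[(horse, limb, surface, condition, v)],
                                limb,
                            )
                for p in ("H", "W", "P"):
                    vals[f"{p}Dup"] = vals[f"{p}Dmax"] - vals[f"{p}Dmin"]
                sum_rows.append(
                    {
                        "horse_id": horse,
                        "session": session,
                        "surface": surface,
                        "condition": condition,
                        "reshod_limb": reshod,
                        "stride_time_ms": design.stride_time_ms,
                        "n_strides": design.strides_per_condition,
                        **vals,
                    }
                )
    truth_summaries = pd.DataFrame(sum_rows)[list(SUMMARY_COLUMNS)]

    # ground-truth normalized differences implied by the session values
    diff_rows = []
    pivot = truth_summaries.set_index(["horse_id", "session", "surface", "condition"])
    for horse in design.horse_ids:
        limb1 = first_limbs[design.horse_ids.index(horse)]
        limb2 = "right" if limb1 == "left" else "left"
        for pre_s, post_s, limb in (("pre", "between", limb1), ("between", "post", limb2)):
            for surface, condition in design.conditions:
                pre = pivot.loc[(horse, pre_s, surface, condition)]
                post = pivot.loc[(horse, post_s, surface, condition)]
                rec = {
                    "horse_id": horse,
                    "reshod_limb": limb,
                    "surface": surface,
                    "direction": _direction_of(condition, limb),
                }
                for v in DIFF_COLUMNS:
                    raw = post[v[1:]] - pre[v[1:]]
                    if v in ASYMMETRY_DIFF_COLUMNS and limb == "right":
                        raw = -raw
                    rec[v] = raw
                diff_rows.append(rec)
    truth_diffs = pd.DataFrame(diff_rows)[list(DIFF_TABLE_COLUMNS)]

    study = SimulatedStudy(
        design=design,
        first_limbs=first_limbs,
        truth_summaries=truth_summaries,
        truth_diffs=truth_diffs,
    )

    if with_signals:
        for row in truth_summaries.itertuples(index=False):
            key = (row.horse_id, row.session, row.surface, row.condition)
            trial = {}
            for lm in LANDMARKS:
                p = LANDMARK_PREFIX[lm]
                shape = shape_from_metrics(
                    getattr(row, f"{p}Dmin"),
                    getattr(row, f"{p}Dmax"),
                    getattr(row, f"{p}ROM"),
                    stride_time_ms=design.stride_time_ms,
                )
                trial[lm] = simulate_stride_signal(
                    shape,
                    design.strides_per_condition,
                    noise=noise,
                    fs=design.fs,
                    landmark=lm,
                    rng=rng_signals,
                )
            study.trials[key] = trial
        logger.info(
            "simulated study: %d horses, %d trials, seed %d",
            design.n_horses,
            len(study.trials),
            noise.seed,
        )
    return study
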