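"""Domain types and table schemas shared across the pipeline.

Units follow the conventions of equine upper-body symmetry analysis:
displacements in millimetres, accelerations in m/s^2, stride times in
milliseconds, sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

LANDMARKS = ("head", "withers", "pelvis")
LANDMARK_PREFIX = {"head": "H", "withers": "W", "pelvis": "P"}
METRIC_NAMES = ("Dmin", "Dmax", "Dup", "ROM")

#: per-landmark metric columns in canonical order (HDmin ... PROM)
SUMMARY_METRIC_COLUMNS = tuple(
    f"{p}{m}" for p in ("H", "W", "P") for m in METRIC_NAMES
)
SUMMARY_COLUMNS = (
    "horse_id",
    "session",
    "surface",
    "condition",
    "reshod_limb",
    "stride_time_ms",
    "n_strides",
) + SUMMARY_METRIC_COLUMNS

#: pre/post difference variables (DHDmin ... DPROM)
DIFF_COLUMNS = tuple("D" + c for c in SUMMARY_METRIC_COLUMNS)
ASYMMETRY_DIFF_COLUMNS = tuple(c for c in DIFF_COLUMNS if not c.endswith("ROM"))
ROM_DIFF_COLUMNS = tuple(c for c in DIFF_COLUMNS if c.endswith("ROM"))
DIFF_TABLE_COLUMNS = ("horse_id", "reshod_limb", "surface", "direction") + DIFF_COLUMNS

SESSIONS = ("pre", "between", "post")
SURFACES = ("hard", "soft")
CONDITIONS = ("straight", "left circle", "right circle")
DIRECTIONS = ("inside", "outside", "straight")
LIMBS = ("left", "right")

#: test-retest repeatability 95% thresholds (mm) used by the pooling check;
#: withers uses the more stringent pelvic value because no published
#: withers-specific repeatability threshold exists.
REPEATABILITY_THRESHOLD_MM = {"H": 6.0, "W": 3.0, "P": 3.0}


def threshold_for(diff_variable: str) -> float:
    """Repeatability threshold (mm) for a difference variable such as 'DHDmin'."""
    prefix = diff_variable[1]
    if diff_variable[0] != "D" or prefix not in REPEATABILITY_THRESHOLD_MM:
        raise ValueError(f"not a difference variable: {diff_variable!r}")
    return REPEATABILITY_THRESHOLD_MM[prefix]


@dataclass
class LandmarkSignal:
    """One landmark's vertical kinematic time series.

    Parameters
    ----------
    samples : ndarray
        Displacement in mm (``kind='displacement'``) or vertical
        acceleration in m/s^2 (``kind='acceleration'``).
    fs : float
        Sampling rate in Hz.
    landmark : str
        One of ``head``, ``withers``, ``pelvis``.
    kind : str
        ``displacement`` or ``acceleration``.
    """

    samples: np.ndarray
    fs: float
    landmark: str = "pelvis"
    kind: str = "displacement"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.landmark not in LANDMARKS:
            raise ValueError(f"unknown landmark {self.landmark!r}")
        if self.kind not in ("displacement", "acceleration"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class StrideShape:
    """Noise-free extrema of one trot stride's vertical displacement.

    A trot stride contains two vertical oscillations; the stride is anchored
    at a displacement minimum, so the extremum sequence within one cycle is
    ``min1, max1, min2, max2`` at the given ``phases`` (fractions of the
    stride). The first half-cycle holds (min1, max1), the second (min2, max2).
    All values in mm, stride time in ms.
    """

    min1: float
    max1: float
    min2: float
    max2: float
    stride_time_ms: float = 720.0
    phases: tuple = (0.0, 0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        vals = (self.min1, self.max1, self.min2, self.max2, self.stride_time_ms)
        if not np.all(np.isfinite(vals)):
            raise ValueError("stride shape values must be finite")
        if not (self.max1 > self.min1 and self.max2 > self.min2):
            raise ValueError("each half-cycle maximum must exceed its minimum")
        if self.stride_time_ms <= 0:
            raise ValueError("stride time must be positive")
        p = np.asarray(self.phases, dtype=float)
        if p.size != 4 or np.any(np.diff(p) <= 0) or p[0] < 0 or p[-1] >= 1:
            raise ValueError("phases must be strictly increasing within [0, 1)")

    @property
    def extrema(self) -> np.ndarray:
        """Extrema values in phase order (min1, max1, min2, max2)."""
        return np.array([self.min1, self.max1, self.min2, self.max2])

    # closed-form single-stride metrics (first half labelled 'left')
    @property
    def dmin(self) -> float:
        return self.min1 - self.min2

    @property
    def dmax(self) -> float:
        return self.max1 - self.max2

    @property
    def dup(self) -> float:
        return (self.max1 - self.min1) - (self.max2 - self.min2)

    @property
    def rom(self) -> float:
        return max(self.max1, self.max2) - min(self.min1, self.min2)


@dataclass
class NoiseModel:
    """Stochastic components of a simulated recording.

    sigma_stride
        SD (mm) of per-stride, per-extremum jitter of the extrema values.
    sigma_meas
        SD (mm) of additive white measurement noise per sample.
    drift_amp, drift_period_s
        Amplitude (mm) and period (s) of a slow sinusoidal baseline drift.
    time_jitter
        SD of extremum-time jitter as a fraction of the stride time.
    seed
        Seed of the generator; fully determines the realisation.
    """

    sigma_stride: float = 0.0
    sigma_meas: float = 0.0
    drift_amp: float = 0.0
    drift_period_s: float = 10.0
    time_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_stride", "sigma_meas", "drift_amp", "time_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")


@dataclass
class StudyDesign:
    """The limb-by-limb re-shoeing study layout.

    Ten horses, both forelimbs re-shod one at a time (order randomized per
    horse), three gait assessments (pre / between / post) and four exercise
    conditions per assessment.
    """

    n_horses: int = 10
    sessions: tuple = SESSIONS
    conditions: tuple = (
        ("hard", "straight"),
        ("soft", "straight"),
        ("soft", "left circle"),
        ("soft", "right circle"),
    )
    strides_per_condition: int = 30
    first_limb_assignment: Optional[Sequence[str]] = None
    stride_time_ms: float = 720.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.n_horses < 1:
            raise ValueError("need at least one horse")
        if self.strides_per_condition < 1:
            raise ValueError("need at least one stride per condition")
        if self.first_limb_assignment is not None:
            fla = tuple(self.first_limb_assignment)
            if len(fla) != self.n_horses or any(l not in LIMBS for l in fla):
                raise ValueError(
                    "first_limb_assignment must give 'left'/'right' per horse"
                )
            self.first_limb_assignment = fla

    @property
    def horse_ids(self) -> tuple:
        return tuple(f"H{i + 1:02d}" for i in range(self.n_horses))


@dataclass
class VariableEffect:
    """True effect structure for one difference variable (mm scale).

    ``cells`` maps (surface, direction) to the true mean of the
    side-normalized pre/post difference; the random structure mirrors the
    mixed model used in the analysis (horse intercept, limb-within-horse
    intercept, residual).
    """

    cells: dict
    sigma_horse: float = 0.0
    sigma_limb: float = 0.0
    sigma_res: float = 0.0

    def __post_init__(self) -> None:
        for v in self.cells.values():
            if not np.isfinite(v):
                raise ValueError("cell effects must be finite")
        for name in ("sigma_horse", "sigma_limb", "sigma_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: mapping of difference-variable name -> VariableEffect
EffectTable = dict


def zero_effect_table(sigma_horse=0.0, sigma_limb=0.0, sigma_res=0.0) -> EffectTable:
    """Effect table with all true shifts zero (null study)."""
    cells = {
        ("hard", "straight"): 0.0,
        ("soft", "straight"): 0.0,
        ("soft", "inside"): 0.0,
        ("soft", "outside"): 0.0,
    }
    return {
        v: VariableEffect(dict(cells), sigma_horse, sigma_limb, sigma_res)
        for v in DIFF_COLUMNS
    }


@dataclass
class StrideSet:
    """Segmented stride cycles of one recording.

    Strides run from one displacement minimum to the second-next one; the
    intervening minimum splits the stride into its two half-cycles. Half
    labels alternate, so the limb attribution of every half follows from
    ``first_half_label``.
    """

    starts: np.ndarray
    mids: np.ndarray
    ends: np.ndarray
    fs: float
    first_half_label: Optional[str] = None
    label_source: Optional[str] = None
    stride_frequency_hz: Optional[float] = None
    discarded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.mids = np.asarray(self.mids, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        n = self.starts.size
        if not (self.mids.size == n and self.ends.size == n):
            raise ValueError("starts, mids and ends must have equal length")
        if n and not (
            np.all(self.starts < self.mids) and np.all(self.mids < self.ends)
        ):
            raise ValueError("stride boundaries must be strictly increasing")
        if self.first_half_label is not None and self.first_half_label not in LIMBS:
            raise ValueError("first_half_label must be 'left' or 'right'")

    @property
    def n_strides(self) -> int:
        return self.starts.size

    @property
    def stride_times_ms(self) -> np.ndarray:
        return (self.ends - self.starts) / self.fs * 1000.0

    @property
    def half_labels(self) -> np.ndarray:
        """Limb label of each half-cycle, two per stride."""
        if self.first_half_label is None:
            raise ValueError("halves are unlabelled; call label_halves first")
        other = "right" if self.first_half_label == "left" else "left"
        return np.array([self.first_half_label, other] * self.n_strides)
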