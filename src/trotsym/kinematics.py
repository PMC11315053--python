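"""Vertical displacement from vertical acceleration.

Twofold numerical integration of an accelerometer trace diverges unless the
low-frequency content is removed, so the signal is high-pass filtered before
and after each integration stage with a zero-phase Butterworth filter. The
cutoff is tied to the stride frequency so that the two-oscillations-per-
stride content of trot is preserved while integration drift is suppressed.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .types import LandmarkSignal


def _highpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def displacement_from_acceleration(
    signal: LandmarkSignal,
    stride_freq_hint: float,
    cutoff_factor: float = 0.5,
    edge_trim_cycles: float = 3.0,
) -> LandmarkSignal:
    """Reconstruct vertical displacement (mm) from acceleration (m/s^2).

    Parameters
    ----------
    signal : LandmarkSignal
        Vertical acceleration with the gravity component already removed.
    stride_freq_hint : float
        Approximate stride frequency in Hz (about 1.4 Hz for trot). The
        high-pass cutoff is ``cutoff_factor * stride_freq_hint``.
    edge_trim_cycles : float
        Cutoff-frequency cycles discarded at each end of the output, where
        the zero-phase filter and integration transients concentrate (the
        settling time scales with the cutoff period, not the stride).

    Returns
    -------
    LandmarkSignal
        Zero-mean displacement in mm, shortened by the edge trim.
    """
    if signal.kind != "acceleration":
        raise ValueError("input signal must be an acceleration trace")
    if stride_freq_hint <= 0:
        raise ValueError("stride_freq_hint must be positive")
    fs = signal.fs
    if fs < 4.0 * stride_freq_hint:
        raise ValueError(
            f"sampling rate {fs} Hz is below 4x the stride frequency "
            f"{stride_freq_hint} Hz; aliasing risk"
        )
    cutoff = cutoff_factor * stride_freq_hint
    dt = 1.0 / fs

    acc = _highpass(signal.samples, fs, cutoff)
    vel = _highpass(cumulative_trapezoid(acc, dx=dt, initial=0.0), fs, cutoff)
    disp = _highpass(cumulative_trapezoid(vel, dx=dt, initial=0.0), fs, cutoff)

    disp_mm = disp * 1000.0
    trim = int(round(edge_trim_cycles * fs / cutoff))
    if trim > 0:
        if 2 * trim >= disp_mm.size:
            raise ValueError("signal too short for the requested edge trim")
        disp_mm = disp_mm[trim:-trim]
    disp_mm = disp_mm - disp_mm.mean()
    return LandmarkSignal(disp_mm, fs, signal.landmark, "displacement")
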