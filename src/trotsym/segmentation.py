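"""Stride segmentation of continuous vertical displacement signals.

Trot produces two vertical oscillations per stride. The dominant
oscillation frequency is estimated from the spectrum; stride cycles are
then delimited at alternate displacement minima, and the intervening
minimum splits each stride into its two half-cycles. Limb identity of the
halves cannot be derived from a single vertical trace, so it is attached
explicitly via :func:`label_halves`.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .types import LandmarkSignal, LIMBS, StrideSet

logger = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when no periodic gait pattern can be identified."""


def dominant_stride_frequency(
    signal: LandmarkSignal,
    band_hz: tuple = (1.0, 6.0),
    snr_min: float = 10.0,
) -> float:
    """Estimate the stride frequency (Hz) from the displacement spectrum.

    The dominant spectral peak within ``band_hz`` is taken as the
    oscillation frequency (two oscillations per stride in trot), refined by
    parabolic interpolation of the log power spectrum. If substantial power
    sits at twice the peak frequency, the peak is interpreted as the stride
    fundamental of an asymmetric gait and the harmonic is used instead.

    Raises
    ------
    SegmentationError
        If the spectrum has no dominant peak (flat or noise-only signal).
    """
    x = signal.samples - signal.samples.mean()
    n = x.size
    if n < 64:
        raise SegmentationError("signal too short for spectral analysis")
    nperseg = min(n, max(256, n // 4))
    freqs, psd = sps.welch(x, fs=signal.fs, nperseg=nperseg)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if band.sum() < 5:
        raise SegmentationError("analysis band too narrow for this record")
    f_band, p_band = freqs[band], psd[band]
    k = int(np.argmax(p_band))
    floor = np.median(p_band)
    if floor <= 0 or p_band[k] / floor < snr_min:
        raise SegmentationError(
            "no dominant oscillation frequency found; the signal does not "
            "look like periodic gait"
        )

    def _refine(fgrid, pgrid, i):
        if 0 < i < pgrid.size - 1 and pgrid[i - 1] > 0 and pgrid[i + 1] > 0:
            la, lb, lc = np.log(pgrid[i - 1 : i + 2])
            denom = la - 2 * lb + lc
            if denom < 0:
                shift = 0.5 * (la - lc) / denom
                return fgrid[i] + shift * (fgrid[1] - fgrid[0])
        return fgrid[i]

    f_osc = _refine(f_band, p_band, k)

    # if a comparable peak exists at ~2*f_osc, f_osc is the stride
    # fundamental of an asymmetric signal; the oscillation is the harmonic
    harm = 2.0 * f_osc
    if harm <= freqs[-1]:
        j = int(np.argmin(np.abs(freqs - harm)))
        window = psd[max(j - 2, 0) : j + 3]
        if window.max() >= 0.5 * p_band[k]:
            jj = max(j - 2, 0) + int(np.argmax(window))
            f_osc = _refine(freqs, psd, jj)
    return f_osc / 2.0


def segment_strides(
    signal: LandmarkSignal,
    outlier_frac: float = 0.25,
    band_hz: tuple = (1.0, 6.0),
    snr_min: float = 10.0,
) -> StrideSet:
    """Segment a displacement signal into stride cycles.

    Displacement minima are detected on a band-pass filtered copy of the
    signal and refined to the local minimum of the raw samples (earliest
    index on ties). Strides run between alternate minima; strides whose
    duration deviates more than ``outlier_frac`` from the median stride
    time are discarded and logged.
    """
    if signal.kind != "displacement":
        raise ValueError("segmentation expects a displacement signal")
    f_stride = dominant_stride_frequency(signal, band_hz=band_hz, snr_min=snr_min)
    f_osc = 2.0 * f_stride
    fs = signal.fs
    x = signal.samples - signal.samples.mean()

    lo, hi = 0.4 * f_osc, min(1.6 * f_osc, 0.45 * fs)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    smooth = sps.sosfiltfilt(sos, x)
    min_dist = max(int(0.7 * fs / f_osc), 1)
    peaks, _ = sps.find_peaks(-smooth, distance=min_dist)
    if peaks.size < 3:
        raise SegmentationError("fewer than three displacement minima detected")

    # refine each minimum on the raw signal; argmin takes the earliest index
    half_win = max(int(0.15 * fs / f_osc), 1)
    minima = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        a, b = max(p - half_win, 0), min(p + half_win + 1, x.size)
        minima[i] = a + int(np.argmin(signal.samples[a:b]))
    minima = np.unique(minima)

    n = (minima.size - 1) // 2
    if n < 1:
        raise SegmentationError("not enough minima for a full stride")
    starts = minima[0 : 2 * n : 2]
    mids = minima[1 : 2 * n : 2]
    ends = minima[2 : 2 * n + 1 : 2]

    times_ms = (ends - starts) / fs * 1000.0
    med = np.median(times_ms)
    keep = np.abs(times_ms - med) <= outlier_frac * med
    discarded = []
    for i in np.nonzero(~keep)[0]:
        discarded.append(
            {"stride_idx": int(i), "stride_time_ms": float(times_ms[i])}
        )
        logger.info(
            "discarding stride %d: duration %.1f ms deviates >%.0f%% from "
            "median %.1f ms",
            i,
            times_ms[i],
            100 * outlier_frac,
            med,
        )
    return StrideSet(
        starts=starts[keep],
        mids=mids[keep],
        ends=ends[keep],
        fs=fs,
        stride_frequency_hz=f_stride,
        discarded=discarded,
    )


def label_halves(
    strides: StrideSet,
    reference: Union[str, Sequence[str]] = "first_half_is_left",
) -> StrideSet:
    """Attach limb labels to the stride halves.

    ``reference`` is either ``'first_half_is_left'`` /
    ``'first_half_is_right'`` or an explicit per-half label sequence (two
    labels per stride, e.g. from simulation ground truth), which must
    alternate consistently.
    """
    if strides.n_strides < 1:
        raise ValueError("cannot label an empty stride set")
    if isinstance(reference, str):
        if reference == "first_half_is_left":
            first = "left"
        elif reference == "first_half_is_right":
            first = "right"
        else:
            raise ValueError(f"unknown labelling reference {reference!r}")
        source = reference
    else:
        labels = list(reference)
        if len(labels) != 2 * strides.n_strides:
            raise ValueError("need exactly two labels per stride")
        if any(l not in LIMBS for l in labels):
            raise ValueError("labels must be 'left' or 'right'")
        if any(labels[i] == labels[i + 1] for i in range(len(labels) - 1)):
            raise ValueError("half labels must alternate")
        first = labels[0]
        source = "external_labels"
    return StrideSet(
        starts=strides.starts,
        mids=strides.mids,
        ends=strides.ends,
        fs=strides.fs,
        first_half_label=first,
        label_source=source,
        stride_frequency_hz=strides.stride_frequency_hz,
        discarded=list(strides.discarded),
    )
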