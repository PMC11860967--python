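"""Threshold spike detection on raw extracellular voltage traces.

The detection rule: a spike is a negative-going excursion of the (bandpass
filtered) trace beyond 6.5 times the standard deviation of baseline noise.
The stages are separable — :func:`bandpass_filter` (zero-phase, 4–4000 Hz),
:func:`estimate_noise_sd` (MAD-based, robust to spikes) and
:func:`detect_spikes` (threshold crossings, timestamp at the extremum,
refractory merging) — and composed by :func:`detect_session`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import SpikeTrain

__all__ = [
    "DetectorParams",
    "bandpass_filter",
    "estimate_noise_sd",
    "detect_spikes",
    "detect_trace",
]

#: MAD-to-SD factor for Gaussian noise: 1 / Phi^{-1}(3/4).
_MAD_SCALE = 1.4826022185056018


@dataclass(frozen=True)
class DetectorParams:
    """Spike-detection parameters.

    ``threshold_multiple``: detection threshold in multiples of the baseline
    noise SD (default 6.5); ``bandpass_low``/``bandpass_high``: passband in Hz
    (defaults 4 and 4000); ``refractory``: events closer than this are merged
    to the first (default 1 ms); ``fs``: sampling rate in Hz (default 10 kHz).
    """

    threshold_multiple: float = 6.5
    bandpass_low: float = 4.0
    bandpass_high: float = 4000.0
    refractory: float = 0.001
    fs: float = 10000.0
    polarity: str = "negative"  # or "both" for absolute-value detection

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high < self.fs / 2:
            raise ValueError("need 0 < bandpass_low < bandpass_high < fs/2")
        if self.threshold_multiple <= 0:
            raise ValueError("threshold_multiple must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.polarity not in ("negative", "both"):
            raise ValueError("polarity must be 'negative' or 'both'")


def bandpass_filter(trace: np.ndarray, params: DetectorParams = DetectorParams()) -> np.ndarray:
    """Zero-phase Butterworth bandpass of the raw trace (same length).

    Zero-phase (forward-backward) filtering introduces no latency, so spike
    timestamps are not systematically shifted.
    """
    trace = np.asarray(trace, dtype=np.float64)
    sos = signal.butter(
        2,
        [params.bandpass_low, params.bandpass_high],
        btype="bandpass",
        fs=params.fs,
        output="sos",
    )
    return signal.sosfiltfilt(sos, trace)


def estimate_noise_sd(
    trace: np.ndarray,
    calibration_window: tuple[float, float] | None = None,
    fs: float = 10000.0,
) -> float:
    """Robust baseline-noise SD via the median absolute deviation.

    ``calibration_window`` is an optional ``(start_s, end_s)`` window; by
    default the whole trace is used.  The MAD is scaled to the SD of a
    Gaussian, so sparse large spikes barely perturb the estimate.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if calibration_window is not None:
        lo, hi = (int(round(x * fs)) for x in calibration_window)
        trace = trace[lo:hi]
    if trace.size == 0:
        raise ValueError("empty calibration window")
    return float(_MAD_SCALE * np.median(np.abs(trace - np.median(trace))))


def detect_spikes(
    trace: np.ndarray,
    params: DetectorParams = DetectorParams(),
    noise_sd: float | None = None,
    electrode_id: str = "e",
) -> SpikeTrain:
    """Threshold-crossing spike detection on an (already filtered) trace.

    A spike epoch is a maximal run of samples at or beyond
    ``-threshold_multiple * noise_sd`` (negative-going by default); its
    timestamp is the most extreme sample of the epoch.  Events closer than
    the refractory period are merged to the first.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace, fs=params.fs)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0 (constant/degenerate trace?)")
    thr = params.threshold_multiple * noise_sd
    score = -trace if params.polarity == "negative" else np.abs(trace)
    over = score >= thr
    duration = trace.size / params.fs
    if not over.any():
        return SpikeTrain(electrode_id, np.empty(0), duration)
    # epoch boundaries: starts where over flips on, ends where it flips off
    edges = np.diff(over.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if over[0]:
        starts = np.r_[0, starts]
    if over[-1]:
        ends = np.r_[ends, over.size]
    peaks = np.array(
        [s + np.argmax(score[s:e]) for s, e in zip(starts, ends)], dtype=np.int64
    )
    times = peaks / params.fs
    if params.refractory > 0 and times.size > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= params.refractory:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(electrode_id, times, duration)


def detect_trace(
    trace: np.ndarray,
    params: DetectorParams = DetectorParams(),
    electrode_id: str = "e",
    calibration_window: tuple[float, float] | None = None,
) -> SpikeTrain:
    """Full detection chain: bandpass filter, estimate noise SD, threshold."""
    filtered = bandpass_filter(trace, params)
    sd = estimate_noise_sd(filtered, calibration_window, fs=params.fs)
    return detect_spikes(filtered, params, sd, electrode_id)
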