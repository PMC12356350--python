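"""Rhythm-strip to median-beat preprocessing.

Pipeline: detect R peaks on one lead (Pan-Tompkins-style energy detector),
extract fixed windows around each peak, take the per-sample median across
beats, and remove baseline wander by subtracting a per-lead least-squares
first-order polynomial.  A QRS weight mask (default weight 10 inside the
QRS window, 1 elsewhere) feeds the representation-learning loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ECGRecord, MedianBeat

#: default median-beat extraction window around the R peak, milliseconds
DEFAULT_WINDOW_MS = (300.0, 900.0)
REFRACTORY_S = 0.2


@dataclass
class WeightMask:
    """Per-sample loss weights: ``qrs_weight`` inside [onset, offset), 1 outside."""

    weights: np.ndarray
    qrs_window: tuple
    qrs_weight: float = 10.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        on, off = self.qrs_window
        if not (0 <= on < off <= self.weights.size):
            raise ValueError(f"invalid qrs_window {self.qrs_window}")


def detect_r_peaks(record: ECGRecord, lead: str = "II") -> list[int]:
    """R-peak sample indices via bandpass -> differentiate -> square ->
    integrate -> threshold, refined to the local extremum of the raw lead.

    A flat or sub-threshold signal yields an empty list and a warning, not
    an exception.  Peaks are sorted and separated by a 200-ms refractory.
    """
    if record.duration < 2.0:
        raise ValueError("record must be at least 2 s long")
    fs = record.sampling_rate
    x = record.samples[record.lead_names.index(lead)]
    if np.ptp(x) < 1e-12:
        warnings.warn("flat signal: no R peaks detected", stacklevel=2)
        return []

    # zero-phase 5-18 Hz bandpass keeps QRS energy, drops P/T and drift
    sos = sps.butter(2, [5.0, 18.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.convolve(bp ** 2, np.ones(int(0.15 * fs)) / int(0.15 * fs),
                         mode="same")
    threshold = 0.3 * np.percentile(energy, 99)
    if threshold <= 0:
        warnings.warn("no QRS energy above threshold", stacklevel=2)
        return []

    above = energy > threshold
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above[0]:
        edges = np.concatenate(([0], edges))
    refractory = int(REFRACTORY_S * fs)
    half = int(0.08 * fs)
    peaks: list[int] = []
    for start in edges:
        stop = start
        while stop < x.size and above[stop]:
            stop += 1
        center = start + int(np.argmax(energy[start:stop])) if stop > start else start
        lo = max(0, center - half)
        hi = min(x.size, center + half + 1)
        # R is the dominant absolute deflection within the QRS burst
        idx = lo + int(np.argmax(np.abs(bp[lo:hi])))
        lo2, hi2 = max(0, idx - 3), min(x.size, idx + 4)
        idx = lo2 + int(np.argmax(np.abs(x[lo2:hi2])))
        if peaks and idx - peaks[-1] < refractory:
            continue
        peaks.append(idx)
    if not peaks:
        warnings.warn("no R peaks detected", stacklevel=2)
    return peaks


def compute_median_beat(
    record: ECGRecord,
    peaks,
    window_ms: tuple = DEFAULT_WINDOW_MS,
) -> MedianBeat:
    """Per-lead, per-sample median across beat windows aligned on R peaks.

    Beats whose window would be truncated by the record edges are dropped.
    With an even number of usable beats the median is the mean of the two
    middle order statistics (numpy convention).  Fewer than 3 usable beats
    is an error naming the count.
    """
    fs = record.sampling_rate
    pre = int(round(window_ms[0] / 1000.0 * fs))
    post = int(round(window_ms[1] / 1000.0 * fs))
    usable = [p for p in peaks if p - pre >= 0 and p + post <= record.n_samples]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 usable beats, got {len(usable)} "
            f"(of {len(list(peaks))} detected)"
        )
    stack = np.stack([record.samples[:, p - pre:p + post] for p in usable])
    return MedianBeat(np.median(stack, axis=0), fs, r_peak_index=pre)


def remove_baseline(beat: MedianBeat) -> MedianBeat:
    """Subtract the per-lead least-squares first-order polynomial (line)."""
    t = np.arange(beat.n_samples, dtype=float)
    # vandermonde least squares per lead, vectorized
    coefs = np.polynomial.polynomial.polyfit(t, beat.samples.T, deg=1)
    fitted = np.polynomial.polynomial.polyval(t, coefs)
    return MedianBeat(beat.samples - fitted, beat.sampling_rate,
                      beat.r_peak_index, beat.lead_names)


def qrs_weight_mask(
    n_samples: int | MedianBeat,
    qrs_window: tuple,
    qrs_weight: float = 10.0,
) -> WeightMask:
    """Length-T weight vector: ``qrs_weight`` in [on, off), 1 elsewhere."""
    T = n_samples.n_samples if isinstance(n_samples, MedianBeat) else int(n_samples)
    on, off = qrs_window
    if not (0 <= on < off <= T):
        raise ValueError(f"invalid qrs_window {qrs_window} for T={T}")
    w = np.ones(T)
    w[on:off] = qrs_weight
    return WeightMask(w, (on, off), qrs_weight)


def qrs_window_from_params(
    beat: MedianBeat,
    qrs_duration_ms: float | None = None,
) -> tuple:
    """QRS [onset, offset) around the R peak; default a 100-ms window when
    the true QRS duration is unknown."""
    fs = beat.sampling_rate
    dur = 100.0 if qrs_duration_ms is None else qrs_duration_ms
    half = int(round(dur / 2000.0 * fs))
    on = max(0, beat.r_peak_index - half)
    off = min(beat.n_samples, beat.r_peak_index + half)
    return (on, off)


def preprocess_record(
    record: ECGRecord,
    window_ms: tuple = DEFAULT_WINDOW_MS,
    lead: str = "II",
) -> MedianBeat:
    """detect -> median -> baseline-correct, the full strip-to-beat path."""
    peaks = detect_r_peaks(record, lead=lead)
    return remove_baseline(compute_median_beat(record, peaks, window_ms))
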