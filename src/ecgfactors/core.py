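"""Core data containers shared across the pipeline.

Conventions used throughout the package: signal amplitudes in millivolts,
time in seconds unless a name says otherwise (``*_ms``), sample indices
0-based, windows half-open ``[on, off)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Standard 12-lead order used everywhere in the package.
LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Frontal-plane angle of each limb lead, degrees (Einthoven/Goldberger).
LIMB_LEAD_ANGLES = {
    "I": 0.0, "II": 60.0, "III": 120.0,
    "aVR": -150.0, "aVL": -30.0, "aVF": 90.0,
}

#: Fixed per-lead gain applied to the horizontal (precordial) component of
#: each wave.  Chosen to mimic normal R-progression V1..V6.
PRECORDIAL_GAINS = {
    "V1": -0.35, "V2": -0.15, "V3": 0.2,
    "V4": 0.65, "V5": 0.95, "V6": 0.75,
}

WAVE_NAMES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth generative factors of one synthetic ECG.

    Doubles as the record's table of traditional ECG parameters
    (ventricular rate, PR, QRS, QT, and the three frontal-plane axes).
    """

    ventricular_rate: float  # beats/min
    pr_interval: float       # ms, P onset -> QRS onset
    qrs_duration: float      # ms
    qt_interval: float       # ms, QRS onset -> T offset
    p_axis: float            # degrees, (-180, 180]
    r_axis: float
    t_axis: float
    wave_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"P": 0.15, "Q": -0.1, "R": 1.0, "S": -0.25, "T": 0.35}
    )
    baseline_slope: float = 0.0   # mV/s, rhythm strips only
    baseline_offset: float = 0.0  # mV
    noise_sd: float = 0.0         # mV

    def __post_init__(self) -> None:
        vals = [self.ventricular_rate, self.pr_interval, self.qrs_duration,
                self.qt_interval, self.p_axis, self.r_axis, self.t_axis,
                self.baseline_slope, self.baseline_offset, self.noise_sd,
                *self.wave_amplitudes.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("GenerativeParams fields must be finite")
        if self.ventricular_rate <= 0:
            raise ValueError("ventricular_rate must be positive")
        if self.pr_interval < 40:
            raise ValueError("pr_interval must be >= 40 ms")
        if self.qrs_duration <= 0:
            raise ValueError("qrs_duration must be positive")
        if self.qt_interval <= self.qrs_duration:
            raise ValueError("qt_interval must exceed qrs_duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = set(WAVE_NAMES) - set(self.wave_amplitudes)
        if missing:
            raise ValueError(f"wave_amplitudes missing components: {sorted(missing)}")

    def replace(self, **changes) -> "GenerativeParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        d = {
            "ventricular_rate": self.ventricular_rate,
            "pr_interval": self.pr_interval,
            "qrs_duration": self.qrs_duration,
            "qt_interval": self.qt_interval,
            "p_axis": self.p_axis,
            "r_axis": self.r_axis,
            "t_axis": self.t_axis,
        }
        for w in WAVE_NAMES:
            d[f"amp_{w}"] = float(self.wave_amplitudes[w])
        d["baseline_slope"] = self.baseline_slope
        d["baseline_offset"] = self.baseline_offset
        d["noise_sd"] = self.noise_sd
        return d


@dataclass
class MedianBeat:
    """One aligned representative cardiac cycle, 12 leads by T samples (mV)."""

    samples: np.ndarray
    sampling_rate: float = 500.0
    r_peak_index: int = 150
    lead_names: tuple = LEAD_NAMES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.lead_names):
            raise ValueError(
                f"samples must be {len(self.lead_names)}xT, got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (0 <= self.r_peak_index < self.samples.shape[1]):
            raise ValueError("r_peak_index out of range")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds, 0 at the R peak."""
        idx = np.arange(self.n_samples)
        return (idx - self.r_peak_index) / self.sampling_rate

    def copy(self) -> "MedianBeat":
        return MedianBeat(self.samples.copy(), self.sampling_rate,
                          self.r_peak_index, self.lead_names)


@dataclass
class ECGRecord:
    """A raw multi-beat rhythm strip, 12 leads by N samples (mV)."""

    samples: np.ndarray
    sampling_rate: float = 500.0
    duration: float = 10.0
    lead_names: tuple = LEAD_NAMES
    #: ground-truth R-peak sample indices when produced by the simulator
    true_r_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_expected = int(round(self.duration * self.sampling_rate))
        if self.samples.shape != (len(self.lead_names), n_expected):
            raise ValueError(
                f"samples must be {len(self.lead_names)}x{n_expected}, "
                f"got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]
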