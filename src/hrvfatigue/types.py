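"""Core in-memory containers for ECG traces, RR tachograms and HRV summaries.

Conventions
-----------
* RR intervals and beat times are in milliseconds; beat times are relative to
  the start of the recording (``t0`` of the source ECG, or 0 for synthetic
  series).
* Sample indexing is 0-based.
* ``math.nan`` is the undefined-value marker throughout (never ``inf``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import HRVError, InsufficientDataError

__all__ = [
    "ECGRecord",
    "RPeakList",
    "RRSeries",
    "UniformTachogram",
    "TimeDomainSummary",
    "PSDEstimate",
    "SpectralSummary",
    "PoincareSummary",
    "SampEnResult",
]


@dataclass
class ECGRecord:
    """Single-channel sampled ECG trace.

    Parameters
    ----------
    samples : array of float
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise HRVError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 2:
            raise HRVError("an ECG record needs at least 2 samples")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (absolute, including t0)."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class RPeakList:
    """Detected R peaks: sample indices, times (ms from t0) and amplitudes."""

    indices: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (self.indices.size == self.times.size == self.amplitudes.size):
            raise HRVError("indices, times and amplitudes must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise HRVError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class RRSeries:
    """Beat-to-beat interval series (the tachogram).

    ``intervals[i]`` is the time in ms between beats ``i`` and ``i+1``;
    ``beat_times`` has length ``N + 1`` and ``intervals`` equals its
    successive differences. ``amplitudes`` optionally carries the R-peak
    amplitude at each beat (length ``N + 1``).
    """

    intervals: np.ndarray
    beat_times: np.ndarray | None = None
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise HRVError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise HRVError("all RR intervals must be positive")
        if self.beat_times is None:
            self.beat_times = np.concatenate(([0.0], np.cumsum(self.intervals)))
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if self.beat_times.size != self.intervals.size + 1:
                raise HRVError("beat_times must have length N + 1")
            if not np.allclose(np.diff(self.beat_times), self.intervals):
                raise HRVError("intervals must equal successive beat_times differences")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.size != self.beat_times.size:
                raise HRVError("amplitudes must have one value per beat (N + 1)")

    @property
    def n(self) -> int:
        """Number of intervals."""
        return self.intervals.size

    @property
    def duration_ms(self) -> float:
        return float(self.intervals.sum())


@dataclass
class UniformTachogram:
    """RR tachogram resampled onto a uniform time grid (for spectral analysis)."""

    values: np.ndarray       # ms
    rate: float              # Hz
    t_start: float           # ms, time of first grid point
    mean_removed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TimeDomainSummary:
    """The eight standard time-domain HRV statistics plus counts."""

    mean_rr: float      # ms
    mean_hr: float      # beats/min
    sdnn: float         # ms, population SD of intervals
    rmssd: float        # ms
    sdsd: float         # ms, population SD of successive differences
    cv: float           # dimensionless fraction, SDNN / meanRR
    pnn20: float        # %
    pnn50: float        # %
    nn20: int
    nn50: int
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "meanRR": self.mean_rr,
            "meanHR": self.mean_hr,
            "SDNN": self.sdnn,
            "RMSSD": self.rmssd,
            "SDSD": self.sdsd,
            "CV": self.cv,
            "PNN20": self.pnn20,
            "PNN50": self.pnn50,
        }


@dataclass
class PSDEstimate:
    """One-sided power spectral density of the tachogram, in ms^2/Hz."""

    freqs: np.ndarray
    density: np.ndarray
    method: str                 # "welch" or "ar"
    resample_rate: float        # Hz
    detrend: str = "linear"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)


@dataclass
class SpectralSummary:
    """Band powers of the RR spectrum and derived indices.

    Normalized powers use the LF+HF denominator (VLF excluded), the standard
    short-term HRV convention, so ``lf_norm + hf_norm == 1`` whenever
    LF+HF > 0. ``lf_hf`` is NaN when HF power is exactly zero.
    """

    vlf_power: float
    lf_power: float
    hf_power: float
    total_power: float
    vlf_percent: float
    lf_percent: float
    hf_percent: float
    lf_norm: float
    hf_norm: float
    lf_hf: float

    def as_dict(self) -> dict[str, float]:
        return {
            "VLF percent": self.vlf_percent,
            "LF percent": self.lf_percent,
            "HF percent": self.hf_percent,
            "LF norm": self.lf_norm,
            "HF norm": self.hf_norm,
            "LF/HF": self.lf_hf,
        }


@dataclass
class PoincareSummary:
    """Poincare-plot ellipse descriptors.

    sd1 is the dispersion across the identity line (short-term variability),
    sd2 along it (long- plus short-term). ``points`` holds the
    (RR_i, RR_{i+1}) scatter for plotting/export.
    """

    sd1: float
    sd2: float
    ratio: float                # sd1/sd2; NaN when sd2 == 0
    points: np.ndarray          # shape (N-1, 2), ms

    def as_dict(self) -> dict[str, float]:
        return {"SD1": self.sd1, "SD2": self.sd2, "SD1/SD2": self.ratio}


@dataclass
class SampEnResult:
    """Sample entropy of a series with the embedding parameters used.

    ``value`` is ln(phi_m / phi_m1) in nats; NaN when no matches exist at
    order m+1 (undefined marker, never infinity).
    """

    m: int
    tau: int
    r: float            # absolute tolerance, series units
    r_coef: float       # tolerance as fraction of the series SD
    phi_m: float        # mean match fraction at order m (self-matches excluded)
    phi_m1: float       # mean match fraction at order m+1
    value: float        # nats
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def require_min_intervals(rr: RRSeries, n_min: int, what: str) -> None:
    if rr.n < n_min:
        raise InsufficientDataError(
            f"{what} needs at least {n_min} RR intervals, got {rr.n}"
        )
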