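"""Time-domain and frequency-domain HRV features of an RR tachogram.

Time domain: meanRR, meanHR, SDNN, RMSSD, SDSD, CV, pNN20/pNN50 with their
counts. SD statistics use the population (1/N) convention by default; a
``ddof`` switch exposes the sample convention. meanHR is 60000/meanRR
(i.e. the rate of the mean interval), not the mean of per-beat rates.

Frequency domain: the unevenly sampled tachogram is cubic-interpolated onto
a uniform grid (default 4 Hz), a one-sided PSD is estimated (Welch by
default, Burg AR as an alternative), and band powers are integrated over
VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz and HF 0.15-0.4 Hz. ULF is excluded:
it needs recordings far longer than the 5-min epochs this package targets.
Normalized powers use the LF+HF denominator so LFnorm + HFnorm = 1.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import interpolate, signal

from .errors import InsufficientDataError, ParameterError
from .types import (
    PSDEstimate,
    RRSeries,
    SpectralSummary,
    TimeDomainSummary,
    UniformTachogram,
    require_min_intervals,
)

__all__ = [
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
    "compute_time_domain",
    "resample_tachogram",
    "estimate_psd",
    "band_powers",
]

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

#: Welch default window for 5-min records: one full-record (300 s) Hann
#: segment. Splitting a 5-min record into shorter detrended segments cannot
#: represent VLF cycles (periods up to 333 s) and roughly doubles the
#: band-power scatter; segment averaging only pays off for longer records.
WELCH_SEGMENT_S = 300.0
DEFAULT_RESAMPLE_HZ = 4.0


def compute_time_domain(rr: RRSeries, ddof: int = 0) -> TimeDomainSummary:
    """Compute the eight time-domain statistics of an RR series.

    Parameters
    ----------
    rr : RRSeries
        At least 2 intervals.
    ddof : int
        0 (default) for population SDs, 1 for sample SDs. RMSSD always
        divides by the number of successive differences (N-1).

    Notes
    -----
    pNNx counts *strictly* greater-than-x-ms absolute successive
    differences, normalized by N-1 pairs. CV is reported as a fraction
    (SDNN/meanRR), not a percentage.
    """
    require_min_intervals(rr, 2, "time-domain analysis")
    x = rr.intervals
    n = x.size
    mean_rr = float(x.mean())
    diffs = np.diff(x)

    sdnn = float(x.std(ddof=ddof))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    sdsd = float(diffs.std(ddof=ddof))
    nn20 = int(np.sum(np.abs(diffs) > 20.0))
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    n_pairs = diffs.size

    return TimeDomainSummary(
        mean_rr=mean_rr,
        mean_hr=60000.0 / mean_rr,
        sdnn=sdnn,
        rmssd=rmssd,
        sdsd=sdsd,
        cv=sdnn / mean_rr,
        pnn20=100.0 * nn20 / n_pairs,
        pnn50=100.0 * nn50 / n_pairs,
        nn20=nn20,
        nn50=nn50,
        n=n,
    )


def resample_tachogram(
    rr: RRSeries, rate: float = DEFAULT_RESAMPLE_HZ, remove_mean: bool = False
) -> UniformTachogram:
    """Cubic-spline interpolate the tachogram onto a uniform grid.

    The RR value at each beat is attached to the time of the beat that
    *ends* the interval; the grid spans the interior of the recording so
    the spline never extrapolates.
    """
    require_min_intervals(rr, 4, "tachogram resampling")
    if rate <= 2 * HF_BAND[1]:
        raise ParameterError(
            f"resampling rate must exceed {2 * HF_BAND[1]} Hz to resolve the HF band"
        )
    t = rr.beat_times[1:]  # ms; interval i ends at beat i+1
    span_ms = t[-1] - t[0]
    if span_ms < 10_000.0:
        raise InsufficientDataError(
            f"series spans {span_ms / 1000:.1f} s; need at least 10 s to resample"
        )
    step_ms = 1000.0 / rate
    grid = np.arange(t[0], t[-1] + 0.5 * step_ms, step_ms)
    grid = grid[grid <= t[-1]]
    spline = interpolate.CubicSpline(t, rr.intervals)
    values = spline(grid)
    if remove_mean:
        values = values - values.mean()
    return UniformTachogram(
        values=values, rate=rate, t_start=float(grid[0]), mean_removed=remove_mean
    )


def estimate_psd(
    uniform: UniformTachogram,
    method: str = "welch",
    segment_s: float = WELCH_SEGMENT_S,
    ar_order: int = 16,
) -> PSDEstimate:
    """One-sided PSD of a uniformly resampled tachogram, in ms^2/Hz.

    ``welch`` uses Hann windows of ``segment_s`` seconds at 50% overlap
    with per-segment linear detrending; its integral over (0, Nyquist]
    matches the variance of the detrended input to within ~10%. ``ar``
    fits Burg reflection coefficients of order ``ar_order`` and evaluates
    the parametric spectrum on the same grid resolution.
    """
    x = uniform.values
    fs = uniform.rate
    if x.size / fs < 60.0:
        raise InsufficientDataError(
            "need at least 60 s of uniform data for band-resolved spectra"
        )
    if method == "welch":
        nperseg = min(int(round(segment_s * fs)), x.size)
        freqs, density = signal.welch(
            x,
            fs=fs,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            detrend="linear",
            scaling="density",
        )
    elif method == "ar":
        freqs, density = _burg_psd(x, fs, ar_order)
    else:
        raise ParameterError(f"unknown PSD method {method!r}; use 'welch' or 'ar'")
    return PSDEstimate(
        freqs=freqs,
        density=np.clip(density, 0.0, None),
        method=method,
        resample_rate=fs,
        detrend="linear",
    )


def _burg_psd(x: np.ndarray, fs: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    from statsmodels.regression.linear_model import burg

    x = signal.detrend(x, type="linear")
    ar_coefs, sigma2 = burg(x, order=order)
    # statsmodels returns phi for x_t = phi_1 x_{t-1} + ...; A(z) = 1 - sum phi_k z^-k
    a = np.concatenate(([1.0], -ar_coefs))
    n_freq = max(1024, x.size)
    freqs = np.linspace(0.0, fs / 2, n_freq)
    _, h = signal.freqz([1.0], a, worN=freqs, fs=fs)
    density = 2.0 * sigma2 / fs * np.abs(h) ** 2  # one-sided
    return freqs, density


def _band_power(freqs: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(density[mask], freqs[mask]))


def band_powers(
    psd: PSDEstimate,
    vlf_band: tuple[float, float] = VLF_BAND,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> SpectralSummary:
    """Integrate the PSD over the VLF/LF/HF bands and derive the indices.

    Total power is the integral over 0.003-0.4 Hz (ULF excluded). LF/HF is
    NaN when HF power is exactly zero; relative powers are NaN when total
    power is zero.
    """
    f, d = psd.freqs, psd.density
    vlf = _band_power(f, d, *vlf_band)
    lf = _band_power(f, d, *lf_band)
    hf = _band_power(f, d, *hf_band)
    total = _band_power(f, d, vlf_band[0], hf_band[1])

    if total > 0:
        vlf_pct, lf_pct, hf_pct = (100.0 * p / total for p in (vlf, lf, hf))
    else:
        vlf_pct = lf_pct = hf_pct = math.nan
    lf_plus_hf = lf + hf
    if lf_plus_hf > 0:
        lf_norm, hf_norm = lf / lf_plus_hf, hf / lf_plus_hf
    else:
        lf_norm = hf_norm = math.nan
    lf_hf = lf / hf if hf > 0 else math.nan

    return SpectralSummary(
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        total_power=total,
        vlf_percent=vlf_pct,
        lf_percent=lf_pct,
        hf_percent=hf_pct,
        lf_norm=lf_norm,
        hf_norm=hf_norm,
        lf_hf=lf_hf,
    )


def spectral_summary(
    rr: RRSeries,
    rate: float = DEFAULT_RESAMPLE_HZ,
    method: str = "welch",
) -> SpectralSummary:
    """Convenience: resample -> PSD -> band powers in one call."""
    uniform = resample_tachogram(rr, rate=rate)
    return band_powers(estimate_psd(uniform, method=method))
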