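"""Synthetic paired-state RR/ECG/FS-14 cohort generator.

Real field recordings of orchard workers are not publicly available, so
this module generates a statistically matched stand-in cohort: for each
subject a pre-work ("nonfatigue") and post-work ("fatigue") 5-min RR
tachogram, optionally a template ECG trace rendered from it, and an FS-14
questionnaire response per state.

The tachogram model is a *non-physiological surrogate*: the RR interval is
a constant mean plus one band-limited stochastic modulation per VLF/LF/HF
band — a random-phase multisine with equal-amplitude components on the
record's Fourier grid, carrying exactly the configured band variance in
ms^2 — evaluated at the running beat times, plus per-beat white noise. It
reproduces the band-power structure and the
fatigue contrast (shorter mean RR, lower SDNN, higher LF/HF) without
modelling respiration, blood pressure coupling or PQRST morphology.

Default state profiles are calibrated to the occupational-fatigue contrast
this package targets: mean RR 845 -> 698 ms, SDNN ~67 -> ~45 ms and LF/HF
3.0 -> 4.8 between the rested and the end-of-shift state; FS-14 totals
average ~21.5 rested and ~49.4 fatigued.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .errors import InvalidProfileError, OverlapError
from .stats import FS14Record, score_fs14
from .time_frequency import HF_BAND, LF_BAND, VLF_BAND
from .types import ECGRecord, RRSeries

__all__ = [
    "ANSProfile",
    "SyntheticSubject",
    "NONFATIGUE_PROFILE",
    "FATIGUE_PROFILE",
    "generate_rr_tachogram",
    "generate_ecg_from_rr",
    "cohort_profiles",
    "generate_cohort",
    "generate_fs14_responses",
]


@dataclass(frozen=True)
class ANSProfile:
    """Parameters of the autonomic-modulation surrogate for one state.

    Powers are band variances of the modulation process in ms^2; center
    frequencies must lie inside their bands (LF 0.04-0.15 Hz, HF
    0.15-0.4 Hz). ``white_noise_sd`` is per-beat white noise in ms.
    """

    mean_rr: float               # ms
    sd_target: float             # ms, approximate SDNN (documentation)
    vlf_power: float             # ms^2
    lf_power: float              # ms^2
    hf_power: float              # ms^2
    lf_center_freq: float = 0.095   # Hz
    hf_center_freq: float = 0.25    # Hz
    white_noise_sd: float = 5.0     # ms, residual beat-timing jitter
    duration: float = 300.0         # s, the 5-min analysis epoch
    ectopic_rate: float = 0.0       # fraction of beats perturbed
    # R-peak amplitude channel: mean (mV), SD and AR(1) smoothness; a lower
    # coefficient gives a rougher series, i.e. higher amplitude entropy
    amp_mean: float = 1.0
    amp_sd: float = 0.05
    amp_ar: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidProfileError(f"mean_rr must be positive, got {self.mean_rr}")
        if self.duration <= 0:
            raise InvalidProfileError(f"duration must be positive, got {self.duration}")
        for name in ("vlf_power", "lf_power", "hf_power"):
            if getattr(self, name) < 0:
                raise InvalidProfileError(f"{name} must be non-negative")
        if not LF_BAND[0] <= self.lf_center_freq <= LF_BAND[1]:
            raise InvalidProfileError("lf_center_freq outside the LF band")
        if not HF_BAND[0] <= self.hf_center_freq <= HF_BAND[1]:
            raise InvalidProfileError("hf_center_freq outside the HF band")
        if not 0 <= self.ectopic_rate < 1:
            raise InvalidProfileError("ectopic_rate must be in [0, 1)")
        if not 0 <= self.amp_ar < 1:
            raise InvalidProfileError("amp_ar must be in [0, 1)")


#: Rested (pre-shift) state: mean RR 845 ms, configured LF/HF = 3.0 (the
#: per-beat jitter adds a small broadband floor to every band, so the
#: measured ratio lands slightly below the configured one).
NONFATIGUE_PROFILE = ANSProfile(
    mean_rr=845.0, sd_target=67.0,
    vlf_power=2000.0, lf_power=1450.0, hf_power=483.0,
    amp_ar=0.92,
)

#: End-of-shift state: mean RR 698 ms; heavier beat-timing jitter (more
#: erratic rhythm, hence higher RR/iHR sample entropy) and a rougher
#: amplitude channel (higher amplitude entropy when fatigued). HF power is
#: set so the measured LF/HF, including the jitter's broadband floor,
#: lands near 4.8.
FATIGUE_PROFILE = ANSProfile(
    mean_rr=698.0, sd_target=45.0,
    vlf_power=880.0, lf_power=782.0, hf_power=131.0,
    white_noise_sd=10.0,
    amp_ar=0.80,
)

#: Mild gender asymmetry of mean RR around the state means (females rest
#: slower, fatigue faster), mirroring the stratified cohort contrast.
GENDER_RR_FACTORS: dict[str, dict[str, float]] = {
    "male": {"nonfatigue": 0.977, "fatigue": 1.022},
    "female": {"nonfatigue": 1.032, "fatigue": 0.968},
}


@dataclass
class SyntheticSubject:
    """One simulated worker: paired RR series and FS-14 responses."""

    subject_id: str
    gender: str
    rr_nonfatigue: RRSeries
    rr_fatigue: RRSeries
    fs14_nonfatigue: FS14Record
    fs14_fatigue: FS14Record


# ---------------------------------------------------------------------------
# RR tachogram synthesis


def _band_components(
    rng: np.random.Generator,
    band: tuple[float, float],
    power: float,
    duration: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random-phase multisine filling ``band`` with total variance ``power``.

    Components sit on the Fourier grid of the record (spacing 1/duration),
    so they are orthogonal over the record and the realized band variance
    equals the configured power up to discretization. Equal amplitudes
    give a flat in-band spectrum; with tens of components the process is
    indistinguishable from band-limited Gaussian noise.
    """
    if power == 0:
        empty = np.empty(0)
        return empty, empty, empty
    # spacing 3/T makes Hann-windowed components exactly orthogonal over the
    # record; the 2/T edge inset keeps their leakage inside the band
    df = 3.0 / duration
    inset = 2.0 / duration
    k_lo = int(np.ceil((band[0] + inset) / df))
    k_hi = int(np.floor((band[1] - inset) / df))
    if k_hi < k_lo:
        freqs = np.array([0.5 * (band[0] + band[1])])
    else:
        freqs = np.arange(k_lo, k_hi + 1) * df
    amps = np.full(freqs.size, np.sqrt(2.0 * power / freqs.size))
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    return freqs, amps, phases


def generate_rr_tachogram(profile: ANSProfile) -> RRSeries:
    """Simulate one RR tachogram from an autonomic-modulation profile.

    The three band processes are evaluated at the running cumulative beat
    times (so the tachogram is irregularly sampled by construction, as
    real RR series are). Beats are appended until the configured duration
    is covered. Intervals are floored at 250 ms to remain physical under
    extreme modulation draws.

    Fully reproducible from ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    duration_ms = profile.duration * 1000.0

    parts = [
        _band_components(rng, VLF_BAND, profile.vlf_power, profile.duration),
        _band_components(
            rng, _centered_band(profile.lf_center_freq, LF_BAND),
            profile.lf_power, profile.duration,
        ),
        _band_components(
            rng, _centered_band(profile.hf_center_freq, HF_BAND),
            profile.hf_power, profile.duration,
        ),
    ]
    freqs = np.concatenate([p[0] for p in parts])
    amps = np.concatenate([p[1] for p in parts])
    phases = np.concatenate([p[2] for p in parts])
    omega = 2.0 * np.pi * freqs

    intervals: list[float] = []
    t_ms = 0.0
    while t_ms < duration_ms:
        t_s = t_ms / 1000.0
        rr = profile.mean_rr + float(np.dot(amps, np.cos(omega * t_s + phases)))
        if profile.white_noise_sd > 0:
            rr += rng.normal(0.0, profile.white_noise_sd)
        rr = max(rr, 250.0)
        intervals.append(rr)
        t_ms += rr

    arr = np.asarray(intervals)
    if profile.ectopic_rate > 0:
        arr = _inject_ectopics(rng, arr, profile.ectopic_rate)

    # stationary AR(1) R-peak amplitude channel, one value per beat
    n_beats = arr.size + 1
    amps = None
    if profile.amp_sd > 0:
        eps = rng.standard_normal(n_beats)
        a = np.empty(n_beats)
        a[0] = eps[0]
        innov = np.sqrt(1.0 - profile.amp_ar**2)
        for i in range(1, n_beats):
            a[i] = profile.amp_ar * a[i - 1] + innov * eps[i]
        amps = profile.amp_mean + profile.amp_sd * a
    elif profile.amp_mean > 0:
        amps = np.full(n_beats, profile.amp_mean)
    return RRSeries(intervals=arr, amplitudes=amps)


def _centered_band(center: float, limits: tuple[float, float]) -> tuple[float, float]:
    """A narrow band around ``center``, clipped to the canonical band."""
    half_width = 0.25 * (limits[1] - limits[0])
    return (max(center - half_width, limits[0]), min(center + half_width, limits[1]))


def _inject_ectopics(
    rng: np.random.Generator, intervals: np.ndarray, rate: float
) -> np.ndarray:
    """Halve or double isolated intervals (no two adjacent) at ``rate``."""
    out = intervals.copy()
    candidates = rng.random(out.size) < rate
    last = -2
    for i in np.flatnonzero(candidates):
        if i - last < 2:
            continue
        out[i] *= 0.5 if rng.random() < 0.5 else 2.0
        last = i
    return out


# ---------------------------------------------------------------------------
# ECG rendering


def generate_ecg_from_rr(
    rr: RRSeries,
    fs: float = 256.0,
    qrs_amplitude: float = 1.0,
    qrs_width: float = 80.0,
) -> tuple[ECGRecord, np.ndarray]:
    """Render a template ECG with one Gaussian R wave per beat.

    Parameters
    ----------
    rr : RRSeries
        Beat schedule; per-beat amplitudes are used when present.
    fs : float
        Sampling rate in Hz (>= 100; the reference acquisition hardware
        samples at 256 Hz).
    qrs_amplitude : float
        Peak amplitude in mV (0 gives a flat trace).
    qrs_width : float
        Full width of the QRS template in ms; must be shorter than the
        shortest interval.

    Returns
    -------
    (ECGRecord, ndarray)
        The trace and the ground-truth beat times in ms.
    """
    if fs < 100:
        raise InvalidProfileError(f"fs must be at least 100 Hz, got {fs}")
    if rr.n and qrs_width >= rr.intervals.min():
        raise OverlapError(
            f"qrs_width {qrs_width} ms >= shortest interval {rr.intervals.min()} ms"
        )
    # lead-in keeps the first QRS clear of the trace boundary
    lead_ms = max(500.0, 2 * qrs_width)
    beat_times_ms = rr.beat_times - rr.beat_times[0] + lead_ms
    total_ms = beat_times_ms[-1] + lead_ms
    n_samples = max(int(np.ceil(total_ms / 1000.0 * fs)) + 1, 2)
    t_ms = np.arange(n_samples) / fs * 1000.0
    sigma = qrs_width / 6.0  # template effectively vanishes at +-3 sigma

    amplitudes = (
        rr.amplitudes if rr.amplitudes is not None
        else np.full(beat_times_ms.size, qrs_amplitude)
    )
    trace = np.zeros(n_samples)
    if qrs_amplitude != 0:
        for bt, amp in zip(beat_times_ms, amplitudes):
            lo = np.searchsorted(t_ms, bt - 4 * sigma)
            hi = np.searchsorted(t_ms, bt + 4 * sigma)
            trace[lo:hi] += amp * np.exp(-0.5 * ((t_ms[lo:hi] - bt) / sigma) ** 2)
    return ECGRecord(samples=trace, fs=fs, t0=0.0), beat_times_ms


# ---------------------------------------------------------------------------
# FS-14 questionnaire synthesis

PHYSICAL_ITEMS = tuple(range(8))    # items 1-8
MENTAL_ITEMS = tuple(range(8, 14))  # items 9-14

#: Cohort-level targets per state: (physical subtotal, mental subtotal).
FS14_TARGETS = {
    "nonfatigue": (12.6, 9.0),   # total ~21.5
    "fatigue": (34.2, 15.2),     # total ~49.4
}
FS14_ITEM_SD = 0.8  # latent per-item SD before discretization


@functools.lru_cache(maxsize=None)
def _latent_mean(target_item_mean: float, sd: float = FS14_ITEM_SD) -> float:
    """Latent Gaussian mean whose round-and-clip expectation hits the target.

    The observed item is round(N(mu, sd)) clipped to 1..5; clipping biases
    the mean near the scale ends, so the latent mean is solved numerically.
    """
    from scipy.optimize import brentq

    def expectation(mu: float) -> float:
        edges = np.arange(1.5, 5.0)  # 1.5, 2.5, 3.5, 4.5
        cdf = sps.norm.cdf(edges, loc=mu, scale=sd)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        return float(np.dot(np.arange(1, 6), probs))

    lo, hi = -4.0, 10.0
    if expectation(lo) > target_item_mean or expectation(hi) < target_item_mean:
        raise InvalidProfileError(f"unreachable item mean {target_item_mean}")
    return float(brentq(lambda mu: expectation(mu) - target_item_mean, lo, hi))


def generate_fs14_responses(
    state: str, seed: int | np.random.Generator = 0
) -> FS14Record:
    """Draw one FS-14 response (14 Likert items in 1..5) for a state.

    Items are independent round-and-clip Gaussians whose latent means are
    calibrated so that *cohort-level* expected subtotals hit the state
    targets (physical 12.6/34.2, mental 9.0/15.2); individual totals vary.
    """
    if state not in FS14_TARGETS:
        raise InvalidProfileError(f"state must be one of {sorted(FS14_TARGETS)}")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phys_total, ment_total = FS14_TARGETS[state]
    mu_phys = _latent_mean(phys_total / len(PHYSICAL_ITEMS))
    mu_ment = _latent_mean(ment_total / len(MENTAL_ITEMS))
    mus = np.array(
        [mu_phys] * len(PHYSICAL_ITEMS) + [mu_ment] * len(MENTAL_ITEMS)
    )
    raw = rng.normal(mus, FS14_ITEM_SD)
    items = np.clip(np.rint(raw), 1, 5).astype(int)
    return score_fs14(items.tolist())


# ---------------------------------------------------------------------------
# Cohort assembly


def cohort_profiles(
    n_male: int,
    n_female: int,
    nonfatigue_profile: ANSProfile = NONFATIGUE_PROFILE,
    fatigue_profile: ANSProfile = FATIGUE_PROFILE,
    between_subject_sd: float = 0.08,
    seed: int = 0,
    gender_rr_factors: dict[str, dict[str, float]] | None = None,
) -> list[dict]:
    """Per-subject state profiles for a paired cohort (no simulation yet).

    Each subject receives a multiplicative jitter (lognormal,
    SD ``between_subject_sd``) on mean RR, on each band power and on the
    beat noise, shared across both states so the design is genuinely
    paired; gender scales mean RR per state. With ``between_subject_sd=0``
    all same-gender subjects share identical profiles apart from their
    realization seeds. Reproducible from ``seed``.
    """
    if n_male + n_female < 2:
        raise InvalidProfileError("cohort needs at least 2 subjects")
    if gender_rr_factors is None:
        gender_rr_factors = GENDER_RR_FACTORS
    root = np.random.SeedSequence(seed)
    genders = ["male"] * n_male + ["female"] * n_female
    out: list[dict] = []
    for i, (gender, ss) in enumerate(zip(genders, root.spawn(len(genders)))):
        rng = np.random.default_rng(ss)
        # shared subject effect: one factor for mean RR, one per power
        rr_jit = _jitter(rng, between_subject_sd)
        power_jit = [_jitter(rng, between_subject_sd) for _ in range(3)]
        noise_jit = _jitter(rng, between_subject_sd)
        state_seeds = rng.integers(0, 2**31 - 1, size=4)

        profiles: dict[str, ANSProfile] = {}
        fs14_seeds: dict[str, int] = {}
        for j, (state, base) in enumerate(
            (("nonfatigue", nonfatigue_profile), ("fatigue", fatigue_profile))
        ):
            g_factor = gender_rr_factors.get(gender, {}).get(state, 1.0)
            profiles[state] = replace(
                base,
                mean_rr=base.mean_rr * rr_jit * g_factor,
                vlf_power=base.vlf_power * power_jit[0] ** 2,
                lf_power=base.lf_power * power_jit[1] ** 2,
                hf_power=base.hf_power * power_jit[2] ** 2,
                white_noise_sd=base.white_noise_sd * noise_jit,
                seed=int(state_seeds[j]),
            )
            fs14_seeds[state] = int(state_seeds[2 + j])
        out.append(
            {"subject_id": f"S{i + 1:03d}", "gender": gender,
             "profiles": profiles, "fs14_seeds": fs14_seeds}
        )
    return out


def generate_cohort(
    n_male: int,
    n_female: int,
    nonfatigue_profile: ANSProfile = NONFATIGUE_PROFILE,
    fatigue_profile: ANSProfile = FATIGUE_PROFILE,
    between_subject_sd: float = 0.08,
    seed: int = 0,
    gender_rr_factors: dict[str, dict[str, float]] | None = None,
) -> list[SyntheticSubject]:
    """Generate a paired nonfatigue/fatigue cohort (see
    :func:`cohort_profiles` for the subject-effect model)."""
    subjects: list[SyntheticSubject] = []
    for spec in cohort_profiles(
        n_male, n_female, nonfatigue_profile, fatigue_profile,
        between_subject_sd, seed, gender_rr_factors,
    ):
        rr = {s: generate_rr_tachogram(p) for s, p in spec["profiles"].items()}
        fs = {
            s: generate_fs14_responses(s, np.random.default_rng(sd))
            for s, sd in spec["fs14_seeds"].items()
        }
        subjects.append(
            SyntheticSubject(
                subject_id=spec["subject_id"],
                gender=spec["gender"],
                rr_nonfatigue=rr["nonfatigue"],
                rr_fatigue=rr["fatigue"],
                fs14_nonfatigue=fs["nonfatigue"],
                fs14_fatigue=fs["fatigue"],
            )
        )
    return subjects


def _jitter(rng: np.random.Generator, sd: float) -> float:
    """Multiplicative subject-effect factor, exactly 1.0 when sd == 0."""
    if sd == 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, sd)))
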