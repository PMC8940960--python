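"""Time-domain statistics and spectral band powers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvfatigue.errors import InsufficientDataError, ParameterError
from hrvfatigue.time_frequency import (
    HF_BAND,
    LF_BAND,
    VLF_BAND,
    band_powers,
    compute_time_domain,
    estimate_psd,
    resample_tachogram,
)
from hrvfatigue.types import PSDEstimate, RRSeries, UniformTachogram

from conftest import random_rr


class TestTimeDomain:
    def test_constant_series_has_zero_variability(self, constant_rr):
        td = compute_time_domain(constant_rr)
        assert td.mean_rr == 800.0
        assert td.mean_hr == 75.0
        assert td.sdnn == td.rmssd == td.sdsd == 0.0
        assert td.pnn20 == td.pnn50 == 0.0
        assert td.cv == 0.0

    def test_two_interval_hand_example(self):
        td = compute_time_domain(RRSeries(intervals=[700.0, 900.0]))
        assert td.mean_rr == 800.0
        assert td.sdnn == 100.0          # population SD
        assert td.rmssd == 200.0
        assert td.pnn50 == 100.0

    def test_strict_threshold_counting(self):
        # diffs are [50, -50, 60]: only |60| strictly exceeds 50 ms
        td = compute_time_domain(RRSeries(intervals=[800.0, 850.0, 800.0, 860.0]))
        assert td.nn50 == 1
        assert td.pnn50 == pytest.approx(100.0 / 3.0)
        assert td.nn20 == 3
        assert td.pnn20 == 100.0

    def test_single_interval_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_time_domain(RRSeries(intervals=[800.0]))

    def test_mean_hr_is_rate_of_mean_interval(self):
        td = compute_time_domain(RRSeries(intervals=[500.0, 1000.0]))
        assert td.mean_hr == pytest.approx(60000.0 / 750.0)

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scale=st.floats(0.2, 5.0, allow_nan=False),
    )
    def test_scale_equivariance(self, seed, scale):
        rr = random_rr(np.random.default_rng(seed), n=40)
        a = compute_time_domain(rr)
        b = compute_time_domain(RRSeries(intervals=rr.intervals * scale))
        for name in ("mean_rr", "sdnn", "rmssd", "sdsd"):
            assert getattr(b, name) == pytest.approx(getattr(a, name) * scale)
        assert b.cv == pytest.approx(a.cv)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rmssd_bounds_sdsd(self, seed):
        # RMSSD^2 = SDSD^2 + mean(diff)^2, so RMSSD >= SDSD with equality
        # iff the mean successive difference vanishes
        rr = random_rr(np.random.default_rng(seed), n=50)
        td = compute_time_domain(rr)
        assert td.rmssd >= td.sdsd - 1e-12
        mean_diff = np.diff(rr.intervals).mean()
        assert td.rmssd**2 == pytest.approx(td.sdsd**2 + mean_diff**2)

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_pnn_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        rr = RRSeries(intervals=800 + rng.normal(0, 30, 50).cumsum() % 200 + 500)
        td = compute_time_domain(rr)
        assert td.pnn20 >= td.pnn50


class TestResampling:
    def test_constant_series_stays_constant(self, constant_rr):
        u = resample_tachogram(constant_rr, rate=4.0)
        assert np.allclose(u.values, 800.0)

    def test_linear_in_time_ramp_is_exact(self):
        # construct a series whose interval is an exact linear function of
        # its beat time; not-a-knot cubic interpolation reproduces it
        a, b = 800.0, 1e-3
        t, intervals = 0.0, []
        for _ in range(40):
            t = (t + a) / (1.0 - b)  # solves RR = a + b * t_end
            intervals.append(a + b * t)
        rr = RRSeries(intervals=intervals)
        u = resample_tachogram(rr, rate=4.0)
        grid = u.t_start + np.arange(u.values.size) * 250.0
        assert np.allclose(u.values, a + b * grid, rtol=1e-9)

    def test_grid_size_for_five_minutes(self, synthetic_rr):
        u = resample_tachogram(synthetic_rr, rate=4.0)
        span_s = (synthetic_rr.beat_times[-1] - synthetic_rr.beat_times[1]) / 1000
        assert abs(u.values.size - span_s * 4.0) <= 1

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            resample_tachogram(RRSeries(intervals=[800.0] * 5), rate=4.0)

    def test_low_rate_rejected(self, constant_rr):
        with pytest.raises(ParameterError):
            resample_tachogram(constant_rr, rate=0.5)


class TestPSD:
    def _uniform(self, values, rate=4.0):
        return UniformTachogram(values=np.asarray(values), rate=rate, t_start=0.0)

    def test_sinusoid_power_and_band(self):
        t = np.arange(0, 300, 0.25)
        a = 50.0
        u = self._uniform(a * np.sin(2 * np.pi * 0.1 * t))
        psd = estimate_psd(u)
        total = np.trapezoid(psd.density, psd.freqs)
        assert total == pytest.approx(a**2 / 2, rel=0.10)
        sp = band_powers(psd)
        assert sp.lf_power >= 0.9 * total

    def test_white_noise_band_powers_track_bandwidth(self):
        rng = np.random.default_rng(11)
        u = self._uniform(rng.normal(0, 30, 48_000))
        sp = band_powers(estimate_psd(u))
        width = {"vlf": 0.037, "lf": 0.11, "hf": 0.25}
        ratio_lf_hf = (sp.lf_power / width["lf"]) / (sp.hf_power / width["hf"])
        ratio_vlf_hf = (sp.vlf_power / width["vlf"]) / (sp.hf_power / width["hf"])
        assert ratio_lf_hf == pytest.approx(1.0, abs=0.25)
        assert ratio_vlf_hf == pytest.approx(1.0, abs=0.25)

    def test_zero_signal_zero_density(self):
        psd = estimate_psd(self._uniform(np.zeros(1200)))
        assert np.allclose(psd.density, 0.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            estimate_psd(self._uniform(np.ones(1200)), method="music")

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_psd(self._uniform(np.ones(100)))

    def test_ar_method_matches_welch_on_broadband(self):
        rng = np.random.default_rng(5)
        u = self._uniform(rng.normal(0, 20, 2400))
        welch = band_powers(estimate_psd(u, method="welch"))
        ar = band_powers(estimate_psd(u, method="ar"))
        assert ar.lf_norm == pytest.approx(welch.lf_norm, abs=0.1)


class TestBandPowers:
    def _psd_from_bands(self, vlf=0.0, lf=0.0, hf=0.0):
        """Synthetic rectangular PSD carrying exact band powers."""
        freqs = np.linspace(0.0, 2.0, 4001)
        density = np.zeros_like(freqs)
        for (lo, hi), p in ((VLF_BAND, vlf), (LF_BAND, lf), (HF_BAND, hf)):
            # strictly interior so adjacent bands share no grid point
            mask = (freqs > lo) & (freqs < hi)
            if p:
                density[mask] = p / (hi - lo)
        return PSDEstimate(freqs=freqs, density=density, method="welch",
                           resample_rate=4.0)

    def test_single_band_limit(self):
        sp = band_powers(self._psd_from_bands(lf=10.0))
        assert sp.lf_percent == pytest.approx(100.0, abs=0.5)
        assert sp.lf_norm == pytest.approx(1.0, abs=1e-6)
        assert sp.hf_norm == pytest.approx(0.0, abs=1e-6)
        assert math.isnan(sp.lf_hf)  # HF exactly zero -> undefined marker

    def test_three_to_one_ratio(self):
        sp = band_powers(self._psd_from_bands(lf=3.0, hf=1.0))
        assert sp.lf_norm == pytest.approx(0.75, abs=0.01)
        assert sp.hf_norm == pytest.approx(0.25, abs=0.01)
        assert sp.lf_hf == pytest.approx(3.0, rel=0.02)

    @settings(max_examples=30, deadline=None)
    @given(
        lf=st.floats(0.1, 100.0),
        hf=st.floats(0.1, 100.0),
        vlf=st.floats(0.0, 100.0),
    )
    def test_normalization_identity(self, lf, hf, vlf):
        sp = band_powers(self._psd_from_bands(vlf=vlf, lf=lf, hf=hf))
        assert sp.lf_norm + sp.hf_norm == pytest.approx(1.0, abs=1e-9)
        assert sp.lf_hf == pytest.approx(sp.lf_power / sp.hf_power)
        assert sp.vlf_percent + sp.lf_percent + sp.hf_percent <= 100.0 + 1e-6
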