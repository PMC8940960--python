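"""FS-14 scoring, nonparametric tests, percent change, KDE, cohort contrast."""

import math

import numpy as np
import pandas as pd
import pytest

from hrvfatigue.errors import HRVError, InsufficientDataError, ParameterError
from hrvfatigue.stats import (
    compare_states,
    estimate_pdf,
    ks_normality,
    mann_whitney_u,
    percent_change,
    score_fs14,
    spearman_rho,
    stars_for_p,
)


class TestFS14Scoring:
    def test_floor(self):
        rec = score_fs14([1] * 14)
        assert (rec.total, rec.physical, rec.mental) == (14, 8, 6)

    def test_ceiling(self):
        assert score_fs14([5] * 14).total == 70

    def test_partition_arithmetic(self):
        rec = score_fs14([5] * 8 + [1] * 6)
        assert (rec.physical, rec.mental, rec.total) == (40, 6, 46)

    def test_out_of_range_rejected(self):
        with pytest.raises(HRVError):
            score_fs14([0] + [3] * 13)
        with pytest.raises(HRVError):
            score_fs14([3] * 13)

    def test_custom_partition(self):
        rec = score_fs14(
            [5] * 7 + [1] * 7,
            physical_items=tuple(range(7)),
            mental_items=tuple(range(7, 14)),
        )
        assert rec.physical == 35
        assert rec.mental == 7


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "**"), (0.001, "*"), (0.01, "*"), (0.049999, "*"),
         (0.05, "NS"), (0.5, "NS"), (math.nan, "NS")],
    )
    def test_convention(self, p, expected):
        assert stars_for_p(p) == expected


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman_rho(x, [10, 20, 30, 50]) == pytest.approx(1.0)
        assert spearman_rho(x, [50, 30, 20, 10]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks differ by (1,-1,1,-1): rho = 1 - 6*4/(4*15) = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_length_contracts(self):
        with pytest.raises(ParameterError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            spearman_rho([1, 2], [3, 4])


class TestMannWhitney:
    def test_exact_fully_separated(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        # 2 of the C(6,3)=20 assignments are at least this extreme
        assert p == pytest.approx(0.1)

    def test_exact_identical_groups(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
        assert p == pytest.approx(1.0)

    def test_exact_vs_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        _, p_exact = mann_whitney_u(a, b, mode="exact")
        _, p_approx = mann_whitney_u(a, b, mode="normal_approx")
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_exact_size_limit(self):
        with pytest.raises(ParameterError):
            mann_whitney_u(np.arange(15), np.arange(15), mode="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_u([], [1, 2])

    def test_u_orientation(self):
        # U counts pairs where the first sample exceeds the second
        u, _ = mann_whitney_u([10, 11], [1, 2], mode="exact")
        assert u == 4.0


class TestKSNormality:
    def test_calibration_on_normal_samples(self):
        rejections = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0, 1, 200)
            _, p = ks_normality(x)
            rejections += p < 0.05
        assert rejections <= 1  # >= 90% of seeds pass

    def test_power_on_exponential_samples(self):
        detections = 0
        for seed in range(10):
            x = np.random.default_rng(seed).exponential(1.0, 200)
            _, p = ks_normality(x)
            detections += p < 0.05
        assert detections >= 9

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            ks_normality([1.0, 2.0, 3.0])

    def test_constant_sample_degenerate(self):
        stat, p = ks_normality(np.ones(20))
        assert math.isnan(stat) and math.isnan(p)


class TestPercentChange:
    def test_increase(self):
        assert percent_change(72.154, 86.692) == pytest.approx(20.15)

    def test_decrease(self):
        assert percent_change(46.996, 28.615) == pytest.approx(-39.11)

    def test_no_change(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_zero_baseline_undefined(self):
        assert math.isnan(percent_change(0.0, 3.0))

    def test_rounding_control(self):
        assert percent_change(3.0, 4.0, decimals=None) == pytest.approx(100 / 3)


class TestKDE:
    def test_density_integrates_to_one(self):
        x = np.random.default_rng(0).normal(10, 3, 200)
        de = estimate_pdf(x)
        assert np.trapezoid(de.density, de.grid) == pytest.approx(1.0, abs=1e-6)

    def test_standard_normal_peak_height(self):
        x = np.random.default_rng(4).normal(0, 1, 1000)
        de = estimate_pdf(x)
        peak_at_zero = de.density[np.argmin(np.abs(de.grid))]
        assert 0.3 <= peak_at_zero <= 0.5  # true value 1/sqrt(2 pi) ~ 0.399

    def test_bimodal_sample_two_modes(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-5, 0.5, 300), rng.normal(5, 0.5, 300)])
        de = estimate_pdf(x)
        d = de.density
        interior_max = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]) & (d[1:-1] > 0.01)
        assert interior_max.sum() == 2

    def test_zero_variance_point_mass(self):
        de = estimate_pdf(np.full(10, 7.0))
        assert de.point_mass == 7.0

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_pdf([1.0, 2.0])


def _feature_table(rng, n_subjects=20, effect=0.0):
    """Paired two-state table with a configurable fatigue shift."""
    rows = []
    for i in range(n_subjects):
        gender = "male" if i % 2 == 0 else "female"
        base = rng.normal(800, 50)
        rows.append({"subject_id": f"S{i}", "gender": gender,
                     "state": "nonfatigue", "feat": base + rng.normal(0, 20)})
        rows.append({"subject_id": f"S{i}", "gender": gender,
                     "state": "fatigue", "feat": base - effect + rng.normal(0, 20)})
    return pd.DataFrame(rows)


class TestCompareStates:
    def test_detects_configured_shift(self, rng):
        df = _feature_table(rng, n_subjects=30, effect=100.0)
        out = compare_states(df)
        row = out.iloc[0]
        assert row["Parameter"] == "feat"
        assert row["p"] < 0.001
        assert row["Sig"] == "**"
        assert row["Rate (%)"] < 0

    def test_row_order_and_relabeling_invariance(self, rng):
        df = _feature_table(rng, n_subjects=15, effect=50.0)
        base = compare_states(df).drop(columns=["note"])
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(
            subject_id=shuffled["subject_id"].map(lambda s: "X" + s)
        )
        again = compare_states(relabeled).drop(columns=["note"])
        pd.testing.assert_frame_equal(base, again)

    def test_null_cohorts_mostly_ns(self):
        # type-I control: ~5% false positives expected at alpha = 0.05
        flags = total = 0
        for seed in range(20):
            df = _feature_table(np.random.default_rng(seed), n_subjects=20)
            out = compare_states(df)
            flags += (out["Sig"] != "NS").sum()
            total += len(out)
        assert flags / total <= 0.10

    def test_gender_stratification(self, rng):
        df = _feature_table(rng, n_subjects=12, effect=80.0)
        out = compare_states(df, stratify_gender=True)
        assert set(out["gender"]) == {"male", "female"}
        only_female = compare_states(
            df[df["gender"] == "female"], stratify_gender=True
        )
        assert set(only_female["gender"]) == {"female"}

    def test_incomplete_pairing_flagged(self, rng):
        df = _feature_table(rng, n_subjects=6, effect=10.0)
        df = df.drop(df[(df["subject_id"] == "S0")
                        & (df["state"] == "fatigue")].index)
        out = compare_states(df)
        # statistics still computed from the unpaired groups
        assert np.isfinite(out.iloc[0]["p"])

    def test_low_n_flag(self):
        df = _feature_table(np.random.default_rng(0), n_subjects=2)
        out = compare_states(df)
        assert bool(out.iloc[0]["low_n"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ParameterError):
            compare_states(pd.DataFrame({"a": [1.0]}))
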