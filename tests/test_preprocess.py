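"""Measurement-cleaning rules: BP averaging and adjustment, outliers,
log transform, age banding, residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twinsem as ts
from twinsem.preprocess import MissingDataError


class TestAverageBpReadings:
    @pytest.mark.parametrize(
        "m1, m2, m3, expect",
        [
            (120, 124, None, 122.0),   # plain average of two close readings
            (120, 134, 126, 123.0),    # closest pair is {120, 126}
            (120, 120, None, 120.0),   # identical readings
            (120, 131, 131, 131.0),    # third coincides with second
        ],
    )
    def test_examples(self, m1, m2, m3, expect):
        assert ts.average_bp_readings(m1, m2, m3) == pytest.approx(expect)

    def test_missing_third_reading_raises(self):
        with pytest.raises(MissingDataError):
            ts.average_bp_readings(120, 134)

    def test_vectorized(self):
        out = ts.average_bp_readings(
            np.array([120.0, 120.0]), np.array([124.0, 134.0]),
            np.array([np.nan, 126.0]),
        )
        np.testing.assert_allclose(out, [122.0, 123.0])

    @given(
        m1=st.floats(80, 200), m2=st.floats(80, 200), m3=st.floats(80, 200)
    )
    @settings(max_examples=100, deadline=None)
    def test_result_within_reading_range(self, m1, m2, m3):
        out = ts.average_bp_readings(m1, m2, m3)
        assert min(m1, m2, m3) - 1e-9 <= out <= max(m1, m2, m3) + 1e-9


class TestAdjustBloodPressure:
    def _records(self, med, sbp=128.0, dbp=84.0):
        return pd.DataFrame(
            {"sbp": [sbp], "dbp": [dbp], "med_bp": [med]}
        )

    def test_medicated_shift(self):
        out = ts.adjust_blood_pressure(self._records(1))
        assert out.loc[0, "sbp"] == 143.0 and out.loc[0, "dbp"] == 94.0

    def test_unmedicated_unchanged(self):
        out = ts.adjust_blood_pressure(self._records(0))
        assert out.loc[0, "sbp"] == 128.0 and out.loc[0, "dbp"] == 84.0

    def test_partial_missing(self):
        out = ts.adjust_blood_pressure(self._records(1, sbp=np.nan))
        assert np.isnan(out.loc[0, "sbp"]) and out.loc[0, "dbp"] == 94.0

    def test_idempotent(self):
        once = ts.adjust_blood_pressure(self._records(1))
        twice = ts.adjust_blood_pressure(once)
        assert twice.loc[0, "sbp"] == 143.0 and twice.loc[0, "dbp"] == 94.0


class TestOutlierMask:
    def test_zero_sd_flags_nothing(self):
        assert not ts.outlier_mask(np.full(100, 5.0)).any()

    def test_hand_computed_vector(self):
        x = np.array([0.0] * 9 + [100.0])
        z = (100.0 - x.mean()) / x.std(ddof=1)
        mask = ts.outlier_mask(x)
        # z-score of the extreme point under this vector decides the flag
        assert mask[-1] == (z > 3.0)
        assert not mask[:-1].any()

    def test_missing_not_flagged(self):
        x = np.array([1.0, 2.0, np.nan, 3.0, 50.0])
        mask = ts.outlier_mask(x)
        assert len(mask) == 5 and not mask[2]

    def test_gaussian_rate_near_theory(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(10_000)
        rate = ts.outlier_mask(x).mean()
        # P(|Z| > 3) = 0.27%; binomial 99% bounds at n = 10,000
        se = np.sqrt(0.0027 * 0.9973 / 10_000)
        assert abs(rate - 0.0027) < 2.58 * se + 1e-4


class TestLogTransform:
    def test_gaussian_untouched(self):
        x = np.random.default_rng(0).normal(10, 1, 5000)
        out, flag = ts.select_and_apply_log(x)
        assert not flag and out[0] == x[0]

    def test_lognormal_transformed(self):
        x = np.exp(np.random.default_rng(1).normal(0, 1, 5000))
        out, flag = ts.select_and_apply_log(x)
        assert flag
        np.testing.assert_allclose(out, np.log(x))

    def test_force_overrides_skew(self):
        x = np.random.default_rng(2).normal(10, 1, 500)
        _, flag = ts.select_and_apply_log(x, force=True)
        assert flag

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ts.select_and_apply_log(np.array([-1.0, 2.0, 3.0]), force=True)


class TestAssignAgeGroup:
    @pytest.mark.parametrize(
        "age, group",
        [(18, "G1"), (50, "G1"), (50.5, "G1"), (51, "G2"), (60, "G2"),
         (60.5, "G3"), (61, "G3"), (75, "G3")],
    )
    def test_boundaries(self, age, group):
        assert ts.assign_age_group(age) == group

    @given(st.floats(0.1, 110, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, age):
        assert ts.assign_age_group(age) in {"G1", "G2", "G3"}


class TestResidualize:
    def test_orthogonal_covariate_is_noop(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 2, 200)
        x = np.tile([1.0, -1.0], 100)  # exactly balanced, near-orthogonal
        out = ts.residualize_covariates(y, pd.DataFrame({"x": x}))
        centered = y - np.polyval(np.polyfit(x, y, 1), x)
        np.testing.assert_allclose(
            out, (centered - centered.mean()) / centered.std(ddof=1), atol=1e-10
        )

    def test_perfect_fit_gives_zero_residuals(self):
        age = np.linspace(30, 70, 50)
        out = ts.residualize_covariates(2 * age, pd.DataFrame({"age": age}))
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_closed_form_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.9, 4.1, 5.5])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        resid = y - (y.mean() + slope * (x - x.mean()))
        expect = (resid - resid.mean()) / resid.std(ddof=1)
        out = ts.residualize_covariates(y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            ts.residualize_covariates(
                x, pd.DataFrame({"a": x, "b": 2 * x})
            )


def test_preprocess_cohort_chain():
    """BP adjustment, outliers and the TG force-log all apply in one pass."""
    rng = np.random.default_rng(5)
    n = 400
    df = pd.DataFrame({
        "sbp": rng.normal(130, 10, n),
        "dbp": rng.normal(82, 8, n),
        "tg": np.exp(rng.normal(0.3, 0.5, n)),
        "med_bp": (rng.random(n) < 0.2).astype(int),
    })
    df.loc[0, "sbp"] = 400.0  # gross outlier
    out, report = ts.preprocess_cohort(df)
    assert np.isnan(out.loc[0, "sbp"])
    assert report["outliers"]["SBP"] >= 1
    assert report["log_transformed"]["TG"]
    assert not report["log_transformed"]["DBP"]
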