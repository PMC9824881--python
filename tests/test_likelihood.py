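"""Likelihood core: expected covariances, FIML evaluation, optimization,
model comparison and profile confidence intervals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import twinsem as ts
from twinsem import likelihood as lk

from conftest import make_cohort


def _sim_pairs(rng, n, params, zygosity, p_cov=2):
    """Draw (y, X) directly from the model for oracle comparisons."""
    cov = lk.expected_cov_univariate(params, zygosity)
    X = np.stack(
        [np.column_stack([np.ones(n), rng.normal(0, 1, (n, p_cov - 1))])] * 2,
        axis=1,
    )
    mu = X @ params.beta
    y = mu + rng.multivariate_normal([0, 0], cov, size=n)
    return y, X


class TestExpectedCov:
    @pytest.mark.parametrize(
        "paths, zyg, off",
        [
            ({"A": np.sqrt(0.72), "E": np.sqrt(0.28)}, "MZ", 0.72),
            ({"A": np.sqrt(0.5), "C": np.sqrt(0.2), "E": np.sqrt(0.3)}, "DZ", 0.45),
            ({"A": np.sqrt(0.4), "D": np.sqrt(0.2), "E": np.sqrt(0.4)}, "DZ", 0.25),
            ({"A": np.sqrt(0.4), "D": np.sqrt(0.2), "E": np.sqrt(0.4)}, "MZ", 0.6),
        ],
    )
    def test_closed_form_off_diagonals(self, paths, zyg, off):
        cov = lk.expected_cov_univariate(paths, zyg)
        assert cov[0, 1] == pytest.approx(off, abs=1e-12)
        assert cov[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert cov[0, 1] == cov[1, 0]

    @given(
        a=st.floats(0.05, 2), cd=st.floats(0, 2), e=st.floats(0.05, 2),
        fam=st.sampled_from(["ACE", "ADE"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_mz_covariance_exceeds_dz_and_psd(self, a, cd, e, fam):
        paths = {"A": a, ("C" if fam == "ACE" else "D"): cd, "E": e}
        mz = lk.expected_cov_univariate(paths, "MZ")
        dz = lk.expected_cov_univariate(paths, "DZ")
        assert mz[0, 1] > dz[0, 1]  # a > 0 strictly
        for m in (mz, dz):
            assert np.all(np.linalg.eigvalsh(m) >= -1e-12)


class TestFimlLoglik:
    def test_standard_normal_pair_at_origin(self):
        params = lk.PathParams("E", {"E": 1.0}, np.array([0.0]))
        data = {"MZ": (np.zeros((1, 2)), np.ones((1, 2, 1)))}
        assert ts.fiml_loglik(data, params) == pytest.approx(
            -np.log(2 * np.pi), abs=1e-9
        )

    def test_matches_brute_force_mvn(self):
        rng = np.random.default_rng(11)
        params = lk.PathParams(
            "ACE", {"A": 0.7, "C": 0.35, "E": 0.6}, np.array([1.0, -0.5])
        )
        data = {}
        for zyg, n in (("MZ", 30), ("DZ", 20)):
            y, X = _sim_pairs(rng, n, params, zyg)
            y[0, 1] = np.nan  # exercise the marginal path
            data[zyg] = (y, X)
        ll = ts.fiml_loglik(data, params)
        brute = 0.0
        for zyg, (y, X) in data.items():
            cov = lk.expected_cov_univariate(params, zyg)
            for i in range(len(y)):
                obs = np.isfinite(y[i])
                brute += multivariate_normal.logpdf(
                    y[i][obs], (X[i] @ params.beta)[obs], cov[np.ix_(obs, obs)]
                )
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_additivity_under_duplication(self):
        rng = np.random.default_rng(5)
        params = lk.PathParams("AE", {"A": 0.8, "E": 0.6}, np.array([0.0]))
        y, X = _sim_pairs(rng, 25, params, "MZ", p_cov=1)
        single = ts.fiml_loglik({"MZ": (y, X)}, params)
        double = ts.fiml_loglik(
            {"MZ": (np.vstack([y, y]), np.vstack([X, X]))}, params
        )
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_invariant_to_pair_and_member_order(self):
        rng = np.random.default_rng(6)
        params = lk.PathParams("ACE", {"A": 0.6, "C": 0.3, "E": 0.7},
                               np.array([0.2, 0.1]))
        y, X = _sim_pairs(rng, 40, params, "DZ")
        base = ts.fiml_loglik({"DZ": (y, X)}, params)
        perm = rng.permutation(40)
        assert ts.fiml_loglik({"DZ": (y[perm], X[perm])}, params) == pytest.approx(
            base, abs=1e-10
        )
        assert ts.fiml_loglik(
            {"DZ": (y[:, ::-1], X[:, ::-1, :])}, params
        ) == pytest.approx(base, abs=1e-10)

    def test_non_pd_covariance_returns_sentinel(self):
        params = lk.PathParams("E", {"E": 0.0}, np.array([0.0]))
        data = {"MZ": (np.ones((3, 2)), np.ones((3, 2, 1)))}
        assert ts.fiml_loglik(data, params) <= -1e11


class TestFitMl:
    def test_null_structure_recovery(self):
        cohort = make_cohort(400, 400, h2=0.0, seed=21)  # pure E
        fit = ts.fit_ml(cohort.trait_arrays("bmi", ()), "ACE")
        shares = ts.standardize(fit).shares
        assert shares["A"] < 0.1 and shares["C"] < 0.1

    def test_parameter_recovery(self):
        cohort = make_cohort(2000, 2000, h2=0.6, c2=0.2, seed=22)
        fit = ts.fit_ml(cohort.trait_arrays("bmi", ("age_c", "female")), "ACE")
        shares = ts.standardize(fit).shares
        assert shares["A"] == pytest.approx(0.6, abs=0.06)
        assert shares["C"] == pytest.approx(0.2, abs=0.06)
        assert shares["E"] == pytest.approx(0.2, abs=0.04)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-8)

    def test_optimum_matches_grid_search(self):
        """On a tiny instance the ML optimum agrees with a dense grid over
        the three path coefficients."""
        cohort = make_cohort(10, 10, h2=0.5, c2=0.2, seed=23)
        data = {z: lk.PairData(*v) for z, v in cohort.trait_arrays("bmi", ()).items()}
        beta = lk._pooled_ols(data)[0]

        fit = ts.fit_ml(data, "ACE")
        grid = np.linspace(0.0, 3.0, 40)
        best = -np.inf
        for a in grid:
            for c in grid:
                for e in grid[1:]:
                    ll = ts.fiml_loglik(
                        data, lk.PathParams("ACE", {"A": a, "C": c, "E": e}, beta)
                    )
                    best = max(best, ll)
        assert fit.loglik >= best - 0.05

    def test_mz_only_ace_is_unidentified(self):
        cohort = make_cohort(50, 0, h2=0.5, seed=24)
        with pytest.raises(ts.IdentifiabilityError):
            ts.fit_ml(cohort.trait_arrays("bmi", ()), "ACE")

    def test_saturated_bounds_structured(self, ae_cohort):
        data = ae_cohort.trait_arrays("bmi", ())
        sat = lk.fit_saturated(data)
        for family in ("ACE", "AE", "E"):
            fit = ts.fit_ml(data, family)
            assert fit.loglik <= sat.loglik + 1e-4

    def test_falconer_equivalence_large_n(self):
        """ML heritability from AE matches the method-of-moments
        2 (rMZ - rDZ) estimate at large n."""
        cohort = make_cohort(10_000, 10_000, h2=0.5, seed=25)
        from twinsem import univariate as uv

        fit = ts.fit_ml(cohort.trait_arrays("bmi", ()), "AE")
        h2_ml = ts.standardize(fit).shares["A"]
        tc = uv.twin_correlations(cohort, "bmi", ())
        falconer = 2 * (tc.r_mz - tc.r_dz)
        assert h2_ml == pytest.approx(falconer, abs=0.02)


class TestCompareModels:
    def test_identical_models_degenerate(self, ae_cohort):
        data = ae_cohort.trait_arrays("bmi", ())
        fit = ts.fit_ml(data, "AE")
        cmp = ts.compare_models(fit, fit)
        assert cmp["lrt_stat"] == 0.0 and cmp["p"] == 1.0 and cmp["df"] == 0

    def test_df_counts(self, ae_cohort):
        data = ae_cohort.trait_arrays("bmi", ())
        ace = ts.fit_ml(data, "ACE")
        ae = ts.fit_ml(data, "AE")
        e = ts.fit_ml(data, "E")
        assert ts.compare_models(ace, ae)["df"] == 1
        assert ts.compare_models(ace, e)["df"] == 2

    def test_non_nested_rejected(self, ae_cohort):
        data = ae_cohort.trait_arrays("bmi", ())
        ae = ts.fit_ml(data, "AE")
        ce = ts.fit_ml(data, "CE")
        with pytest.raises(lk.NestingError):
            ts.compare_models(ae, ce)

    def test_boundary_null_rejection_rate(self):
        """Dropping C when the true c2 = 0 sits on the parameter boundary:
        with the naive chi2_1 reference the LRT rejects in about 2.5% of
        replicates (half of nominal, the 50:50 mixture effect); the mixture
        correction restores about 5%."""
        naive = mixture = 0
        reps = 120
        for i in range(reps):
            cohort = make_cohort(250, 250, h2=0.5, seed=3000 + i)
            data = cohort.trait_arrays("bmi", ())
            ace = ts.fit_ml(data, "ACE")
            ae = ts.fit_ml(data, "AE")
            cmp = ts.compare_models(ace, ae)
            naive += cmp["p"] < 0.05
            mixture += lk.boundary_mixture_p(cmp["lrt_stat"], 1) < 0.05
        assert naive / reps < 0.07
        assert 0.005 <= mixture / reps <= 0.11


class TestProfileCI:
    def test_containment(self, ae_cohort):
        data = ae_cohort.trait_arrays("bmi", ())
        fit = ts.fit_ml(data, "AE")
        h2 = ts.standardize(fit).shares["A"]
        ci = ts.profile_ci(data, fit, "A")
        assert ci.lo <= h2 <= ci.hi
        assert 0.0 <= ci.lo and ci.hi <= 1.0

    def test_profile_close_to_wald_at_large_n(self):
        cohort = make_cohort(5000, 5000, h2=0.5, seed=26)
        data = cohort.trait_arrays("bmi", ())
        fit = ts.fit_ml(data, "AE")
        ci = ts.profile_ci(data, fit, "A")

        def neg(theta):
            paths = dict(zip(("A", "E"), theta[:2]))
            return -ts.fiml_loglik(data, lk.PathParams("AE", paths, theta[2:]))

        cov = lk.wald_theta_cov(neg, fit.theta)

        def share(theta):
            v = theta[:2] ** 2
            return v[0] / v.sum()

        _, lo, hi = lk.delta_ci(share, fit.theta, cov)
        assert (ci.hi - ci.lo) == pytest.approx(hi - lo, rel=0.15)
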