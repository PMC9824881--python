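"""Bivariate Cholesky model: expected covariance, derived correlations,
fitting, cross-path tests and the equal-correlation homogeneity test."""

import numpy as np
import pytest

import twinsem as ts
from twinsem import bivariate as bv
from twinsem import likelihood as lk

from conftest import make_cohort


def _params(a=(1.0, 0.0, 1.0), c=None, e=(1.0, 0.0, 1.0), beta=None):
    paths = {"a": a, "e": e}
    family = "AE"
    if c is not None:
        paths["c"] = c
        family = "ACE"
    return bv.CholeskyParams(family, paths, np.zeros(2) if beta is None else beta)


def _simulate_latent_cov(params, zygosity, n, rng):
    """Brute-force covariance of latent-factor scores under the path model,
    independent of the analytic construction."""
    k = {"a": {"MZ": 1.0, "DZ": 0.5}, "c": {"MZ": 1.0, "DZ": 1.0},
         "e": {"MZ": 0.0, "DZ": 0.0}}
    y = np.zeros((n, 4))
    for comp, (x11, x21, x22) in params.paths.items():
        L = np.array([[x11, 0.0], [x21, x22]])
        r = k[comp][zygosity]
        shared = rng.standard_normal((n, 2))
        own1 = rng.standard_normal((n, 2))
        own2 = rng.standard_normal((n, 2))
        f1 = np.sqrt(r) * shared + np.sqrt(1 - r) * own1
        f2 = np.sqrt(r) * shared + np.sqrt(1 - r) * own2
        y[:, :2] += f1 @ L.T
        y[:, 2:] += f2 @ L.T
    return np.cov(y.T)


class TestExpectedCovBivariate:
    def test_no_cross_paths_block_diagonal_per_trait(self):
        p = _params(a=(0.8, 0.0, 0.7), e=(0.6, 0.0, 0.5))
        cov = ts.expected_cov_bivariate(p, "MZ")
        assert cov[0, 1] == 0.0 and cov[0, 3] == 0.0 and cov[2, 1] == 0.0

    def test_closed_form_cross_twin_cross_trait(self):
        p = _params(a=(1.0, 1.0, 1.0), e=(0.0, 0.0, 0.0))
        cov = ts.expected_cov_bivariate(p, "DZ")
        assert cov[0, 3] == pytest.approx(0.5)  # half of a11 * a21

    def test_symmetric_psd(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = _params(a=tuple(rng.normal(0, 1, 3)),
                        c=tuple(rng.normal(0, 1, 3)),
                        e=tuple(rng.normal(0, 1, 3)))
            for zyg in ("MZ", "DZ"):
                cov = ts.expected_cov_bivariate(p, zyg)
                np.testing.assert_allclose(cov, cov.T, atol=1e-12)
                assert np.all(np.linalg.eigvalsh(cov) >= -1e-10)

    @pytest.mark.parametrize("zygosity", ["MZ", "DZ"])
    def test_matches_latent_factor_simulation(self, zygosity):
        rng = np.random.default_rng(9)
        p = _params(a=(0.8, 0.3, 0.6), c=(0.3, 0.1, 0.2), e=(0.5, 0.15, 0.45))
        analytic = ts.expected_cov_bivariate(p, zygosity)
        brute = _simulate_latent_cov(p, zygosity, 200_000, rng)
        np.testing.assert_allclose(brute, analytic, atol=0.02)


class TestDeriveStats:
    def test_zero_cross_path_zero_genetic_correlation(self):
        r = ts.derive_bivariate_stats(_params(a=(0.8, 0.0, 0.7)))
        assert r.r_a == 0.0

    def test_unit_paths_closed_form(self):
        r = ts.derive_bivariate_stats(_params(a=(1.0, 1.0, 1.0)))
        assert r.r_a == pytest.approx(1 / np.sqrt(2))

    def test_matches_latent_score_correlation(self):
        """r_a equals the correlation of the two traits' simulated additive
        genetic scores."""
        rng = np.random.default_rng(12)
        a = (0.9, 0.4, 0.55)
        r = ts.derive_bivariate_stats(_params(a=a))
        L = np.array([[a[0], 0.0], [a[1], a[2]]])
        scores = rng.standard_normal((500_000, 2)) @ L.T
        sim_r = np.corrcoef(scores.T)[0, 1]
        assert r.r_a == pytest.approx(sim_r, abs=0.01)

    def test_trait2_without_genetic_variance_undefined(self):
        r = ts.derive_bivariate_stats(_params(a=(0.8, 0.0, 0.0)))
        assert r.r_a is None

    def test_dropped_c_reported_as_structural_zero(self):
        r = ts.derive_bivariate_stats(_params())
        assert r.r_c == 0.0 and r.p_c == 0.0

    def test_decomposition_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = _params(a=tuple(rng.normal(0, 1, 3)),
                        c=tuple(rng.normal(0, 0.5, 3)),
                        e=tuple(0.3 + rng.random(3)))
            r = ts.derive_bivariate_stats(p)
            total = 0.0
            for rc, s1, s2 in ((r.r_a, r.h2_1, r.h2_2),
                               (r.r_c, r.c2_1, r.c2_2),
                               (r.r_e, r.e2_1, r.e2_2)):
                if rc is not None:
                    total += rc * np.sqrt(s1 * s2)
            assert total == pytest.approx(r.r_ph, abs=1e-6)


class TestFitBivariate:
    def test_parameter_recovery(self, biv_cohort):
        res = ts.fit_bivariate(biv_cohort, "bmi", "dbp", (), (), family="AE")
        r = res.result
        assert r.r_a == pytest.approx(0.39, abs=0.08)
        assert r.r_e == pytest.approx(0.20, abs=0.08)
        assert r.h2_1 == pytest.approx(0.6, abs=0.05)

    def test_null_cross_structure(self):
        cohort = make_cohort(1000, 1000, h2=0.6, seed=51,
                             second_trait=dict(name="DBP", h2=0.6))
        res = ts.fit_bivariate(cohort, "bmi", "dbp", (), (), family="AE")
        assert abs(res.result.r_ph) < 0.05

    def test_negative_genetic_correlation_supported(self):
        cohort = make_cohort(1000, 1000, h2=0.65, seed=52,
                             second_trait=dict(name="DBP", h2=0.65,
                                               r_a=-0.4, r_e=-0.15))
        res = ts.fit_bivariate(cohort, "bmi", "dbp", (), (), family="AE")
        r = res.result
        assert r.r_a < -0.2 and r.r_ph < 0
        assert 0.0 < r.p_a <= 1.0 + 1e-9

    def test_marginal_h2_matches_univariate(self, biv_cohort):
        res = ts.fit_bivariate(biv_cohort, "bmi", "dbp", (), (), family="AE")
        uni = ts.fit_ml(biv_cohort.trait_arrays("bmi", ()), "AE")
        h2_uni = ts.standardize(uni).shares["A"]
        assert res.result.h2_1 == pytest.approx(h2_uni, abs=0.03)

    def test_sign_coherence_with_sample_correlation(self, biv_cohort):
        res = ts.fit_bivariate(biv_cohort, "bmi", "dbp", (), (), family="AE")
        w = biv_cohort.wide
        sample_r = np.corrcoef(
            np.concatenate([w["bmi_1"], w["bmi_2"]]),
            np.concatenate([w["dbp_1"], w["dbp_2"]]),
        )[0, 1]
        assert np.sign(res.result.r_ph) == np.sign(sample_r)

    def test_optimum_matches_grid_on_cross_paths(self):
        """With trait-specific paths held at truth, the optimizer's optimum
        over the three cross paths matches a dense grid search."""
        cohort = make_cohort(150, 150, h2=0.6, seed=53,
                             second_trait=dict(name="DBP", h2=0.6,
                                               r_a=0.4, r_e=0.2))
        data = bv._standardized_biv_data(cohort, "bmi", "dbp", (), ())
        data = lk.as_pair_data(data)
        fit = ts.fit_bivariate(cohort, "bmi", "dbp", (), (), family="AE",
                               data=data)
        grid = np.linspace(-0.6, 0.6, 25)
        best = -np.inf
        fixed = fit.params
        for a21 in grid:
            for e21 in grid:
                p = bv.CholeskyParams("AE", {
                    "a": (fixed.paths["a"][0], a21, fixed.paths["a"][2]),
                    "e": (fixed.paths["e"][0], e21, fixed.paths["e"][2]),
                }, fixed.beta)
                ll = sum(
                    d.loglik(p.beta, ts.expected_cov_bivariate(p, z))
                    for z, d in data.items()
                )
                best = max(best, ll)
        assert fit.fit.loglik >= best - 1e-6


class TestCrossPathTests:
    def test_lrt_nonnegative_and_strong_a21_detected(self, biv_cohort):
        rows = ts.cross_path_tests(biv_cohort, "bmi", "dbp", (), (),
                                   family="AE")
        by_path = {r["path"]: r for r in rows}
        assert all(r["lrt"] >= 0 for r in rows)
        assert by_path["a21"]["p"] < 0.05  # r_a = 0.39 at n = 2,000 pairs
        assert by_path["a21"]["df"] == 1


class TestRHomogeneity:
    def test_identical_groups_high_p(self):
        cohort = make_cohort(400, 400, h2=0.6, seed=54,
                             second_trait=dict(name="DBP", h2=0.6,
                                               r_a=0.4, r_e=0.2))
        res = bv.bivariate_r_homogeneity({"A": cohort, "B": cohort},
                                         "bmi", "dbp", (), (), family="AE")
        assert res.p > 0.5
        assert res.df == 2  # (2 groups - 1) x {r_a, r_e}

    def test_detects_different_genetic_correlation(self):
        g1 = make_cohort(700, 700, h2=0.6, seed=55,
                         second_trait=dict(name="DBP", h2=0.6, r_a=0.5, r_e=0.2))
        g2 = make_cohort(700, 700, h2=0.6, seed=56,
                         second_trait=dict(name="DBP", h2=0.6, r_a=0.0, r_e=0.2))
        res = bv.bivariate_r_homogeneity({"G1": g1, "G2": g2},
                                         "bmi", "dbp", (), (), family="AE")
        assert res.p < 0.01
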