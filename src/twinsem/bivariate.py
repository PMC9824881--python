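"""Bivariate Cholesky twin models for (BMI, cardiometabolic trait) pairs.

Each of the A, C and E components loads on the two traits through a
lower-triangular 2x2 path matrix (a11, a21, a22 and analogues), so every
component covariance block is positive semi-definite by construction.  The
within-person block is Sigma_A + Sigma_C + Sigma_E; the cross-twin block is
k Sigma_A + Sigma_C with k = 1 (MZ) or 1/2 (DZ).

From a fitted model the phenotypic correlation r_ph decomposes as

    r_ph = r_a sqrt(h2_1 h2_2) + r_c sqrt(c2_1 c2_2) + r_e sqrt(e2_1 e2_2)

where r_a = a11 a21 / sqrt(a11^2 (a21^2 + a22^2)) is the genetic correlation
(r_c, r_e analogous) and h2_i, c2_i, e2_i are the per-trait standardized
shares.  The genetic share of the phenotypic correlation is
p_a = r_a sqrt(h2_1 h2_2) / r_ph, and p_e analogously; p_a + p_e = 1 when
the C block is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import likelihood as lk
from .cohort import PairedCohort

logger = logging.getLogger(__name__)

_COMPONENTS = {"ACE": ("a", "c", "e"), "AE": ("a", "e")}
_KAPPA = {"a": {"MZ": 1.0, "DZ": 0.5}, "c": {"MZ": 1.0, "DZ": 1.0},
          "e": {"MZ": 0.0, "DZ": 0.0}}
_PATH_NAMES = ("11", "21", "22")


@dataclass
class CholeskyParams:
    """Lower-triangular paths per component plus the two means models.

    ``paths`` maps component letter ('a', 'c', 'e') to the triple
    (x11, x21, x22); a dropped C block is simply absent.  ``beta`` holds the
    stacked means-model coefficients (trait 1 then trait 2).
    """

    family: str
    paths: dict[str, tuple[float, float, float]]
    beta: np.ndarray

    def block(self, comp: str) -> np.ndarray:
        """Component covariance block L @ L.T (2x2, PSD by construction)."""
        if comp not in self.paths:
            return np.zeros((2, 2))
        x11, x21, x22 = self.paths[comp]
        L = np.array([[x11, 0.0], [x21, x22]])
        return L @ L.T


@dataclass
class BivariateResult:
    """Derived correlations and shares from a bivariate fit."""

    r_ph: float
    r_a: float | None
    r_c: float | None
    r_e: float | None
    p_a: float | None
    p_c: float | None
    p_e: float | None
    h2_1: float
    h2_2: float
    c2_1: float
    c2_2: float
    e2_1: float
    e2_2: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class BivariateFit:
    trait_x: str
    trait_y: str
    fit: lk.FitResult
    params: CholeskyParams
    result: BivariateResult


def expected_cov_bivariate(params: CholeskyParams, zygosity: str) -> np.ndarray:
    """4x4 expected covariance, member-major order
    (x_m1, y_m1, x_m2, y_m2)."""
    within = sum(params.block(c) for c in params.paths)
    cross = sum(_KAPPA[c][zygosity] * params.block(c) for c in params.paths)
    return np.block([[within, cross], [cross, within]])


def _corr(block: np.ndarray) -> float | None:
    v1, v2 = block[0, 0], block[1, 1]
    if v1 <= 1e-12 or v2 <= 1e-12:
        return None
    return float(block[0, 1] / np.sqrt(v1 * v2))


def derive_bivariate_stats(params: CholeskyParams) -> BivariateResult:
    """Correlation decomposition of a fitted Cholesky parameter set.

    A component correlation is undefined (None, reported missing) when the
    component has no variance on one of the traits; the corresponding term
    contributes zero covariance to r_ph.
    """
    blocks = {c: params.block(c) for c in ("a", "c", "e")}
    within = sum(blocks.values())
    v1, v2 = within[0, 0], within[1, 1]
    r_ph = float(within[0, 1] / np.sqrt(v1 * v2))
    rs = {c: _corr(b) for c, b in blocks.items()}
    shares1 = {c: float(b[0, 0] / v1) for c, b in blocks.items()}
    shares2 = {c: float(b[1, 1] / v2) for c, b in blocks.items()}
    ps = {}
    for c, b in blocks.items():
        if c not in params.paths:
            ps[c] = 0.0 if c == "c" else None
            continue
        term = float(b[0, 1] / np.sqrt(v1 * v2))  # signed covariance share
        ps[c] = term / r_ph if abs(r_ph) > 1e-12 else None
    if "c" not in params.paths:
        rs["c"] = 0.0  # structural zero, not missing
        ps["c"] = 0.0
    return BivariateResult(
        r_ph=r_ph, r_a=rs["a"], r_c=rs["c"], r_e=rs["e"],
        p_a=ps["a"], p_c=ps["c"], p_e=ps["e"],
        h2_1=shares1["a"], h2_2=shares2["a"],
        c2_1=shares1["c"], c2_2=shares2["c"],
        e2_1=shares1["e"], e2_2=shares2["e"],
    )


# ---------------------------------------------------------------------------
# fitting


def _theta_layout(family: str, drop: frozenset[str]):
    """Free-parameter names for the path part of theta."""
    return [
        comp + suffix
        for comp in _COMPONENTS[family]
        for suffix in _PATH_NAMES
        if comp + suffix not in drop
    ]


def _params_from_theta(theta, names, family, beta_dim) -> CholeskyParams:
    vals = dict(zip(names, theta[: len(names)]))
    paths = {}
    for comp in _COMPONENTS[family]:
        paths[comp] = tuple(vals.get(comp + s, 0.0) for s in _PATH_NAMES)
    return CholeskyParams(family, paths, np.asarray(theta[len(names):]))


def _standardized_biv_data(cohort, col_x, col_y, covariates_x, covariates_y):
    from .cohort import drop_constant_covariates

    data = cohort.bivariate_arrays(col_x, col_y, covariates_x, covariates_y)
    data = drop_constant_covariates(data)
    out = {}
    scale = {}
    for t, idx in (("x", (0, 2)), ("y", (1, 3))):
        vals = np.concatenate(
            [y[:, idx][np.isfinite(y[:, idx])] for y, _ in data.values()]
        )
        scale[t] = (vals.mean(), vals.std(ddof=1))
    for zyg, (y, X) in data.items():
        y = y.copy()
        for t, idx in (("x", [0, 2]), ("y", [1, 3])):
            mu, sd = scale[t]
            y[:, idx] = (y[:, idx] - mu) / sd
        out[zyg] = (y, X)
    return out


def fit_bivariate(
    cohort: PairedCohort,
    col_x: str,
    col_y: str,
    covariates_x: tuple[str, ...] = ("age_c", "female"),
    covariates_y: tuple[str, ...] = ("age_c", "female"),
    family: str = "ACE",
    drop: frozenset[str] | set[str] = frozenset(),
    options: lk.FitOptions | None = None,
    ci: bool = False,
    data=None,
    init: CholeskyParams | None = None,
) -> BivariateFit:
    """Maximize the 4-dimensional FIML likelihood of the Cholesky model.

    ``drop`` names cross or trait-specific paths fixed to zero (e.g.
    {'a21'}) for constraint tests.  Both traits are z-scored internally;
    all reported quantities are standardized and scale-invariant.  With
    ``ci=True``, delta-method CIs from the observed information are attached
    to the derived quantities.
    """
    options = options or lk.FitOptions()
    if family not in _COMPONENTS:
        raise ValueError("bivariate families are ACE and AE")
    if data is None:
        data = _standardized_biv_data(cohort, col_x, col_y, covariates_x, covariates_y)
    data = lk.as_pair_data(data)
    for zyg in ("MZ", "DZ"):
        if data.get(zyg) is None or data[zyg].n_used < 2:
            raise lk.IdentifiabilityError(
                f"bivariate {family} fit needs >=2 pairs in each zygosity group"
            )
    drop = frozenset(drop)
    names = _theta_layout(family, drop)
    p = next(iter(data.values())).p

    def neg(theta):
        params = _params_from_theta(theta, names, family, p)
        ll = 0.0
        for zyg, pd_ in data.items():
            ll += pd_.loglik(params.beta, expected_cov_bivariate(params, zyg))
        return -ll

    starts = _bivariate_starts(data, names, family, options)
    if init is not None:
        flat = _flat_paths(init)
        beta0 = init.beta if len(init.beta) == p else starts[0][len(names):]
        starts = [np.concatenate([[flat.get(n, 0.0) for n in names], beta0])] + starts[:-1]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": options.ftol,
                     "gtol": options.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x.copy()
    # fix reflection indeterminacy: diagonal paths and each component's
    # leading path non-negative (signs of whole columns are unidentified)
    params = _params_from_theta(theta, names, family, p)
    params = _canonicalize(params)
    ll = -best.fun
    gnorm = float(np.max(np.abs(best.jac)))
    fit = lk.FitResult(
        family=family,
        params=None,
        loglik=ll,
        n_params=len(names) + p,
        converged=bool(best.success) or gnorm <= options.gtol * max(1.0, abs(ll)),
        gradient_norm=gnorm,
        n_pairs_used={z: d.n_used for z, d in data.items()},
        theta=np.concatenate([[_flat_paths(params)[n] for n in names], params.beta]),
        label=f"{family}-chol" + (f"-drop({','.join(sorted(drop))})" if drop else ""),
        component_names=tuple(names),  # free path names define nesting
        seed=options.seed,
    )
    result = derive_bivariate_stats(params)
    bf = BivariateFit(col_x, col_y, fit, params, result)
    if ci:
        result.ci.update(_bivariate_delta_cis(neg, fit.theta, names, family, p))
    return bf


def _flat_paths(params: CholeskyParams) -> dict[str, float]:
    return {
        comp + s: params.paths[comp][i]
        for comp in params.paths
        for i, s in enumerate(_PATH_NAMES)
    }


def _canonicalize(params: CholeskyParams) -> CholeskyParams:
    """Resolve sign indeterminacy: each component's column signs are chosen
    so x11 >= 0 and x22 >= 0 (the cross path x21 keeps its relative sign)."""
    paths = {}
    for comp, (x11, x21, x22) in params.paths.items():
        s1 = -1.0 if x11 < 0 else 1.0
        s2 = -1.0 if x22 < 0 else 1.0
        paths[comp] = (x11 * s1, x21 * s1, x22 * s2)
    return CholeskyParams(params.family, paths, params.beta)


def _bivariate_starts(data, names, family, options: lk.FitOptions):
    # moment-based start: per-trait univariate shares and cross correlation
    ys, Xs = [], []
    for pd_ in data.values():
        obs = np.isfinite(pd_.y)
        ys.append(pd_.y[obs]); Xs.append(pd_.X[obs])
    beta0, *_ = np.linalg.lstsq(np.concatenate(Xs), np.concatenate(ys), rcond=None)
    base = {}
    for comp in _COMPONENTS[family]:
        amp = {"a": 0.6, "c": 0.3, "e": 0.55}[comp]
        base.update({comp + "11": amp, comp + "21": 0.1 * amp, comp + "22": amp})
    x0 = np.concatenate([[base[n] for n in names], beta0])
    rng = np.random.default_rng(options.seed)
    starts = [x0]
    while len(starts) < options.n_starts:
        pert = x0.copy()
        pert[: len(names)] *= np.exp(rng.normal(0.0, 0.3, len(names)))
        pert[: len(names)] += rng.normal(0.0, 0.05, len(names))
        starts.append(pert)
    return starts


_DERIVED = ("r_ph", "r_a", "r_c", "r_e", "p_a", "p_e", "h2_1", "h2_2", "e2_1", "e2_2")


def _bivariate_delta_cis(neg, theta, names, family, beta_dim, level=0.95):
    cov = lk.wald_theta_cov(neg, theta)
    out = {}
    for q in _DERIVED:
        if family == "AE" and q in ("r_c",):
            continue

        def qfn(th, q=q):
            params = _params_from_theta(th, names, family, beta_dim)
            val = getattr(derive_bivariate_stats(params), q)
            return np.nan if val is None else val

        if not np.isfinite(qfn(theta)):
            continue
        val, lo, hi = lk.delta_ci(qfn, theta, cov, level)
        if q.startswith("r_"):
            lo, hi = max(lo, -1.0), min(hi, 1.0)
        out[q] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# constraint tests


def cross_path_tests(
    cohort: PairedCohort,
    col_x: str,
    col_y: str,
    covariates_x=("age_c", "female"),
    covariates_y=("age_c", "female"),
    family: str = "ACE",
    options: lk.FitOptions | None = None,
    full: BivariateFit | None = None,
) -> list[dict]:
    """LRT of each cross path (a21, c21, e21) fixed to zero against the full
    bivariate model; one row per path with the statistic, df and p-value."""
    options = options or lk.FitOptions()
    data = _standardized_biv_data(cohort, col_x, col_y, covariates_x, covariates_y)
    if full is None:
        full = fit_bivariate(cohort, col_x, col_y, covariates_x, covariates_y,
                             family=family, options=options, data=data)
    from dataclasses import replace as _replace

    sub_opts = _replace(options, n_starts=2)
    rows = []
    for comp in _COMPONENTS[family]:
        path = comp + "21"
        constrained = fit_bivariate(
            cohort, col_x, col_y, covariates_x, covariates_y,
            family=family, drop={path}, options=sub_opts, data=data,
            init=full.params,
        )
        cmp = lk.compare_models(full.fit, constrained.fit)
        rows.append({"path": path, "lrt": cmp["lrt_stat"], "df": cmp["df"],
                     "p": cmp["p"], "delta_aic": cmp["delta_aic"]})
    return rows


# ---------------------------------------------------------------------------
# multigroup homogeneity of the component correlations


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


def fit_bivariate_multigroup_equal_r(
    datasets: dict[str, dict],
    family: str = "AE",
    options: lk.FitOptions | None = None,
    init_free: dict[str, "BivariateFit"] | None = None,
) -> lk.FitResult:
    """Constrained multigroup bivariate fit with the genetic and unique
    environmental correlations (and r_c under ACE) equated across groups.

    Parameterized directly in standardized quantities: per group the
    per-trait shares, the two trait scales and the means coefficients are
    free; the component correlations are shared.  df versus the free model
    is (n_groups - 1) x n_shared_correlations.
    """
    options = options or lk.FitOptions()
    groups = sorted(datasets)
    data = {g: lk.as_pair_data(datasets[g]) for g in groups}
    ps = {g: next(iter(data[g].values())).p for g in groups}
    comps = _COMPONENTS[family]
    n_r = len(comps) if family == "ACE" else 2  # ra, (rc), re

    def build_cov(shares1, shares2, rs, s1, s2, zyg):
        blocks = {}
        for i, comp in enumerate(comps):
            v1, v2 = shares1[comp], shares2[comp]
            cov = rs[i] * np.sqrt(v1 * v2)
            blocks[comp] = np.array([[v1, cov], [cov, v2]])
        within = sum(blocks.values())
        cross = sum(_KAPPA[c][zyg] * blocks[c] for c in comps)
        D = np.diag([s1, s2])
        DD = np.block([[D, np.zeros((2, 2))], [np.zeros((2, 2)), D]])
        return DD @ np.block([[within, cross], [cross, within]]) @ DD

    def shares_from(u1, u2=None):
        if family == "AE":
            h = _sigmoid(u1)
            return {"a": h, "e": 1.0 - h}
        h = _sigmoid(u1)
        c = (1.0 - h) * _sigmoid(u2)
        return {"a": h, "c": c, "e": 1.0 - h - c}

    n_share_u = 1 if family == "AE" else 2

    def split(theta):
        rs = np.tanh(theta[:n_r])
        pos = n_r
        per_group = {}
        for g in groups:
            u1 = theta[pos: pos + n_share_u]
            pos += n_share_u
            u2 = theta[pos: pos + n_share_u]
            pos += n_share_u
            ls = theta[pos: pos + 2]
            pos += 2
            beta = theta[pos: pos + ps[g]]
            pos += ps[g]
            per_group[g] = (u1, u2, ls, beta)
        return rs, per_group

    def neg(theta):
        rs, per_group = split(theta)
        ll = 0.0
        for g in groups:
            u1, u2, ls, beta = per_group[g]
            sh1 = shares_from(*u1)
            sh2 = shares_from(*u2)
            s1, s2 = np.exp(np.clip(ls, -15, 15))
            for zyg, pd_ in data[g].items():
                cov = build_cov(sh1, sh2, rs, s1, s2, zyg)
                ll += pd_.loglik(beta, cov)
        return -ll

    def _logit(x):
        x = float(np.clip(x, 1e-4, 1 - 1e-4))
        return np.log(x / (1.0 - x))

    x0_parts = [np.zeros(n_r)]
    if init_free:
        rs0 = {"a": [], "c": [], "e": []}
        for g in groups:
            r = init_free[g].result
            rs0["a"].append(r.r_a or 0.0)
            rs0["c"].append(r.r_c or 0.0)
            rs0["e"].append(r.r_e or 0.0)
        order = comps if family == "ACE" else ("a", "e")
        x0_parts = [np.arctanh(np.clip([np.mean(rs0[c]) for c in order], -0.99, 0.99))]
    for g in groups:
        ys, Xs = [], []
        for pd_ in data[g].values():
            obs = np.isfinite(pd_.y)
            ys.append(pd_.y[obs]); Xs.append(pd_.X[obs])
        beta0, *_ = np.linalg.lstsq(np.concatenate(Xs), np.concatenate(ys), rcond=None)
        if init_free:
            r = init_free[g].result
            beta_free = init_free[g].params.beta
            if len(beta_free) == ps[g]:
                beta0 = beta_free
            if family == "AE":
                u = [[_logit(r.h2_1)], [_logit(r.h2_2)]]
            else:
                u = [
                    [_logit(r.h2_1), _logit(r.c2_1 / max(1 - r.h2_1, 1e-4))],
                    [_logit(r.h2_2), _logit(r.c2_2 / max(1 - r.h2_2, 1e-4))],
                ]
            x0_parts += [np.ravel(u[0]), np.ravel(u[1]), np.zeros(2), beta0]
        else:
            x0_parts += [np.zeros(2 * n_share_u), np.zeros(2), beta0]
    x0 = np.concatenate(x0_parts)
    rng = np.random.default_rng(options.seed)
    n_starts = 1 if init_free else max(options.n_starts // 2, 1)
    best = None
    for s in range(n_starts):
        xs = x0 if s == 0 else x0 + rng.normal(0, 0.2, len(x0))
        res = optimize.minimize(
            neg, xs, method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": options.ftol,
                     "gtol": options.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    # identified params: n_r shared + per group (2 share u's per trait? ->
    # n_share_u * 2 + 2 scales + beta)
    n_params = n_r + sum(2 * n_share_u + 2 + ps[g] for g in groups)
    return lk.FitResult(
        family=family,
        params=None,
        loglik=-best.fun,
        n_params=n_params,
        converged=bool(best.success),
        gradient_norm=float(np.max(np.abs(best.jac))),
        n_pairs_used={g: sum(d.n_used for d in data[g].values()) for g in groups},
        theta=best.x,
        label=f"{family}-equal-r",
        component_names=tuple(_theta_layout(family, frozenset())),
    )


@dataclass
class BivariateHomogeneity:
    """Equal-correlation test across groups, with the per-group free fits
    retained (their derived r_a/r_e are the per-group trend estimates)."""

    lrt_stat: float
    df: int
    p: float
    free: dict[str, BivariateFit]
    constrained_fit: lk.FitResult


def bivariate_r_homogeneity(
    cohorts_by_group: dict[str, PairedCohort],
    col_x: str,
    col_y: str,
    covariates_x=("age_c", "female"),
    covariates_y=("age_c", "female"),
    family: str = "AE",
    options: lk.FitOptions | None = None,
) -> BivariateHomogeneity:
    """Test whether the genetic/environmental correlations between two
    traits can be equated across groups (free per-group Cholesky fits versus
    the equal-correlation constrained fit, warm-started from the free
    solutions)."""
    options = options or lk.FitOptions()
    datasets = {}
    free_fits: dict[str, BivariateFit] = {}
    for group, cohort in sorted(cohorts_by_group.items()):
        data = _standardized_biv_data(cohort, col_x, col_y, covariates_x, covariates_y)
        datasets[group] = data
        free_fits[group] = fit_bivariate(
            cohort, col_x, col_y, covariates_x, covariates_y,
            family=family, options=options, data=data,
        )
    free = lk.combine_free_fits({g: f.fit for g, f in free_fits.items()})
    constrained = fit_bivariate_multigroup_equal_r(
        datasets, family, options, init_free=free_fits
    )
    cmp = lk.compare_models(free, constrained)
    return BivariateHomogeneity(cmp["lrt_stat"], cmp["df"], cmp["p"],
                                free_fits, constrained)
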