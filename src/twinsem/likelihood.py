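"""Gaussian full-information likelihood machinery for twin-pair models.

A twin pair is one observation unit.  Under the biometrical model the two
members' trait values are bivariate normal with mean ``X @ beta`` (the
covariate means model, one coefficient vector shared by both members) and a
zygosity-specific covariance built from latent variance components:

* additive genetic (A): cross-twin correlation 1 in MZ, 1/2 in DZ pairs;
* shared environment (C): cross-twin correlation 1 in both;
* genetic dominance (D): cross-twin correlation 1 in MZ, 1/4 in DZ;
* unique environment (E, includes measurement error): uncorrelated.

C and D are not jointly identifiable in twins reared together, so the model
families are ACE, ADE and their submodels AE, CE and E.  E is never dropped.

Parameters are raw path coefficients; variances enter as their squares, so
non-negativity of every component is automatic and the optimizer runs
unconstrained.  Pairs with one member's trait missing contribute the
univariate marginal density (full-information ML) rather than being dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_NEG_INF = -1e12  # optimizer-safe sentinel for a non-PD covariance

FAMILY_COMPONENTS: dict[str, tuple[str, ...]] = {
    "ACE": ("A", "C", "E"),
    "ADE": ("A", "D", "E"),
    "AE": ("A", "E"),
    "CE": ("C", "E"),
    "E": ("E",),
}

#: cross-twin loading of each component's variance
KAPPA = {
    "A": {"MZ": 1.0, "DZ": 0.5},
    "C": {"MZ": 1.0, "DZ": 1.0},
    "D": {"MZ": 1.0, "DZ": 0.25},
    "E": {"MZ": 0.0, "DZ": 0.0},
}

SHARE_NAMES = {"A": "h2", "C": "c2", "D": "d2", "E": "e2"}


class IdentifiabilityError(ValueError):
    """The requested model is not identifiable from the available pairs."""


class NestingError(ValueError):
    """Model comparison requested for non-nested fits."""


# ---------------------------------------------------------------------------
# data container


class PairData:
    """Pre-grouped (y, X) arrays for fast repeated likelihood evaluation.

    Rows are observation units (pairs); ``y`` is (n, d) with NaN for missing
    entries and ``X`` is (n, d, p).  Rows are grouped once by missingness
    pattern so each likelihood evaluation is a handful of vectorized
    Gaussian density computations.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        if y.ndim != 2 or X.ndim != 3 or X.shape[:2] != y.shape:
            raise ValueError("y must be (n, d) and X must be (n, d, p)")
        self.y, self.X = y, X
        self.n, self.d = y.shape
        self.p = X.shape[2]
        obs = np.isfinite(y)
        codes = obs @ (1 << np.arange(self.d))
        self.patterns: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for code in np.unique(codes):
            if code == 0:
                continue
            cols = np.array([(int(code) >> j) & 1 for j in range(self.d)], bool)
            rows = np.flatnonzero(codes == code)
            self.patterns.append((cols, y[np.ix_(rows, np.flatnonzero(cols))],
                                  X[np.ix_(rows, np.flatnonzero(cols))]))
        self.n_used = int(obs.any(axis=1).sum())

    def loglik(self, beta: np.ndarray, cov: np.ndarray) -> float:
        """FIML log-likelihood under mean ``X @ beta``, covariance ``cov``."""
        total = 0.0
        for cols, ysub, Xsub in self.patterns:
            sub = cov[np.ix_(cols, cols)]
            try:
                L = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return _NEG_INF
            r = ysub - Xsub @ beta
            z = solve_triangular(L, r.T, lower=True)
            k, m = sub.shape[0], len(ysub)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            total += -0.5 * m * (k * _LOG2PI + logdet) - 0.5 * float((z * z).sum())
        return total


def as_pair_data(data) -> dict[str, PairData]:
    """Wrap a ``{zygosity: (y, X)}`` mapping into :class:`PairData` objects."""
    out = {}
    for zyg, value in data.items():
        out[zyg] = value if isinstance(value, PairData) else PairData(*value)
    return out


# ---------------------------------------------------------------------------
# parameters and results


@dataclass
class PathParams:
    """Univariate path coefficients plus means-model coefficients.

    ``paths`` maps component letter -> path coefficient; dropped components
    are absent (variance fixed at exactly 0).  Path signs are not identified
    (only squares enter the covariance), so coefficients are reported as
    absolute values.
    """

    family: str
    paths: dict[str, float]
    beta: np.ndarray

    @property
    def variances(self) -> dict[str, float]:
        return {c: v * v for c, v in self.paths.items()}

    @property
    def total_variance(self) -> float:
        return sum(self.variances.values())


@dataclass
class VarianceComponents:
    """Standardized variance shares (sum to one) with optional CIs."""

    family: str
    shares: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def h2(self) -> float:
        return self.shares.get("A", 0.0)

    @property
    def c2(self) -> float:
        return self.shares.get("C", 0.0)

    @property
    def d2(self) -> float:
        return self.shares.get("D", 0.0)

    @property
    def e2(self) -> float:
        return self.shares.get("E", 0.0)


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    family: str
    params: PathParams | None
    loglik: float
    n_params: int
    converged: bool
    gradient_norm: float
    n_pairs_used: dict[str, int]
    theta: np.ndarray | None = None
    label: str = ""
    component_names: tuple[str, ...] = ()
    seed: int | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


@dataclass
class FitOptions:
    n_starts: int = 5
    seed: int = 2024
    gtol: float = 1e-5
    ftol: float = 1e-10
    maxiter: int = 2000


# ---------------------------------------------------------------------------
# expected covariance and likelihood


def expected_cov_univariate(params: PathParams | dict, zygosity: str) -> np.ndarray:
    """2x2 expected twin-pair covariance for one trait.

    Diagonal: total variance (sum of squared paths).  Off-diagonal: each
    component's variance times its cross-twin loading — a^2 + c^2 for MZ,
    a^2/2 + c^2 for DZ under ACE; a^2 + d^2 (MZ) and a^2/2 + d^2/4 (DZ)
    under ADE.
    """
    paths = params.paths if isinstance(params, PathParams) else params
    total = sum(v * v for v in paths.values())
    off = sum(KAPPA[c][zygosity] * v * v for c, v in paths.items())
    return np.array([[total, off], [off, total]])


def fiml_loglik(data, params: PathParams) -> float:
    """Sum of per-pair Gaussian log densities across zygosity groups."""
    data = as_pair_data(data)
    total = 0.0
    for zyg, pd_ in data.items():
        total += pd_.loglik(params.beta, expected_cov_univariate(params, zyg))
    return total


# ---------------------------------------------------------------------------
# fitting


def _pooled_ols(data: dict[str, PairData]) -> tuple[np.ndarray, float]:
    """Quick pooled OLS of all observed member values on the design."""
    ys, Xs = [], []
    for pd_ in data.values():
        obs = np.isfinite(pd_.y)
        ys.append(pd_.y[obs])
        Xs.append(pd_.X[obs])
    yv = np.concatenate(ys)
    Xv = np.concatenate(Xs)
    beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = yv - Xv @ beta
    return beta, float(resid.var(ddof=Xv.shape[1]))


def _moment_shares(data: dict[str, PairData], beta: np.ndarray) -> tuple[float, float, float]:
    """(r_mz, r_dz, residual variance) from quick residual correlations."""
    rs, var = {}, 1.0
    for zyg, pd_ in data.items():
        r = pd_.y - pd_.X @ beta
        ok = np.isfinite(r).all(axis=1)
        if ok.sum() >= 3:
            c = np.corrcoef(r[ok, 0], r[ok, 1])[0, 1]
        else:
            c = 0.0
        rs[zyg] = float(np.clip(c, -0.95, 0.95))
        if ok.sum() >= 3:
            var = float(np.nanvar(r[ok], ddof=1))
    return rs.get("MZ", 0.0), rs.get("DZ", 0.0), max(var, 1e-6)


def _start_points(
    data: dict[str, PairData], family: str, options: FitOptions
) -> list[np.ndarray]:
    comps = FAMILY_COMPONENTS[family]
    beta0, v0 = _pooled_ols(data)
    rmz, rdz, v = _moment_shares(data, beta0)
    v = max(v0, 1e-6)
    if family == "ADE":
        # rmz = a2 + d2, rdz = a2/2 + d2/4 -> a2 = 4 rdz - rmz, d2 = 2 rmz - 4 rdz
        a2 = np.clip(4.0 * rdz - rmz, 0.02, 0.95)
        d2 = np.clip(2.0 * rmz - 4.0 * rdz, 0.02, 0.95)
        c2 = 0.0
    else:
        a2 = np.clip(2.0 * (rmz - rdz), 0.02, 0.95)
        c2 = np.clip(2.0 * rdz - rmz, 0.02, 0.95)
        d2 = 0.0
    shares = {"A": a2, "C": c2, "D": d2}
    used = {c: shares.get(c, 0.0) for c in comps if c != "E"}
    s = sum(used.values())
    if s > 0.9:
        used = {c: 0.9 * val / s for c, val in used.items()}
    used["E"] = 1.0 - sum(used.values())
    base = np.concatenate(
        [[np.sqrt(max(used[c], 0.02) * v) for c in comps], beta0]
    )
    rng = np.random.default_rng(options.seed)
    starts = [base]
    equal = np.concatenate(
        [[np.sqrt(v / len(comps))] * len(comps), beta0]
    )
    starts.append(equal)
    while len(starts) < options.n_starts:
        pert = base.copy()
        k = len(comps)
        pert[:k] *= np.exp(rng.normal(0.0, 0.4, k))
        pert[k:] += rng.normal(0.0, 0.1 * max(np.sqrt(v), 1e-3), len(beta0))
        starts.append(pert)
    return starts


def _minimize(neg, x0, options: FitOptions):
    return optimize.minimize(
        neg,
        x0,
        method="L-BFGS-B",
        options={"maxiter": options.maxiter, "ftol": options.ftol, "gtol": options.gtol},
    )


def fit_ml(
    data,
    family: str = "ACE",
    options: FitOptions | None = None,
    label: str = "",
) -> FitResult:
    """Maximize the FIML likelihood of a univariate twin model.

    Multi-start L-BFGS-B over path coefficients and means-model
    coefficients; the best of ``n_starts`` seeded starts is kept.  Raises
    :class:`IdentifiabilityError` when A and C (or D) cannot be separated
    because one zygosity group has fewer than two pairs.
    """
    options = options or FitOptions()
    data = as_pair_data(data)
    comps = FAMILY_COMPONENTS[family]
    if family in ("ACE", "ADE"):
        for zyg in ("MZ", "DZ"):
            if data.get(zyg) is None or data[zyg].n_used < 2:
                raise IdentifiabilityError(
                    f"family {family} needs >=2 MZ and >=2 DZ pairs; "
                    f"{zyg} group has too few"
                )
    k = len(comps)

    def unpack(theta):
        return dict(zip(comps, theta[:k])), theta[k:]

    def neg(theta):
        paths, beta = unpack(theta)
        ll = 0.0
        for zyg, pd_ in data.items():
            ll += pd_.loglik(beta, expected_cov_univariate(paths, zyg))
        return -ll

    best = None
    for x0 in _start_points(data, family, options):
        res = _minimize(neg, x0, options)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x.copy()
    theta[:k] = np.abs(theta[:k])  # path signs are not identified
    paths, beta = unpack(theta)
    ll = -best.fun
    gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
    converged = bool(best.success) or gnorm <= options.gtol * max(1.0, abs(ll))
    if not converged:
        logger.warning("fit %s (%s) did not converge: %s", family, label, best.message)
    return FitResult(
        family=family,
        params=PathParams(family, paths, beta),
        loglik=ll,
        n_params=k + len(beta),
        converged=converged,
        gradient_norm=gnorm,
        n_pairs_used={z: d.n_used for z, d in data.items()},
        theta=theta,
        label=label or family,
        component_names=comps,
        seed=options.seed,
    )


def standardize(fit: FitResult) -> VarianceComponents:
    """Standardized shares: each squared path over the total variance."""
    var = fit.params.variances
    total = sum(var.values())
    return VarianceComponents(fit.family, {c: v / total for c, v in var.items()})


def fit_saturated(data, options: FitOptions | None = None) -> FitResult:
    """Per-zygosity unstructured 2x2 covariance with a common means model.

    Upper reference point: no structured twin model can exceed its maximized
    likelihood on the same data.
    """
    options = options or FitOptions()
    data = as_pair_data(data)
    zygs = sorted(data)
    p = next(iter(data.values())).p

    def covs(theta):
        out = {}
        for i, zyg in enumerate(zygs):
            l11, l21, l22 = theta[3 * i : 3 * i + 3]
            L = np.array([[l11, 0.0], [l21, l22]])
            out[zyg] = L @ L.T
        return out

    def neg(theta):
        beta = theta[3 * len(zygs):]
        cv = covs(theta)
        return -sum(pd_.loglik(beta, cv[z]) for z, pd_ in data.items())

    beta0, v0 = _pooled_ols(data)
    x0 = np.concatenate([[np.sqrt(v0), 0.3 * np.sqrt(v0), np.sqrt(0.8 * v0)] * len(zygs), beta0])
    res = _minimize(neg, x0, options)
    return FitResult(
        family="saturated",
        params=None,
        loglik=-res.fun,
        n_params=3 * len(zygs) + p,
        converged=bool(res.success),
        gradient_norm=float(np.max(np.abs(res.jac))),
        n_pairs_used={z: d.n_used for z, d in data.items()},
        theta=res.x,
        label="saturated",
    )


# ---------------------------------------------------------------------------
# model comparison


def compare_models(full: FitResult, nested: FitResult, clip: bool = True) -> dict:
    """Likelihood-ratio test of a nested against a fuller model.

    ``lrt_stat = 2 (ll_full - ll_nested)``, clipped at zero for numerical
    noise; the p-value uses the chi-square reference with df equal to the
    parameter-count difference (the naive reference standard in the twin
    literature; see :func:`boundary_mixture_p` for the 50:50 mixture
    correction at a variance boundary).
    """
    if full.component_names and nested.component_names:
        if not set(nested.component_names) <= set(full.component_names):
            raise NestingError(
                f"{nested.label or nested.family} is not nested in "
                f"{full.label or full.family}"
            )
    df = full.n_params - nested.n_params
    if df < 0:
        raise NestingError("nested model has more parameters than the full model")
    stat = 2.0 * (full.loglik - nested.loglik)
    if clip:
        stat = max(stat, 0.0)
    if df == 0:
        p = 1.0 if abs(stat) < 1e-6 else 0.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return {
        "lrt_stat": float(stat),
        "df": int(df),
        "p": p,
        "delta_aic": float(nested.aic - full.aic),
    }


def boundary_mixture_p(stat: float, df: int = 1) -> float:
    """p-value under the 50:50 mixture (chi2_{df-1} : chi2_df) reference,
    appropriate when the constrained parameter is a variance on its
    boundary."""
    if stat <= 0:
        return 1.0
    lower = stats.chi2.sf(stat, df - 1) if df > 1 else 0.0
    return float(0.5 * lower + 0.5 * stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# profile confidence intervals (standardized shares)


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


@dataclass
class ProfileCI:
    lo: float
    hi: float
    level: float
    lo_at_boundary: bool = False
    hi_at_boundary: bool = False


def _unit_correlation(shares: dict[str, float], zygosity: str) -> float:
    return sum(KAPPA[c][zygosity] * s for c, s in shares.items())


def profile_ci(
    data,
    fit: FitResult,
    component: str,
    level: float = 0.95,
    options: FitOptions | None = None,
    xtol: float = 2e-4,
) -> ProfileCI:
    """Profile-likelihood CI for one standardized variance share.

    The share of ``component`` is fixed at a trial value t; the remaining
    shares (re-normalized to 1 - t), the total variance and the means-model
    coefficients are re-optimized.  Bounds are where the profile
    log-likelihood drops chi2_1(level)/2 below the maximum, truncated at the
    [0, 1] boundary with a flag when the drop is never reached.
    """
    options = options or FitOptions()
    data = as_pair_data(data)
    comps = list(fit.component_names)
    if component not in comps:
        raise ValueError(f"component {component!r} not in model {comps}")
    others = [c for c in comps if c != component]
    shares_hat = standardize(fit).shares
    point = shares_hat[component]
    crit = stats.chi2.ppf(level, 1) / 2.0
    target = fit.loglik - crit

    v_hat = fit.params.total_variance
    beta_hat = fit.params.beta
    if len(others) == 2:
        s1 = shares_hat[others[0]]
        frac = s1 / max(s1 + shares_hat[others[1]], 1e-12)
        u0 = float(np.log(np.clip(frac, 1e-6, 1 - 1e-6) / (1 - np.clip(frac, 1e-6, 1 - 1e-6))))
        x0_base = np.concatenate([[u0, np.log(v_hat)], beta_hat])
    else:
        x0_base = np.concatenate([[np.log(v_hat)], beta_hat])

    inner_opts = replace(options, maxiter=500)

    def prof(t: float) -> float:
        t = float(np.clip(t, 0.0, 1.0 - 1e-9))

        def neg(x):
            if len(others) == 2:
                u, logv = x[0], x[1]
                beta = x[2:]
                rest = (1.0 - t) * np.array([_sigmoid(u), 1.0 - _sigmoid(u)])
                shares = {component: t, others[0]: rest[0], others[1]: rest[1]}
            else:
                logv = x[0]
                beta = x[1:]
                shares = {component: t, others[0]: 1.0 - t}
            v = np.exp(np.clip(logv, -30.0, 30.0))
            ll = 0.0
            for zyg, pd_ in data.items():
                off = _unit_correlation(shares, zyg)
                cov = v * np.array([[1.0, off], [off, 1.0]])
                ll += pd_.loglik(beta, cov)
            return -ll

        res = _minimize(neg, x0_base, inner_opts)
        return -res.fun

    def f(t):
        return prof(t) - target

    # lower bound
    if point <= xtol:
        lo, lo_bound = 0.0, True
    elif f(0.0) >= 0.0:
        lo, lo_bound = 0.0, True
    else:
        lo = float(optimize.brentq(f, 0.0, point, xtol=xtol))
        lo_bound = False
    # upper bound
    hi_edge = 1.0 - 1e-6
    if point >= 1.0 - xtol:
        hi, hi_bound = 1.0, True
    elif f(hi_edge) >= 0.0:
        hi, hi_bound = 1.0, True
    else:
        hi = float(optimize.brentq(f, point, hi_edge, xtol=xtol))
        hi_bound = False
    return ProfileCI(lo, hi, level, lo_bound, hi_bound)


# ---------------------------------------------------------------------------
# Wald machinery (numerical curvature)


def numerical_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, float)
    n = len(x)
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                f1 = fun(x + ei)
                f2 = fun(x - ei)
                H[i, i] = (f1 - 2 * f0 + f2) / steps[i] ** 2
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def numerical_gradient(fun, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(len(x)):
        e = np.zeros_like(x); e[i] = steps[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2 * steps[i])
    return g


def wald_theta_cov(negloglik, theta: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the raw parameter vector: inverse observed
    information (pseudo-inverse when the Hessian is singular, e.g. a path
    estimated at zero)."""
    H = numerical_hessian(negloglik, theta)
    return np.linalg.pinv(H)


def delta_ci(
    quantity_fn, theta: np.ndarray, theta_cov: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """Delta-method CI for a smooth scalar function of the parameters."""
    val = float(quantity_fn(theta))
    g = numerical_gradient(quantity_fn, theta)
    var = float(g @ theta_cov @ g)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return val, val - z * se, val + z * se


# ---------------------------------------------------------------------------
# multigroup homogeneity fits (equal standardized shares)


def fit_multigroup_equal_shares(
    datasets: dict[str, dict],
    family: str = "ACE",
    options: FitOptions | None = None,
) -> FitResult:
    """Constrained multigroup fit: standardized variance shares equated
    across groups, total variance and means free per group.

    Shares are parameterized by a stick-breaking transform (k - 1 free
    parameters for k components), so the identified parameter count is
    (k - 1) + n_groups scales + the per-group means coefficients.
    """
    options = options or FitOptions()
    groups = sorted(datasets)
    data = {g: as_pair_data(datasets[g]) for g in groups}
    comps = FAMILY_COMPONENTS[family]
    k = len(comps)
    ps = {g: next(iter(data[g].values())).p for g in groups}

    def shares_from(u):
        shares = {}
        rest = 1.0
        for i, c in enumerate(comps[:-1]):
            frac = _sigmoid(u[i])
            shares[c] = rest * frac
            rest *= 1.0 - frac
        shares[comps[-1]] = rest
        return shares

    def split(theta):
        u = theta[: k - 1]
        pos = k - 1
        logv = {}
        for g in groups:
            logv[g] = theta[pos]; pos += 1
        betas = {}
        for g in groups:
            betas[g] = theta[pos : pos + ps[g]]; pos += ps[g]
        return u, logv, betas

    def neg(theta):
        u, logv, betas = split(theta)
        shares = shares_from(u)
        ll = 0.0
        for g in groups:
            v = np.exp(np.clip(logv[g], -30.0, 30.0))
            for zyg, pd_ in data[g].items():
                off = _unit_correlation(shares, zyg)
                cov = v * np.array([[1.0, off], [off, 1.0]])
                ll += pd_.loglik(betas[g], cov)
        return -ll

    x0_parts = [np.zeros(k - 1)]
    for g in groups:
        beta0, v0 = _pooled_ols(data[g])
        x0_parts.append([np.log(max(v0, 1e-6))])
    for g in groups:
        beta0, _ = _pooled_ols(data[g])
        x0_parts.append(beta0)
    x0 = np.concatenate(x0_parts)

    rng = np.random.default_rng(options.seed)
    best = None
    for s in range(max(options.n_starts // 2, 1)):
        xs = x0 if s == 0 else x0 + rng.normal(0, 0.3, len(x0))
        res = _minimize(neg, xs, options)
        if best is None or res.fun < best.fun:
            best = res
    u, logv, betas = split(best.x)
    shares = shares_from(u)
    n_params = (k - 1) + len(groups) + sum(ps.values())
    return FitResult(
        family=family,
        params=PathParams(
            family,
            {c: float(np.sqrt(shares[c])) for c in comps},
            np.concatenate([betas[g] for g in groups]),
        ),
        loglik=-best.fun,
        n_params=n_params,
        converged=bool(best.success),
        gradient_norm=float(np.max(np.abs(best.jac))),
        n_pairs_used={g: sum(d.n_used for d in data[g].values()) for g in groups},
        theta=best.x,
        label=f"{family}-equal-shares",
        component_names=comps,
    )


def combine_free_fits(fits: dict[str, FitResult], label: str = "free") -> FitResult:
    """Sum independent per-group fits into one multigroup 'free' FitResult."""
    groups = sorted(fits)
    comps = fits[groups[0]].component_names
    return FitResult(
        family=fits[groups[0]].family,
        params=None,
        loglik=sum(f.loglik for f in fits.values()),
        n_params=sum(f.n_params for f in fits.values()),
        converged=all(f.converged for f in fits.values()),
        gradient_norm=max(f.gradient_norm for f in fits.values()),
        n_pairs_used={g: sum(f.n_pairs_used.values()) for g, f in fits.items()},
        label=label,
        component_names=comps,
    )
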