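"""Per-trait univariate workflow: twin correlations, model-family choice,
submodel selection and multigroup homogeneity tests.

The workflow follows classical twin-study practice: MZ and DZ twin
correlations on covariate-residualized values choose between the ACE and ADE
families (ACE when r_MZ < 2 r_DZ, ADE otherwise); the full family is fitted
by FIML and submodels dropping A and C (or D) are tested by likelihood
ratio; E is never dropped because it absorbs measurement error.  Among the
full model and the submodels whose constraints are not rejected at the 0.05
level, the most parsimonious model is selected, with AIC breaking ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import likelihood as lk
from .cohort import PairedCohort
from .preprocess import residualize_covariates

logger = logging.getLogger(__name__)

#: submodels examined for each full family (E is never dropped; dominance
#: without an additive effect is not biologically meaningful, so ADE reduces
#: to AE or E only)
SUBMODELS = {"ACE": ("AE", "CE", "E"), "ADE": ("AE", "E")}


@dataclass
class TwinCorrelations:
    r_mz: float
    r_dz: float
    n_mz: int
    n_dz: int


@dataclass
class UnivariateFit:
    trait: str
    correlations: TwinCorrelations | None
    family_full: str
    best: lk.FitResult
    components: lk.VarianceComponents
    trace: list[dict] = field(default_factory=list)


@dataclass
class HomogeneityResult:
    lrt_stat: float
    df: int
    p: float
    free_fits: dict[str, lk.FitResult]
    constrained_fit: lk.FitResult


def _double_entry_r(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation on double-entered pairs (both orderings), making
    the estimate symmetric in twin labelling."""
    a = np.concatenate([x1, x2])
    b = np.concatenate([x2, x1])
    return float(np.corrcoef(a, b)[0, 1])


def twin_correlations(
    cohort: PairedCohort,
    trait_col: str,
    covariates: tuple[str, ...] = ("age_c", "female"),
    min_pairs: int = 3,
) -> TwinCorrelations:
    """Double-entry Pearson twin correlations per zygosity group.

    Trait values are residualized on the covariates (OLS, then standardized)
    before correlating; only complete pairs enter.  Groups with fewer than
    ``min_pairs`` complete pairs yield a missing correlation with a warning.
    """
    data = cohort.trait_arrays(trait_col, covariates)
    out = {}
    ns = {}
    for zyg, (y, X) in data.items():
        ok = np.isfinite(y).all(axis=1)
        ns[zyg] = int(ok.sum())
        if ns[zyg] < min_pairs:
            logger.warning(
                "%s: only %d complete %s pairs; correlation unavailable",
                trait_col, ns[zyg], zyg,
            )
            out[zyg] = np.nan
            continue
        # residualize member values jointly on the shared design
        import pandas as pd

        yv = np.concatenate([y[ok, 0], y[ok, 1]])
        Xv = np.vstack([X[ok, 0, 1:], X[ok, 1, 1:]])  # drop intercept column
        Xv = Xv[:, Xv.std(axis=0) > 1e-12]  # constant covariates carry nothing
        if Xv.shape[1]:
            resid = residualize_covariates(yv, pd.DataFrame(Xv))
        else:
            resid = (yv - yv.mean()) / yv.std(ddof=1)
        n = ns[zyg]
        out[zyg] = _double_entry_r(resid[:n], resid[n:])
    return TwinCorrelations(out.get("MZ", np.nan), out.get("DZ", np.nan),
                            ns.get("MZ", 0), ns.get("DZ", 0))


def choose_model_family(r: TwinCorrelations) -> str:
    """ACE when r_MZ < 2 r_DZ (shared environment plausible), ADE when
    r_MZ > 2 r_DZ (dominance pattern); exact ties go to ACE."""
    if not (np.isfinite(r.r_mz) and np.isfinite(r.r_dz)):
        raise ValueError("both twin correlations are required")
    return "ADE" if r.r_mz > 2.0 * r.r_dz else "ACE"


def _standardized_data(cohort: PairedCohort, trait_col: str, covariates):
    """z-score the trait across all observed members (shares are
    scale-invariant; scaling only conditions the optimizer)."""
    from .cohort import drop_constant_covariates

    data = drop_constant_covariates(cohort.trait_arrays(trait_col, covariates))
    vals = np.concatenate([y[np.isfinite(y)] for y, _ in data.values()])
    mu, sd = vals.mean(), vals.std(ddof=1)
    return {z: ((y - mu) / sd, X) for z, (y, X) in data.items()}


def fit_univariate_trait(
    cohort: PairedCohort,
    trait_col: str,
    covariates: tuple[str, ...] = ("age_c", "female"),
    family: str | None = None,
    options: lk.FitOptions | None = None,
    alpha: float = 0.05,
    ci: str | None = "profile",
    select: bool = True,
) -> UnivariateFit:
    """Full univariate procedure for one trait.

    Fits the chosen family and its admissible submodels, selects the winner,
    and returns standardized components (with profile CIs unless
    ``ci=None``) plus the complete selection trace.
    """
    options = options or lk.FitOptions()
    data = _standardized_data(cohort, trait_col, covariates)
    corr = None
    if family is None:
        corr = twin_correlations(cohort, trait_col, covariates)
        family = choose_model_family(corr)

    full = lk.fit_ml(data, family, options, label=family)
    candidates = [full]
    trace = [{"model": family, "loglik": full.loglik, "aic": full.aic,
              "n_params": full.n_params, "lrt_vs_full": 0.0, "df": 0,
              "p": 1.0, "admissible": True}]
    for sub in SUBMODELS.get(family, ()) if select else ():
        fit = lk.fit_ml(data, sub, options, label=sub)
        cmp = lk.compare_models(full, fit)
        admissible = cmp["p"] >= alpha
        trace.append({"model": sub, "loglik": fit.loglik, "aic": fit.aic,
                      "n_params": fit.n_params, "lrt_vs_full": cmp["lrt_stat"],
                      "df": cmp["df"], "p": cmp["p"], "admissible": admissible})
        if admissible:
            candidates.append(fit)
    # most parsimonious admissible model; AIC breaks ties
    best = min(candidates, key=lambda f: (f.n_params, f.aic))
    for row in trace:
        row["selected"] = row["model"] == best.family
    components = lk.standardize(best)
    if ci == "profile":
        for comp in best.component_names:
            pci = lk.profile_ci(data, best, comp, options=options)
            components.ci[comp] = (pci.lo, pci.hi)
    elif ci == "wald":
        components.ci.update(_wald_share_cis(data, best))
    return UnivariateFit(trait_col, corr, family, best, components, trace)


def _wald_share_cis(data, fit: lk.FitResult, level: float = 0.95) -> dict:
    """Delta-method CIs for the standardized shares (used where speed
    matters more than boundary-accurate intervals)."""
    data = lk.as_pair_data(data)
    comps = list(fit.component_names)
    k = len(comps)

    def neg(theta):
        paths = dict(zip(comps, theta[:k]))
        beta = theta[k:]
        return -sum(
            pd_.loglik(beta, lk.expected_cov_univariate(paths, z))
            for z, pd_ in data.items()
        )

    cov = lk.wald_theta_cov(neg, fit.theta)
    out = {}
    for i, comp in enumerate(comps):
        def share(theta, i=i):
            v = theta[:k] ** 2
            return v[i] / v.sum()

        val, lo, hi = lk.delta_ci(share, fit.theta, cov, level)
        out[comp] = (max(lo, 0.0), min(hi, 1.0))
    return out


def homogeneity_test(
    cohorts_by_group: dict[str, PairedCohort],
    trait_col: str,
    family: str,
    covariates: tuple[str, ...] = ("age_c", "female"),
    options: lk.FitOptions | None = None,
) -> HomogeneityResult:
    """LRT of equal standardized variance shares across groups.

    Free model: every group gets its own components, scale and means.
    Constrained model: shares equated, scale and means still free (means are
    always allowed to vary across groups).  df = (n_groups - 1) x (number of
    free standardized components, i.e. components minus one).
    """
    options = options or lk.FitOptions()
    if len(cohorts_by_group) < 2:
        raise ValueError("homogeneity test needs at least two groups")
    datasets = {}
    free_fits = {}
    for group, cohort in sorted(cohorts_by_group.items()):
        data = _standardized_data(cohort, trait_col, covariates)
        datasets[group] = data
        try:
            free_fits[group] = lk.fit_ml(data, family, options, label=f"{group}:{family}")
        except lk.IdentifiabilityError as err:
            raise lk.IdentifiabilityError(f"group {group!r}: {err}") from err
    free = lk.combine_free_fits(free_fits)
    constrained = lk.fit_multigroup_equal_shares(datasets, family, options)
    cmp = lk.compare_models(free, constrained)
    return HomogeneityResult(cmp["lrt_stat"], cmp["df"], cmp["p"], free_fits, constrained)
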