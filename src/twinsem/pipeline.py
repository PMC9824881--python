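"""End-to-end orchestration: preprocessing, univariate and bivariate fits,
homogeneity tests, and table-shaped outputs.

One run writes, to the output directory:

* ``table2.csv`` — best-fitting univariate components per trait (full
  population) with profile-likelihood CIs and the sex-homogeneity p-value;
* ``table3.csv`` — bivariate correlations (r_ph, r_a, r_e) and the genetic/
  environmental shares of the phenotypic correlation (p_a, p_e) with
  delta-method CIs, full population;
* ``fig3.csv`` — MZ/DZ twin correlations per trait and age group;
* ``fig4.csv`` — heritability per trait and age group plus the age-group
  homogeneity p-value;
* ``fig5.csv`` — genetic/environmental correlations with the anchor trait
  per age group plus the equal-correlation homogeneity p-value;
* ``selection_trace.json`` — every model-comparison decision taken;
* ``run.log`` — seed, configuration echo and stage log.

The significance threshold is 0.05 throughout and no multiple-testing
correction is applied; every table is schema-checked before writing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import likelihood as lk
from . import bivariate as bv
from . import univariate as uv
from .cohort import PairedCohort, pair_twins, read_cohort
from .preprocess import PreprocessConfig, preprocess_cohort
from .traits import TRAITS, TRAIT_ORDER, covariates_for

logger = logging.getLogger(__name__)

TABLE_SCHEMAS = {
    "table2": ["trait", "model", "h2", "h2_lo", "h2_hi", "c2", "c2_lo", "c2_hi",
               "d2", "d2_lo", "d2_hi", "e2", "e2_lo", "e2_hi",
               "p_homogeneity_sex"],
    "table3": ["trait", "model", "r_ph", "r_ph_lo", "r_ph_hi", "r_a", "r_a_lo",
               "r_a_hi", "r_e", "r_e_lo", "r_e_hi", "p_a", "p_a_lo", "p_a_hi",
               "p_e", "p_e_lo", "p_e_hi"],
    "fig3": ["trait", "group", "zygosity", "r", "n_pairs"],
    "fig4": ["trait", "group", "model", "h2", "h2_lo", "h2_hi",
             "p_homogeneity_age"],
    "fig5": ["trait", "group", "r_a", "r_e", "p_homogeneity_r"],
}


@dataclass
class PipelineConfig:
    traits: tuple[str, ...] = tuple(TRAIT_ORDER)
    anchor: str = "BMI"
    alpha: float = 0.05
    include_med_covariates: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fit: lk.FitOptions = field(default_factory=lk.FitOptions)
    group_by: str = "age"  # age | sex | none
    sex_homogeneity: bool = True
    bivariate_groups: bool = True
    seed: int = 2024


class PipelineError(RuntimeError):
    pass


def _check_schema(name: str, df: pd.DataFrame) -> pd.DataFrame:
    want = TABLE_SCHEMAS[name]
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise PipelineError(f"{name}: missing output columns {missing}")
    return df[want]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", na_rep="NA")


def _ci(components: lk.VarianceComponents, comp: str) -> tuple[float, float, float]:
    share = components.shares.get(comp, 0.0)
    lo, hi = components.ci.get(comp, (np.nan, np.nan))
    if comp not in components.shares:
        share, lo, hi = 0.0, 0.0, 0.0  # dropped: structural zero
    return share, lo, hi


def run_pipeline(
    cohort, outdir, config: PipelineConfig | None = None
) -> dict[str, Path]:
    """Execute the full analysis on a cohort (path or records DataFrame).

    Returns a mapping of output names to written paths.  Any stage failure
    raises :class:`PipelineError` after logging; partial outputs written so
    far are retained.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("twinsem")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    written: dict[str, Path] = {}
    trace: dict = {"config": {"alpha": config.alpha, "seed": config.seed,
                              "traits": list(config.traits),
                              "anchor": config.anchor}}
    try:
        from . import __version__

        logger.info("twinsem %s pipeline start; seed=%d", __version__, config.seed)
        records = cohort if isinstance(cohort, pd.DataFrame) else read_cohort(cohort)
        stage = "preprocess"
        records, report = preprocess_cohort(records, config.preprocess)
        trace["preprocess"] = report
        paired = pair_twins(records)
        logger.info(
            "%d pairs (%d MZ / %d DZ), %d singleton(s) excluded",
            paired.n_pairs, paired.n_mz, paired.n_dz, paired.n_excluded_singletons,
        )
        trace["cohort"] = {
            "n_pairs": paired.n_pairs, "n_individuals": 2 * paired.n_pairs,
            "n_mz": paired.n_mz, "n_dz": paired.n_dz,
            "n_excluded_singletons": paired.n_excluded_singletons,
        }
        groups = paired.split_by("age_group")
        sexes = paired.split_by("sex")

        from dataclasses import replace as _replace

        opts = config.fit
        # secondary (group-level / homogeneity) fits start from good moment
        # estimates; two starts suffice there
        sub_opts = _replace(opts, n_starts=2)
        trait_cols = {t: TRAITS[t].column for t in config.traits}

        # ---- univariate stage ----------------------------------------
        stage = "univariate"
        t2_rows, f3_rows, f4_rows = [], [], []
        trace["univariate"] = {}
        full_fits: dict[str, uv.UnivariateFit] = {}
        for name, col in trait_cols.items():
            covs = covariates_for(name, config.include_med_covariates)
            res = uv.fit_univariate_trait(
                paired, col, covs, options=opts, alpha=config.alpha, ci="profile"
            )
            full_fits[name] = res
            trace["univariate"][name] = {
                "family_full": res.family_full,
                "selected": res.best.family,
                "trace": res.trace,
            }
            p_sex = np.nan
            if config.sex_homogeneity and len(sexes) == 2:
                try:
                    hom = uv.homogeneity_test(sexes, col, res.best.family, covs, sub_opts)
                    p_sex = hom.p
                except lk.IdentifiabilityError as err:
                    logger.warning("%s sex homogeneity skipped: %s", name, err)
            comps = res.components
            h2, h2lo, h2hi = _ci(comps, "A")
            c2, c2lo, c2hi = _ci(comps, "C")
            d2, d2lo, d2hi = _ci(comps, "D")
            e2, e2lo, e2hi = _ci(comps, "E")
            t2_rows.append(dict(trait=name, model=res.best.family,
                                h2=h2, h2_lo=h2lo, h2_hi=h2hi,
                                c2=c2, c2_lo=c2lo, c2_hi=c2hi,
                                d2=d2, d2_lo=d2lo, d2_hi=d2hi,
                                e2=e2, e2_lo=e2lo, e2_hi=e2hi,
                                p_homogeneity_sex=p_sex))
            # twin correlations per age group
            for gname, gcohort in groups.items():
                tc = uv.twin_correlations(gcohort, col, covs)
                f3_rows.append(dict(trait=name, group=gname, zygosity="MZ",
                                    r=tc.r_mz, n_pairs=tc.n_mz))
                f3_rows.append(dict(trait=name, group=gname, zygosity="DZ",
                                    r=tc.r_dz, n_pairs=tc.n_dz))
            # per-group fits of the selected family + age homogeneity
            p_age = np.nan
            if config.group_by == "age" and len(groups) >= 2:
                try:
                    hom = uv.homogeneity_test(groups, col, res.best.family, covs, sub_opts)
                    p_age = hom.p
                except lk.IdentifiabilityError as err:
                    logger.warning("%s age homogeneity skipped: %s", name, err)
            for gname, gcohort in groups.items():
                # per-group components under the family selected on the
                # full population (no per-group re-selection)
                gres = uv.fit_univariate_trait(
                    gcohort, col, covs, family=res.best.family,
                    options=sub_opts, alpha=config.alpha, ci="wald",
                    select=False,
                )
                g_h2, g_lo, g_hi = _ci(gres.components, "A")
                f4_rows.append(dict(trait=name, group=gname,
                                    model=gres.best.family, h2=g_h2,
                                    h2_lo=g_lo, h2_hi=g_hi,
                                    p_homogeneity_age=p_age))
        _write(_check_schema("table2", pd.DataFrame(t2_rows)), outdir / "table2.csv")
        written["table2"] = outdir / "table2.csv"
        _write(_check_schema("fig3", pd.DataFrame(f3_rows)), outdir / "fig3.csv")
        written["fig3"] = outdir / "fig3.csv"
        _write(_check_schema("fig4", pd.DataFrame(f4_rows)), outdir / "fig4.csv")
        written["fig4"] = outdir / "fig4.csv"

        # ---- bivariate stage -----------------------------------------
        stage = "bivariate"
        anchor_col = trait_cols[config.anchor]
        anchor_covs = covariates_for(config.anchor, config.include_med_covariates)
        t3_rows, f5_rows = [], []
        trace["bivariate"] = {}
        partners = [t for t in config.traits if t != config.anchor]
        for name in partners:
            col = trait_cols[name]
            covs = covariates_for(name, config.include_med_covariates)
            # AE bivariate unless either trait retained C (or D) univariately
            retained = {c for f in (full_fits[config.anchor], full_fits[name])
                        for c in f.best.component_names}
            family = "ACE" if ("C" in retained or "D" in retained) else "AE"
            bres = bv.fit_bivariate(paired, anchor_col, col, anchor_covs, covs,
                                    family=family, options=opts, ci=True)
            tests = bv.cross_path_tests(paired, anchor_col, col, anchor_covs,
                                        covs, family=family, options=opts,
                                        full=bres)
            trace["bivariate"][name] = {
                "family": family,
                "cross_path_tests": tests,
                "converged": bres.fit.converged,
            }
            r = bres.result
            ci = r.ci
            t3_rows.append(dict(
                trait=name, model=family,
                r_ph=r.r_ph, r_ph_lo=ci.get("r_ph", (np.nan,) * 2)[0],
                r_ph_hi=ci.get("r_ph", (np.nan,) * 2)[1],
                r_a=r.r_a, r_a_lo=ci.get("r_a", (np.nan,) * 2)[0],
                r_a_hi=ci.get("r_a", (np.nan,) * 2)[1],
                r_e=r.r_e, r_e_lo=ci.get("r_e", (np.nan,) * 2)[0],
                r_e_hi=ci.get("r_e", (np.nan,) * 2)[1],
                p_a=r.p_a, p_a_lo=ci.get("p_a", (np.nan,) * 2)[0],
                p_a_hi=ci.get("p_a", (np.nan,) * 2)[1],
                p_e=r.p_e, p_e_lo=ci.get("p_e", (np.nan,) * 2)[0],
                p_e_hi=ci.get("p_e", (np.nan,) * 2)[1],
            ))
            if config.bivariate_groups and len(groups) >= 2:
                try:
                    hom = bv.bivariate_r_homogeneity(
                        groups, anchor_col, col, anchor_covs, covs,
                        family=family, options=sub_opts,
                    )
                    for gname, gfit in hom.free.items():
                        f5_rows.append(dict(trait=name, group=gname,
                                            r_a=gfit.result.r_a,
                                            r_e=gfit.result.r_e,
                                            p_homogeneity_r=hom.p))
                except lk.IdentifiabilityError as err:
                    logger.warning("%s r-homogeneity skipped: %s", name, err)
        _write(_check_schema("table3", pd.DataFrame(t3_rows)), outdir / "table3.csv")
        written["table3"] = outdir / "table3.csv"
        if f5_rows:
            _write(_check_schema("fig5", pd.DataFrame(f5_rows)), outdir / "fig5.csv")
            written["fig5"] = outdir / "fig5.csv"

        with open(outdir / "selection_trace.json", "w") as fh:
            json.dump(trace, fh, indent=1, default=_jsonable)
        written["selection_trace"] = outdir / "selection_trace.json"
        logger.info("pipeline complete in %.1f s", time.time() - t0)
    except Exception as err:
        logger.error("pipeline failed at stage %r: %s", stage, err)
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()
    return written


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return str(obj)
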