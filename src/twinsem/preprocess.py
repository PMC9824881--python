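"""Measurement-cleaning rules applied before model fitting.

The rules mirror standard twin-registry practice for cardiometabolic
phenotypes:

* repeated sitting blood-pressure readings are averaged, with a third
  reading resolving discrepant first two readings (difference > 10 mmHg);
* antihypertensive medication is compensated by adding 15 mmHg to SBP and
  10 mmHg to DBP of medicated individuals;
* values more than 3 SD from the mean are removed (one pass, computed on the
  full analysis population);
* right-skewed traits are log-transformed (sample skewness rule plus a
  force-list, TG by default);
* ages are banded into three groups: <=50, 51-60, >60 years.

Covariate residualization here serves only the descriptive twin-correlation
stage; the maximum-likelihood fits adjust for covariates through the means
model instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class MissingDataError(ValueError):
    """A required measurement is absent (e.g. third BP reading)."""


@dataclass
class PreprocessConfig:
    outlier_sd: float = 3.0
    skew_threshold: float = 1.0
    log_force_list: tuple[str, ...] = ("TG",)
    bp_adjust: dict = field(default_factory=lambda: {"sbp": 15.0, "dbp": 10.0})
    bp_discrepancy_mmhg: float = 10.0


def average_bp_readings(m1, m2, m3=None, discrepancy: float = 10.0):
    """Combine sequential blood-pressure readings (mmHg).

    The first two readings are averaged; when they differ by more than
    ``discrepancy`` mmHg a third reading is required and the two closest of
    the three are averaged.

    Accepts scalars or equal-length arrays (NaN marks an absent third
    reading).
    """
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    scalar = m1.ndim == 0
    m1, m2 = np.atleast_1d(m1), np.atleast_1d(m2)
    m3 = np.full_like(m1, np.nan) if m3 is None else np.atleast_1d(np.asarray(m3, float))
    need_third = np.abs(m1 - m2) > discrepancy
    if np.any(need_third & ~np.isfinite(m3)):
        raise MissingDataError(
            "third reading required when the first two differ by more than "
            f"{discrepancy:g} mmHg"
        )
    out = (m1 + m2) / 2.0
    if need_third.any():
        trio = np.stack([m1, m2, m3])  # (3, n)
        # pairwise distances between the three readings
        pairs = [(0, 1), (0, 2), (1, 2)]
        dists = np.stack([np.abs(trio[i] - trio[j]) for i, j in pairs])
        best = np.argmin(dists, axis=0)
        means = np.stack([(trio[i] + trio[j]) / 2.0 for i, j in pairs])
        out = np.where(need_third, means[best, np.arange(m1.size)], out)
    return float(out[0]) if scalar else out


def adjust_blood_pressure(df: pd.DataFrame, config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Shift SBP/DBP of antihypertensive-medication users upward.

    Adds the configured increments (+15 mmHg SBP, +10 mmHg DBP) to rows with
    ``med_bp`` set.  Missing values stay missing; each field is adjusted
    independently.  A ``bp_adjusted`` flag column guards idempotence.
    """
    config = config or PreprocessConfig()
    df = df.copy()
    if "bp_adjusted" not in df.columns:
        df["bp_adjusted"] = False
    todo = (df["med_bp"].astype(bool)) & (~df["bp_adjusted"].astype(bool))
    for col, delta in config.bp_adjust.items():
        if col in df.columns:
            df.loc[todo, col] = df.loc[todo, col] + delta
    df.loc[:, "bp_adjusted"] = df["bp_adjusted"].astype(bool) | df["med_bp"].astype(bool)
    return df


def outlier_mask(values, n_sd: float = 3.0) -> np.ndarray:
    """Flag values more than ``n_sd`` standard deviations from the mean.

    Single pass: mean and SD are computed once from the non-missing values,
    and the returned boolean array marks outliers.  Missing values are never
    flagged (they stay missing).  A zero SD flags nothing.
    """
    x = np.asarray(values, float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(x, bool)
    mask = np.zeros_like(x, bool)
    mask[finite] = np.abs(x[finite] - mu) > n_sd * sd
    return mask


def select_and_apply_log(
    values,
    force: bool = False,
    skew_threshold: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Log-transform a trait vector when its distribution is non-normal.

    The working proxy for non-normality is |sample skewness| above
    ``skew_threshold``; ``force`` applies the transform regardless (used for
    the configured force-list).  Returns the (possibly transformed) vector
    and a flag recording the decision.
    """
    x = np.asarray(values, float)
    finite = np.isfinite(x)
    transform = force or abs(stats.skew(x[finite])) > skew_threshold
    if not transform:
        return x.copy(), False
    if (x[finite] <= 0).any():
        raise ValueError("log transform requires strictly positive values")
    out = np.where(finite, np.log(np.where(finite, x, 1.0)), np.nan)
    return out, True


def assign_age_group(age: float) -> str:
    """Band an age (years) into G1 (<=50), G2 (51-60) or G3 (>60).

    G2 is the closed band [51, 60]; non-integer ages in (50, 51) fall in G1
    and in (60, 61) fall in G3, so every positive age maps to exactly one
    group.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    if age < 51.0:
        return "G1"
    if age <= 60.0:
        return "G2"
    return "G3"


AGE_GROUPS = ("G1", "G2", "G3")
AGE_GROUP_LABELS = {"G1": "<=50 y", "G2": "51-60 y", "G3": ">60 y"}


def residualize_covariates(trait, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of a trait on covariates, standardized to mean 0, SD 1.

    Rows with a missing trait value propagate NaN.  A rank-deficient design
    raises an error naming the collinear columns.
    """
    y = np.asarray(trait, float)
    X = np.column_stack([np.ones(len(y)), covariates.to_numpy(float)])
    names = ["intercept"] + list(covariates.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the correlation scale
        _, r = np.linalg.qr(X)
        small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
        bad = [names[i] for i in np.where(small)[0]] or names
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - X[ok] @ beta
    sd = np.nanstd(resid, ddof=1)
    scale = max(np.nanstd(y), 1.0)
    if sd <= 1e-10 * scale:  # (numerically) perfect fit: nothing to scale
        return resid - np.nanmean(resid)
    return (resid - np.nanmean(resid)) / sd


def preprocess_cohort(
    records: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the full cleaning chain to an individual-level table.

    Order: BP medication adjustment, then per-trait single-pass outlier
    removal on the full population (raw scale), then log transformation for
    skewed traits.  Returns the cleaned table and a report dict with
    per-trait outlier counts and transform flags.
    """
    from .traits import TRAITS

    config = config or PreprocessConfig()
    df = adjust_blood_pressure(records, config)
    report: dict = {"outliers": {}, "log_transformed": {}}
    for name, trait in TRAITS.items():
        col = trait.column
        if col not in df.columns:
            continue
        mask = outlier_mask(df[col], config.outlier_sd)
        df.loc[mask, col] = np.nan
        report["outliers"][name] = int(mask.sum())
        vals, flag = select_and_apply_log(
            df[col], force=name in config.log_force_list,
            skew_threshold=config.skew_threshold,
        )
        df[col] = vals
        report["log_transformed"][name] = flag
    return df, report
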