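"""Reading, validating and pairing tidy twin-cohort tables.

The on-disk format is a long/tidy CSV with one row per individual and the
columns ``family_id, member_index, zygosity, sex, age`` followed by the trait
columns (``bmi, hba1c, fbg, sbp, dbp, tc, tg, ldl, hdl``) and medication
indicator columns (``med_bp, med_glu, med_lipid``).  Missing values are empty
cells or ``NA``.  Column names can be remapped via a schema dictionary.

Pairing turns the long table into a :class:`PairedCohort` with one row per
twin pair; only complete same-family pairs are analysable, singletons are
excluded and counted (mirroring the registry eligibility rule that both twin
members must be available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import MED_COLUMNS, TRAIT_COLUMNS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is absent or a column has an invalid value domain."""


class IntegrityError(ValueError):
    """The table violates twin-structure invariants (duplicates, zygosity
    mismatch within a family, families with more than two members)."""


ID_COLUMNS = ("family_id", "member_index", "zygosity", "sex", "age")
NUMERIC_COLUMNS = ("age",) + tuple(TRAIT_COLUMNS.values())

#: canonical name -> CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    c: c for c in ID_COLUMNS + tuple(TRAIT_COLUMNS.values()) + MED_COLUMNS
}

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", "", "na", "nan"}


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        raise SchemaError(
            f"column {column!r}: unparseable boolean values {sorted(s[bad].unique())}"
        )
    return s.isin(_TRUE).astype(int)


def read_cohort(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a tidy cohort CSV.

    Returns a DataFrame with canonical column names.  Unparseable numeric
    cells become missing values with a logged warning.  Row and missing-value
    counts are stored in ``df.attrs``.

    Raises
    ------
    SchemaError
        if a required column is missing.
    IntegrityError
        on duplicate (family_id, member_index) rows or within-family
        zygosity/sex disagreement.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [src for src in (colmap[c] for c in ID_COLUMNS) if src not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    n_warn = 0
    for canon, src in colmap.items():
        if src not in raw.columns:
            if canon in ID_COLUMNS:
                raise SchemaError(f"missing required column {src!r}")
            continue  # optional trait/med column absent
        col = raw[src].str.strip()
        if canon == "family_id":
            df[canon] = col
        elif canon == "member_index":
            df[canon] = pd.to_numeric(col, errors="coerce")
        elif canon == "zygosity":
            df[canon] = col.str.upper()
        elif canon == "sex":
            df[canon] = col.str.lower().replace({"m": "male", "f": "female"})
        elif canon in MED_COLUMNS:
            df[canon] = _parse_bool(col, src)
        else:  # numeric trait / age
            empty = (col == "") | (col.str.upper() == "NA")
            vals = pd.to_numeric(col.where(~empty, None), errors="coerce")
            n_bad = int((vals.isna() & ~empty).sum())
            if n_bad:
                n_warn += n_bad
                logger.warning(
                    "column %r: %d unparseable numeric cell(s) set to missing", src, n_bad
                )
            df[canon] = vals

    for med in MED_COLUMNS:
        if med not in df.columns:
            df[med] = 0

    return validate_records(df, n_parse_warnings=n_warn)


def validate_records(df: pd.DataFrame, n_parse_warnings: int = 0) -> pd.DataFrame:
    """Check record-level invariants on a canonical-column DataFrame."""
    if df["member_index"].isna().any() or not df["member_index"].isin([1, 2]).all():
        raise SchemaError("member_index must be 1 or 2 for every row")
    df = df.copy()
    df["member_index"] = df["member_index"].astype(int)
    bad_zyg = ~df["zygosity"].isin(["MZ", "DZ"])
    if bad_zyg.any():
        raise SchemaError(
            f"zygosity must be MZ or DZ; got {sorted(df.loc[bad_zyg, 'zygosity'].unique())}"
        )
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise SchemaError(
            f"sex must be male or female; got {sorted(df.loc[bad_sex, 'sex'].unique())}"
        )
    if (df["age"].isna() | (df["age"] <= 0)).any():
        raise SchemaError("age must be present and positive for every row")

    dup = df.duplicated(subset=["family_id", "member_index"])
    if dup.any():
        raise IntegrityError(
            f"duplicate (family_id, member_index): {df.loc[dup, 'family_id'].tolist()}"
        )
    zyg_n = df.groupby("family_id")["zygosity"].nunique()
    if (zyg_n > 1).any():
        raise IntegrityError(
            f"zygosity differs within family: {zyg_n[zyg_n > 1].index.tolist()}"
        )

    trait_cols = [c for c in TRAIT_COLUMNS.values() if c in df.columns]
    df.attrs["n_rows"] = len(df)
    df.attrs["n_missing"] = int(df[trait_cols].isna().sum().sum()) if trait_cols else 0
    df.attrs["n_parse_warnings"] = n_parse_warnings
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a canonical cohort table; numeric text round-trips bit-exactly."""
    df.to_csv(path, index=False, na_rep="NA")


@dataclass
class PairedCohort:
    """Twin pairs in wide (one row per pair) form.

    ``wide`` has per-pair columns ``family_id, zygosity, sex, female, age,
    age_group`` (pair-level) and per-member columns ``<col>_1, <col>_2`` for
    age, every trait and every medication flag.  Member order follows
    ``member_index``; no likelihood in the package depends on that order.
    """

    wide: pd.DataFrame
    n_excluded_singletons: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.wide)

    @property
    def n_mz(self) -> int:
        return int((self.wide["zygosity"] == "MZ").sum())

    @property
    def n_dz(self) -> int:
        return int((self.wide["zygosity"] == "DZ").sum())

    def subset(self, mask) -> "PairedCohort":
        return PairedCohort(self.wide.loc[mask].reset_index(drop=True),
                            self.n_excluded_singletons, dict(self.meta))

    def split_by(self, column: str) -> dict[str, "PairedCohort"]:
        """Partition pairs by a pair-level column (e.g. age_group or sex)."""
        return {
            str(value): self.subset(self.wide[column] == value)
            for value in sorted(self.wide[column].dropna().unique())
        }

    # -- design-matrix construction ------------------------------------

    def _member_covariates(self, covariates: tuple[str, ...], member: int) -> np.ndarray:
        cols = [np.ones(self.n_pairs)]
        for cov in covariates:
            if cov == "age_c":
                cols.append((self.wide[f"age_{member}"].to_numpy(float) - 50.0) / 10.0)
            elif cov == "female":
                cols.append(self.wide["female"].to_numpy(float))
            elif f"{cov}_{member}" in self.wide.columns:
                cols.append(self.wide[f"{cov}_{member}"].to_numpy(float))
            else:
                raise KeyError(f"unknown covariate {cov!r}")
        return np.column_stack(cols)

    def trait_arrays(
        self, trait_col: str, covariates: tuple[str, ...] = ("age_c", "female")
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-zygosity ``(y, X)`` arrays for one trait.

        ``y`` is (n, 2) with NaN for missing member values; ``X`` is
        (n, 2, p) with an identical coefficient vector applying to both
        members.  A member whose covariates are incomplete is treated as
        missing.
        """
        out = {}
        for zyg in ("MZ", "DZ"):
            sub = self.subset(self.wide["zygosity"] == zyg)
            y = np.column_stack(
                [sub.wide[f"{trait_col}_{m}"].to_numpy(float) for m in (1, 2)]
            )
            X = np.stack(
                [sub._member_covariates(covariates, m) for m in (1, 2)], axis=1
            )
            bad = ~np.isfinite(X).all(axis=2)
            y[bad] = np.nan
            X[~np.isfinite(X)] = 0.0
            out[zyg] = (y, X)
        return out

    def bivariate_arrays(
        self,
        col_x: str,
        col_y: str,
        covariates_x: tuple[str, ...] = ("age_c", "female"),
        covariates_y: tuple[str, ...] = ("age_c", "female"),
    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-zygosity ``(y, X)`` for a trait pair.

        ``y`` is (n, 4) ordered (x_member1, y_member1, x_member2, y_member2);
        ``X`` is (n, 4, p_x + p_y) block-structured so the two traits carry
        separate means-model coefficients.
        """
        out = {}
        px, py = 1 + len(covariates_x), 1 + len(covariates_y)
        for zyg in ("MZ", "DZ"):
            sub = self.subset(self.wide["zygosity"] == zyg)
            n = sub.n_pairs
            y = np.column_stack(
                [
                    sub.wide[f"{col_x}_1"].to_numpy(float),
                    sub.wide[f"{col_y}_1"].to_numpy(float),
                    sub.wide[f"{col_x}_2"].to_numpy(float),
                    sub.wide[f"{col_y}_2"].to_numpy(float),
                ]
            )
            X = np.zeros((n, 4, px + py))
            for m, (rx, ry) in enumerate([(0, 1), (2, 3)], start=1):
                X[:, rx, :px] = sub._member_covariates(covariates_x, m)
                X[:, ry, px:] = sub._member_covariates(covariates_y, m)
            bad = ~np.isfinite(X).all(axis=2)
            y[bad] = np.nan
            X[~np.isfinite(X)] = 0.0
            out[zyg] = (y, X)
        return out


def drop_constant_covariates(data: dict) -> dict:
    """Remove design columns with no variation in the (sub)cohort.

    A medication indicator can be identically zero within an age group,
    which would make the means model rank-deficient; such columns carry no
    information and are dropped.  All-ones (intercept) columns are kept.
    """
    allX = np.concatenate([X.reshape(-1, X.shape[2]) for _, X in data.values()])
    sd = allX.std(axis=0)
    keep = (sd > 1e-12) | (np.abs(allX.mean(axis=0) - 1.0) < 1e-12)
    if keep.all():
        return data
    return {z: (y, X[:, :, keep]) for z, (y, X) in data.items()}


def pair_twins(records: pd.DataFrame, age_group_fn=None) -> PairedCohort:
    """Assemble complete twin pairs from validated individual records.

    Families with exactly two members become pairs; singletons are excluded
    and counted.  Families with more than two rows raise
    :class:`IntegrityError`.  The pair-level age is the mean of member ages
    (twins share a birth date; a warning is logged when recorded ages
    differ), and ``age_group_fn`` (default: the standard ≤50 / 51–60 / >60
    banding from :mod:`twinsem.preprocess`) assigns the pair age group.
    """
    from .preprocess import assign_age_group

    if age_group_fn is None:
        age_group_fn = assign_age_group

    sizes = records.groupby("family_id").size()
    too_big = sizes[sizes > 2]
    if len(too_big):
        raise IntegrityError(
            f"families with more than two members: {too_big.index.tolist()}"
        )
    singles = set(sizes[sizes == 1].index)
    if singles:
        logger.info("excluding %d singleton families (no co-twin)", len(singles))
    complete = records[~records["family_id"].isin(singles)]

    member_cols = ["age"] + [
        c for c in list(TRAIT_COLUMNS.values()) + list(MED_COLUMNS)
        if c in complete.columns
    ]
    parts = {}
    for m in (1, 2):
        part = (
            complete[complete["member_index"] == m]
            .set_index("family_id")[member_cols]
            .add_suffix(f"_{m}")
        )
        parts[m] = part
    pair_level = (
        complete[complete["member_index"] == 1]
        .set_index("family_id")[["zygosity", "sex"]]
    )
    wide = pair_level.join([parts[1], parts[2]], how="inner").reset_index()
    if len(wide) != len(sizes[sizes == 2]):
        raise IntegrityError(
            "some two-member families lack member_index 1 and 2 exactly once"
        )
    wide["female"] = (wide["sex"] == "female").astype(float)
    age_diff = (wide["age_1"] - wide["age_2"]).abs()
    if (age_diff > 1e-9).any():
        logger.warning(
            "%d pair(s) with differing member ages; using the pair mean",
            int((age_diff > 1e-9).sum()),
        )
    wide["age"] = (wide["age_1"] + wide["age_2"]) / 2.0
    wide["age_group"] = [age_group_fn(a) for a in wide["age"]]
    return PairedCohort(wide, n_excluded_singletons=len(singles))
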