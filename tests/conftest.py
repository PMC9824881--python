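"""Shared fixtures: small constructed cohorts and simulated datasets."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

import twinsem as ts
from twinsem import simulate as sim


def make_cohort(
    n_mz: int,
    n_dz: int,
    h2: float,
    c2: float = 0.0,
    seed: int = 0,
    second_trait: dict | None = None,
    trait_kwargs: dict | None = None,
) -> ts.PairedCohort:
    """Single-group synthetic cohort paired and ready for fitting."""
    traits = {"BMI": sim.TraitSpec("BMI", h2=h2, c2=c2, **(trait_kwargs or {}))}
    if second_trait is not None:
        spec = {"name": "DBP", **second_trait}
        traits[spec["name"]] = sim.TraitSpec(**spec)
    cfg = sim.SimulationConfig(
        n_pairs={("G1", "MZ"): n_mz, ("G1", "DZ"): n_dz},
        traits=traits,
        seed=seed,
    )
    records, _ = sim.simulate_cohort(cfg)
    return ts.pair_twins(records)


@pytest.fixture(scope="session")
def ae_cohort() -> ts.PairedCohort:
    """2,000 pairs generated under AE with h2 = 0.72."""
    return make_cohort(1000, 1000, h2=0.72, seed=42)


@pytest.fixture(scope="session")
def biv_cohort() -> ts.PairedCohort:
    """2,000 pairs of (BMI, DBP) with r_a = 0.39, r_e = 0.20, h2 = 0.6."""
    return make_cohort(
        1000, 1000, h2=0.6, seed=7,
        second_trait=dict(name="DBP", h2=0.6, r_a=0.39, r_e=0.20),
    )


def tidy_csv(rows: list[dict]) -> io.StringIO:
    """In-memory cohort CSV from row dicts (missing keys become NA)."""
    cols = ["family_id", "member_index", "zygosity", "sex", "age",
            "bmi", "sbp", "dbp", "med_bp", "med_glu", "med_lipid"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = "" if c not in ("med_bp", "med_glu", "med_lipid") else 0
    buf = io.StringIO()
    df[cols].to_csv(buf, index=False)
    buf.seek(0)
    return buf


def basic_rows(n_fam: int = 3, zygosity=("MZ", "MZ", "DZ")) -> list[dict]:
    rows = []
    rng = np.random.default_rng(1)
    for i in range(n_fam):
        for m in (1, 2):
            rows.append(dict(
                family_id=f"F{i}", member_index=m, zygosity=zygosity[i % len(zygosity)],
                sex="female" if i % 2 else "male", age=40 + i,
                bmi=round(24 + rng.normal(), 2), sbp=round(120 + 5 * rng.normal(), 1),
                dbp=round(80 + 3 * rng.normal(), 1),
                med_bp=0, med_glu=0, med_lipid=0,
            ))
    return rows
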