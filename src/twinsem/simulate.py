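"""Synthetic twin-cohort generator with known ground truth.

Cohorts are generated from explicit latent additive-genetic (A), shared
environment (C) and unique environment (E) factor draws with the textbook
twin correlation structure (A: 1 in MZ / 0.5 in DZ; C: 1; E: 0), so oracle
checks that correlate latent scores directly are possible.  Cross-trait
structure versus an anchor trait (BMI) is induced by mixing each trait's
latent factors with the anchor's at the configured component correlations,
which reproduces the phenotypic-correlation decomposition

    r_ph = r_a sqrt(h2_1 h2_2) + r_c sqrt(c2_1 c2_2) + r_e sqrt(e2_1 e2_2).

Standardized latent phenotypes are rescaled to plausible trait units, age
and sex effects are added through the means model, medication indicators
are drawn per age-group prevalence, and — mirroring field measurement —
the *emitted* SBP/DBP of medicated individuals are the unadjusted (lower)
values so the preprocessing medication adjustment is exercised downstream.

One master seed drives a hierarchical stream: each (age group, zygosity)
cell has its own independent substream, so changing one cell's pair count
does not perturb the draws of any other cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .traits import TRAITS, TRAIT_ORDER

AGE_RANGES = {"G1": (30.0, 50.0), "G2": (51.0, 60.0), "G3": (61.0, 75.0)}


class ConfigError(ValueError):
    pass


@dataclass
class TraitSpec:
    """Generating parameters of one trait.

    ``h2``/``c2`` may be single floats or per-age-group mappings; ``e2`` is
    the complement.  ``r_a``, ``r_c``, ``r_e`` are the component
    correlations with the anchor trait (ignored for the anchor itself).
    ``log_scale`` draws the trait log-normally (the latent model applies on
    the log scale), exercising the skewness-triggered log transform.
    """

    name: str
    h2: float | dict = 0.5
    c2: float | dict = 0.0
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0
    mean: float | None = None
    sd: float | None = None
    beta_age: float = 0.0   # per year, centred at 48 y
    beta_sex: float = 0.0   # female effect
    log_scale: bool = False
    missing_rate: float = 0.0

    def shares(self, group: str) -> tuple[float, float, float]:
        h2 = self.h2[group] if isinstance(self.h2, dict) else self.h2
        c2 = self.c2[group] if isinstance(self.c2, dict) else self.c2
        e2 = 1.0 - h2 - c2
        if min(h2, c2, e2) < -1e-9 or e2 <= 0:
            raise ConfigError(
                f"{self.name}: invalid shares h2={h2}, c2={c2} in group {group}"
            )
        return h2, c2, e2


@dataclass
class SimulationConfig:
    """Ground-truth description of a synthetic twin cohort."""

    n_pairs: dict[tuple[str, str], int]  # (age group, zygosity) -> pairs
    traits: dict[str, TraitSpec]
    anchor: str = "BMI"
    age_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(AGE_RANGES)
    )
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.375, "G2": 0.328, "G3": 0.25}
    )
    med_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 2024

    def validate(self) -> None:
        if any(n < 0 for n in self.n_pairs.values()):
            raise ConfigError("pair counts must be non-negative")
        for med, by_group in self.med_prevalence.items():
            for g, p in by_group.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{med} prevalence in {g} outside [0, 1]")
        for name, spec in self.traits.items():
            for g in {g for g, _ in self.n_pairs}:
                spec.shares(g)
            if not 0.0 <= spec.missing_rate <= 1.0:
                raise ConfigError(f"{name}: missing_rate outside [0, 1]")


def _pair_latent(rng: np.random.Generator, n: int, kind: str, zygosity: str) -> np.ndarray:
    """(n, 2) standard-normal latent scores with the twin correlation
    structure of one component."""
    if kind == "E":
        return rng.standard_normal((n, 2))
    if kind == "C" or zygosity == "MZ":
        return np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
    # additive genetic, DZ: correlation 1/2
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, 2))
    return np.sqrt(0.5) * shared + np.sqrt(0.5) * own


def _mix(anchor: np.ndarray, own: np.ndarray, r: float) -> np.ndarray:
    return r * anchor + np.sqrt(max(1.0 - r * r, 0.0)) * own


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate an individual-level cohort table plus a ground-truth record.

    Returns the tidy records DataFrame (cohort CSV schema) and a dict
    holding the generating configuration, the seed, and the pre-shift
    blood-pressure values of medicated individuals.
    """
    config.validate()
    trait_names = [config.anchor] + [t for t in config.traits if t != config.anchor]
    frames = []
    preshift = []
    for (group, zygosity), n in sorted(config.n_pairs.items()):
        if n == 0:
            continue
        gi = sorted({g for g, _ in config.n_pairs}).index(group)
        zi = 0 if zygosity == "MZ" else 1
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, zi))
        )
        lo, hi = config.age_ranges[group]
        age = rng.uniform(lo, hi, n)
        female = rng.random(n) < config.female_fraction.get(group, 0.5)
        meds = {}
        for med in ("med_bp", "med_glu", "med_lipid"):
            p = config.med_prevalence.get(med, {}).get(group, 0.0)
            meds[med] = rng.random((n, 2)) < p

        anchor_latents: dict[str, np.ndarray] = {}
        values: dict[str, np.ndarray] = {}
        for name in trait_names:
            spec = config.traits[name]
            h2, c2, e2 = spec.shares(group)
            latents = {
                k: _pair_latent(rng, n, k, zygosity) for k in ("A", "C", "E")
            }
            if name == config.anchor:
                anchor_latents = latents
            else:
                latents = {
                    "A": _mix(anchor_latents["A"], latents["A"], spec.r_a),
                    "C": _mix(anchor_latents["C"], latents["C"], spec.r_c),
                    "E": _mix(anchor_latents["E"], latents["E"], spec.r_e),
                }
            z = (
                np.sqrt(h2) * latents["A"]
                + np.sqrt(c2) * latents["C"]
                + np.sqrt(e2) * latents["E"]
            )
            trait = TRAITS[name]
            mean = spec.mean if spec.mean is not None else trait.mean
            sd = spec.sd if spec.sd is not None else trait.sd
            shift = (
                spec.beta_age * (age[:, None] - 48.0)
                + spec.beta_sex * female[:, None].astype(float)
            )
            if spec.log_scale:
                cv2 = (sd / mean) ** 2
                sigma = np.sqrt(np.log1p(cv2))
                mu = np.log(mean) - 0.5 * sigma**2
                vals = np.exp(mu + sigma * z + shift)
            else:
                vals = mean + sd * z + shift
            if spec.missing_rate > 0:
                vals = np.where(rng.random((n, 2)) < spec.missing_rate, np.nan, vals)
            values[name] = vals

        # medicated individuals' emitted BP is the unadjusted (lower) value
        for name, delta in (("SBP", 15.0), ("DBP", 10.0)):
            if name in values:
                med = meds["med_bp"]
                if med.any():
                    preshift.append(
                        pd.DataFrame({
                            "group": group, "zygosity": zygosity,
                            "trait": name,
                            "value": values[name][med],
                        })
                    )
                values[name] = values[name] - delta * med

        fam = np.array([f"{group}-{zygosity}-{i:05d}" for i in range(n)])
        rows = {
            "family_id": np.repeat(fam, 2),
            "member_index": np.tile([1, 2], n),
            "zygosity": zygosity,
            "sex": np.repeat(np.where(female, "female", "male"), 2),
            "age": np.repeat(age, 2),
        }
        for name in trait_names:
            rows[TRAITS[name].column] = values[name].reshape(-1)
        for med, draws in meds.items():
            rows[med] = draws.reshape(-1).astype(int)
        frames.append(pd.DataFrame(rows))

    records = pd.concat(frames, ignore_index=True)
    truth = {
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "n_pairs_total": int(sum(config.n_pairs.values())),
        "preshift_bp": pd.concat(preshift, ignore_index=True) if preshift else None,
    }
    return records, truth


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["n_pairs"] = {f"{g}:{z}": n for (g, z), n in config.n_pairs.items()}
    return d


def save_truth(truth: dict, path) -> None:
    out = dict(truth)
    if out.get("preshift_bp") is not None:
        out["preshift_bp"] = out["preshift_bp"].to_dict(orient="list")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


# ---------------------------------------------------------------------------
# preset emulating the registry cohort structure


def preset_cntr_like(seed: int = 2024) -> SimulationConfig:
    """A 1421-pair, three-age-group configuration with a realistic MZ
    excess (~59%) and per-group heritability profiles declining with age.

    The generating shares and cross-trait correlations are illustrative
    values in the range reported for adult East Asian cohorts; they define
    a plausible study population, not estimates from any particular one.
    """
    h2 = {
        "BMI": {"G1": 0.74, "G2": 0.66, "G3": 0.60},
        "HbA1c": {"G1": 0.67, "G2": 0.33, "G3": 0.34},
        "FBG": {"G1": 0.52, "G2": 0.49, "G3": 0.47},
        "SBP": {"G1": 0.61, "G2": 0.50, "G3": 0.42},
        "DBP": {"G1": 0.50, "G2": 0.45, "G3": 0.39},
        "TC": {"G1": 0.66, "G2": 0.60, "G3": 0.58},
        "TG": {"G1": 0.62, "G2": 0.55, "G3": 0.52},
        "LDL-C": {"G1": 0.63, "G2": 0.58, "G3": 0.55},
        "HDL-C": {"G1": 0.72, "G2": 0.66, "G3": 0.63},
    }
    r_a = {"HbA1c": 0.23, "FBG": 0.18, "SBP": 0.31, "DBP": 0.39,
           "TC": 0.19, "TG": 0.37, "LDL-C": 0.14, "HDL-C": -0.34}
    r_e = {"HbA1c": 0.14, "FBG": 0.17, "SBP": 0.17, "DBP": 0.20,
           "TC": 0.13, "TG": 0.31, "LDL-C": 0.13, "HDL-C": -0.15}
    beta_age = {"BMI": -0.02, "HbA1c": 0.02, "FBG": 0.02, "SBP": 0.55,
                "DBP": 0.15, "TC": 0.005, "TG": 0.0, "LDL-C": 0.005, "HDL-C": 0.002}
    beta_sex = {"BMI": -0.5, "HbA1c": 0.0, "FBG": -0.1, "SBP": -4.0,
                "DBP": -2.0, "TC": 0.05, "TG": -0.1, "LDL-C": 0.0, "HDL-C": 0.1}
    traits = {}
    for name in TRAIT_ORDER:
        traits[name] = TraitSpec(
            name=name,
            h2=h2[name],
            c2=0.0,
            r_a=r_a.get(name, 0.0),
            r_e=r_e.get(name, 0.0),
            beta_age=beta_age[name],
            beta_sex=beta_sex[name],
            log_scale=TRAITS[name].log_skewed,
        )
    n_pairs = {
        ("G1", "MZ"): 471, ("G1", "DZ"): 371,
        ("G2", "MZ"): 219, ("G2", "DZ"): 132,
        ("G3", "MZ"): 153, ("G3", "DZ"): 75,
    }
    med_prevalence = {
        "med_bp": {"G1": 0.064, "G2": 0.217, "G3": 0.382},
        "med_glu": {"G1": 0.036, "G2": 0.110, "G3": 0.136},
        "med_lipid": {"G1": 0.004, "G2": 0.012, "G3": 0.011},
    }
    return SimulationConfig(
        n_pairs=n_pairs,
        traits=traits,
        med_prevalence=med_prevalence,
        seed=seed,
    )
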