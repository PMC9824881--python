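"""Registry of the analysed phenotypes.

BMI plus eight cardiometabolic traits: two glycemic (HbA1c, FBG), two blood
pressure (SBP, DBP) and four lipid traits (TC, TG, LDL-C, HDL-C).  The
registry records the measurement unit, the trait class (which determines the
medication covariate added to the means model), and illustrative adult
population location/scale values used only as defaults by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Trait:
    """Static description of one phenotype.

    ``med_covariate`` names the medication-use column entered as a covariate
    in the means model (glucoregulatory drugs for glycemic traits, lipid
    drugs for lipid traits).  Blood pressure is handled differently: values
    of medicated individuals are shifted upward during preprocessing instead
    of adding a covariate.
    """

    name: str
    column: str
    unit: str
    kind: str  # anthropometric | glycemic | blood_pressure | lipid
    med_covariate: str | None
    mean: float
    sd: float
    log_skewed: bool = False


TRAITS: dict[str, Trait] = {
    t.name: t
    for t in [
        Trait("BMI", "bmi", "kg/m2", "anthropometric", None, 24.6, 3.4),
        Trait("HbA1c", "hba1c", "%", "glycemic", "med_glu", 5.8, 1.2),
        Trait("FBG", "fbg", "mmol/L", "glycemic", "med_glu", 5.8, 2.1),
        Trait("SBP", "sbp", "mmHg", "blood_pressure", None, 133.8, 22.2),
        Trait("DBP", "dbp", "mmHg", "blood_pressure", None, 82.2, 13.8),
        Trait("TC", "tc", "mmol/L", "lipid", "med_lipid", 4.9, 1.0),
        Trait("TG", "tg", "mmol/L", "lipid", "med_lipid", 1.9, 2.4, log_skewed=True),
        Trait("LDL-C", "ldl", "mmol/L", "lipid", "med_lipid", 2.6, 0.8),
        Trait("HDL-C", "hdl", "mmol/L", "lipid", "med_lipid", 1.3, 0.4),
    ]
}

TRAIT_ORDER = list(TRAITS)

#: columns of the tidy cohort CSV holding trait values
TRAIT_COLUMNS = {name: t.column for name, t in TRAITS.items()}
COLUMN_TO_TRAIT = {t.column: name for name, t in TRAITS.items()}

MED_COLUMNS = ("med_bp", "med_glu", "med_lipid")


def lookup(name: str) -> Trait:
    """Return the trait description, accepting either name or CSV column."""
    if name in TRAITS:
        return TRAITS[name]
    if name in COLUMN_TO_TRAIT:
        return TRAITS[COLUMN_TO_TRAIT[name]]
    valid = ", ".join(TRAITS)
    raise KeyError(f"unknown trait {name!r}; valid traits: {valid}")


def covariates_for(name: str, include_meds: bool = True) -> tuple[str, ...]:
    """Default means-model covariates for a trait: age, sex and, for glycemic
    and lipid traits, the relevant medication indicator."""
    t = lookup(name)
    covs: list[str] = ["age_c", "female"]
    if include_meds and t.med_covariate is not None:
        covs.append(t.med_covariate)
    return tuple(covs)
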