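# twinsem

Variance decomposition of twin-pair phenotype data: univariate ACE/ADE
structural-equation models and bivariate Cholesky models fitted by
full-information maximum likelihood (FIML) to same-sex MZ/DZ twin pairs.

The package is aimed at epidemiologists and behaviour geneticists analysing
registry-style twin cohorts of BMI and cardiometabolic traits (HbA1c, FBG,
SBP, DBP, TC, TG, LDL-C, HDL-C).  It answers two questions: how heritable
is each trait (and does that change across age groups or sex), and how much
of the phenotypic correlation between BMI and each cardiometabolic trait is
driven by shared genes versus shared unique environment.

## The model

For a trait measured on both members of a twin pair, the pair vector is
modelled as bivariate normal with mean **Xβ** (age, sex and medication
covariates, one β for both twins) and covariance built from latent
components: additive genetic **A** (cross-twin correlation 1 in MZ, ½ in
DZ), shared environment **C** (1 in both) or dominance **D** (1 / ¼), and
unique environment **E** (0).  With paths a, c, e the expected covariance is

    Var  = a² + c² + e²
    Cov(MZ) = a² + c²          Cov(DZ) = ½a² + c²

and heritability is the standardized share h² = a²/(a²+c²+e²).  The ACE
family is used when r_MZ < 2·r_DZ, ADE otherwise; submodels dropping A or C
are tested by likelihood ratio (E is never dropped), and the most
parsimonious non-rejected model wins, AIC breaking ties.

The bivariate model gives each component a lower-triangular 2×2 path matrix
(Cholesky), yielding genetic and environmental correlations r_a, r_e and
the decomposition r_ph = r_a·√(h²₁h²₂) + r_c·√(c²₁c²₂) + r_e·√(e²₁e²₂),
with p_a = r_a·√(h²₁h²₂)/r_ph the genetic share of the phenotypic
correlation.

Preprocessing follows registry conventions: repeat blood-pressure readings
averaged (third reading resolves a >10 mmHg discrepancy), +15/+10 mmHg
SBP/DBP correction for antihypertensive users, single-pass 3-SD outlier
removal, skewness-triggered log transformation, and age banding into
≤50 / 51–60 / >60 years.  See `docs/methods.md` for the full account.

## Worked example

Real registry data are not redistributable, so the example runs on the
package's synthetic cohort generator, which emulates a 1,421-pair,
three-age-group registry cohort with known ground truth (BMI generated at
h² declining 0.74→0.60 across age groups; r_a = 0.39, r_e = 0.20 between
BMI and DBP):

```python
import twinsem as ts
from twinsem import simulate as sim
from twinsem.preprocess import preprocess_cohort
from twinsem.traits import covariates_for

records, truth = sim.simulate_cohort(sim.preset_cntr_like(seed=1))
records, report = preprocess_cohort(records)
paired = ts.pair_twins(records)

res = ts.fit_univariate_trait(paired, "bmi", covariates_for("BMI"))
print(res.correlations)        # r_MZ = 0.686 (n=840), r_DZ = 0.340 (n=573)
print(res.best.family)         # AE  (C dropped by likelihood ratio)
print(res.components.shares)   # A: 0.69, E: 0.31
print(res.components.ci)       # A: (0.65, 0.72), E: (0.28, 0.35)

biv = ts.fit_bivariate(paired, "bmi", "dbp",
                       covariates_for("BMI"), covariates_for("DBP"),
                       family="AE")
print(biv.result)              # r_ph = 0.28, r_a = 0.36, r_e = 0.18,
                               # p_a = 0.73, p_e = 0.27
```

The MZ correlation (0.69) being about twice the DZ correlation (0.34) is
the signature of additive genetic control; the fitted h² = 0.69
(95% profile CI 0.65–0.72) recovers the generating heritability, and the
bivariate fit attributes 73% of the BMI–DBP correlation to shared genetic
influences (truth: r_a = 0.39, r_e = 0.20 at these sample sizes).

The same workflow is scriptable from the shell:

```bash
twinsem simulate --seed 1 --out cohort.csv
twinsem fit-uni cohort.csv BMI
twinsem fit-biv cohort.csv DBP --anchor BMI
twinsem pipeline cohort.csv --out results/ --seed 1
```

`pipeline` writes `table2.csv` (univariate components + profile CIs),
`table3.csv` (bivariate correlations + CIs), `fig3.csv` (twin correlations
by age group), `fig4.csv` (heritability by age group with homogeneity
p-values), `fig5.csv` (r_a/r_e by age group), `selection_trace.json` and
`run.log`.

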