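# Methods

## The biometrical twin model

`twinsem` estimates how much of the variation in BMI and eight
cardiometabolic traits (HbA1c, FBG, SBP, DBP, TC, TG, LDL-C, HDL-C) is
attributable to genes versus environment, using same-sex MZ/DZ twin pairs.
A twin pair is one observation unit: the two members' values of a trait are
bivariate normal with mean given by a covariate model and covariance implied
by latent variance components,

* **A** — additive genetic effects, correlated 1 across MZ co-twins and 1/2
  across DZ co-twins;
* **C** — shared (family) environment, correlated 1 in both zygosities;
* **D** — genetic dominance, correlated 1 (MZ) and 1/4 (DZ);
* **E** — unique environment plus measurement error, uncorrelated.

C and D are not jointly identifiable in twins reared together, so the model
families are ACE and ADE with submodels AE, CE and E.  With path
coefficients a, c (or d), e, the expected 2x2 pair covariance has diagonal
a² + c² + e² and off-diagonal a² + c² (MZ) or a²/2 + c² (DZ); ADE replaces
c² by d² with DZ weight 1/4.  Standardized shares h² = a²/total etc. sum to
one; heritability is h².  The MZ correlation estimates A + C and the DZ
correlation A/2 + C, which motivates the family choice rule: ACE when
r_MZ < 2 r_DZ, ADE otherwise (ties go to ACE).

The bivariate model for (BMI, trait) uses a Cholesky parameterization: each
component loads on the two traits through a lower-triangular 2x2 path
matrix, so each component covariance block is positive semi-definite by
construction.  Derived quantities are the component correlations
(r_a = genetic, r_c = shared-environment, r_e = unique-environment), the
phenotypic correlation r_ph, and the decomposition

    r_ph = r_a sqrt(h²₁ h²₂) + r_c sqrt(c²₁ c²₂) + r_e sqrt(e²₁ e²₂).

The genetic share of the phenotypic correlation is defined as
p_a = r_a sqrt(h²₁ h²₂) / r_ph (the genetic covariance share), and p_e
analogously; p_a + p_e = 1 when C is dropped.  The alternative definition
p_a = r_a / r_ph is not used: it is not a share (it can exceed 1) and is
inconsistent with the decomposition above.

## Estimation

The Gaussian log-likelihood is evaluated per pair (full information):
pairs with one member's trait missing contribute the univariate marginal
density of the observed member rather than being dropped.  Covariates
(age, sex, and for glycemic/lipid traits the relevant medication indicator)
enter the means model with one coefficient vector shared by both twins;
this keeps the variance decomposition on the covariate-adjusted scale.
Pre-residualization on covariates is used only for the descriptive twin
correlations, which are double-entry Pearson correlations (each pair enters
in both orders, making the estimate symmetric in twin labelling).

Paths are optimized unconstrained (variances enter as squares, so
non-negativity is automatic) by L-BFGS-B with numerical gradients, using
five seeded starts: a moment-based start from the observed twin
correlations, an equal-shares start, and three random perturbations; the
best optimum is kept.  Path signs are not identified and are reported as
absolute values (in the bivariate model, each component's column signs are
chosen so the diagonal paths are non-negative).  Default tolerances are
`ftol = 1e-10` and a projected-gradient tolerance of `1e-5`; a fit is
flagged non-converged when the optimizer fails and the final gradient norm
is large relative to the log-likelihood.  Traits are z-scored internally
before fitting — every reported quantity is standardized and
scale-invariant — and a non-positive-definite covariance evaluates to a
large negative sentinel rather than raising, so the optimizer can recover.

### Model selection

For each trait the full family (ACE or ADE, chosen by the correlation rule)
is fitted along with submodels dropping A and dropping C; E is never
dropped because it absorbs measurement error, and dominance without an
additive effect is not considered (ADE reduces to AE or E).  Each submodel
is compared to the full model by likelihood ratio; submodels whose
constraint is rejected at p < 0.05 are inadmissible.  Among the admissible
models the most parsimonious is selected, with AIC (−2 logL + 2k) breaking
ties.  p-values use the naive chi-square reference, the default in twin
software; when a variance is constrained to its boundary (e.g. c² = 0 true)
this reference is conservative by roughly a factor of two, and
`likelihood.boundary_mixture_p` provides the 50:50 mixture correction for
users who want it.  The cross-path constraints of the bivariate model
(a21 = c21 = e21 = 0 tests) are interior hypotheses, so the chi-square
reference applies directly there.

### Confidence intervals

Univariate shares get profile-likelihood intervals: the share is fixed at a
trial value, all remaining parameters (the other shares renormalized, the
total variance, the means coefficients) are re-optimized, and the bounds
are where the profile drops chi²₁(0.95)/2 = 1.92 below the maximum,
truncated at [0, 1] with a boundary flag.  Derived bivariate quantities
(r_ph, r_a, r_e, p_a, p_e, per-trait shares) get delta-method intervals
from the numerically evaluated observed information; profiling a derived
nonlinear function of ~15 parameters is far more expensive and, away from
the correlation boundaries, agrees closely with the delta method at these
sample sizes.  Per-age-group heritabilities in `fig4.csv` likewise use
delta-method intervals for speed; the headline full-population intervals in
`table2.csv` are always profile-based.

### Homogeneity across groups

Whether components change across strata (age groups, sex) is tested by a
likelihood-ratio test of a constrained multigroup fit against free
per-group fits.  The constrained univariate model equates the
*standardized* shares across groups while total variance and means stay
free per group (shares are what is reported, so shares are what is
equated); its degrees of freedom are (n_groups − 1) × (components − 1).
The bivariate analogue equates the component correlations {r_a, r_e} (plus
r_c under ACE) across groups while per-group shares, scales and means stay
free, df = (n_groups − 1) × n_correlations; it is parameterized directly in
(shares, correlations) through logistic/tanh transforms and warm-started
from the free fits.

## Preprocessing conventions

* Repeated sitting BP readings: average the first two; if they differ by
  more than 10 mmHg a third reading is required and the two closest of the
  three are averaged.
* Antihypertensive medication: +15 mmHg to SBP and +10 mmHg to DBP of
  medicated individuals (a standard censored-treatment correction); applied
  per field, idempotent via a processed flag.  Glucoregulatory and lipid
  medication are means-model covariates instead.
* Outliers: values more than 3 SD from the mean are removed in a single
  pass, computed on the full analysis population on the raw scale before
  age-group splitting and before log transformation.  The single-shot
  full-population convention is a documented choice; iterating the rule or
  applying it per group would remove slightly different sets.
* Log transformation: a trait is transformed when |sample skewness| > 1 or
  when it is on the force-list (default {TG}, the clearly right-skewed
  lipid); both the threshold and the list are configurable.
* Age groups: G1 ≤ 50 y, G2 = [51, 60] y, G3 > 60 y.  G2 is a closed
  integer band, so non-integer ages in (50, 51) fall in G1 and in (60, 61)
  fall in G3; every positive age maps to exactly one group.  Twins share a
  birth date, so the pair age (mean of members, with a warning if they
  disagree) determines the group.

## The synthetic cohort generator

Real twin-registry phenotype data are not redistributable, so every
analysis stage is exercised on generated cohorts with known ground truth.
The generator draws explicit latent A/C/E scores per trait with the twin
correlation structure above — latent-factor simulation rather than a draw
from the implied covariance matrix, so that oracle checks can correlate the
latent scores directly.  Cross-trait structure versus BMI is induced by
mixing each trait's latents with BMI's at the configured component
correlations.  Standardized scores are rescaled to plausible adult trait
units, age and sex effects are added, medication flags are drawn per
age-group prevalence, and the emitted SBP/DBP of medicated individuals are
the *unadjusted* values so that preprocessing has real work to do.
Missingness is completely at random.  One master seed drives a
`SeedSequence` hierarchy with an independent substream per (age group,
zygosity) cell, so changing one cell's count does not perturb any other
cell's draws.

`preset_cntr_like()` describes a 1,421-pair cohort: 842/351/228 pairs in
the three age groups with MZ fractions 0.559/0.624/0.671 (59.3% MZ
overall), female fractions 0.375/0.328/0.250, age-increasing
antihypertensive (6.4%/21.7%/38.2%), glucoregulatory and lipid medication
prevalences, per-trait heritabilities declining with age (e.g. BMI
0.74 → 0.66 → 0.60), no shared-environment variance, and genetic/
environmental correlations with BMI ranging from r_a = −0.34 (HDL-C) to
0.39 (DBP).  These are illustrative values chosen to be realistic for an
adult East Asian registry population; they define a plausible study
population for exercising the pipeline, not estimates of any particular
cohort.

What the generator does **not** emulate: assortative mating, sex-specific
genetic architecture, genotype data, selection effects in registry
recruitment, non-Gaussian measurement error, informative missingness, or
longitudinal repeat measures.  Passing tests therefore demonstrate that the
estimators recover known generating structure under the model's own
assumptions — not that those assumptions hold in any real cohort.

## Problem sizes used in the test suite

Parameter-recovery checks use 4,000 pairs (estimates within ±0.04 of
generating shares; ±0.06 for bivariate correlations); profile-CI coverage
uses 200 replicates of 1,000 pairs; LRT calibration uses 300 replicates of
400-pair groups (within the 3–7% band at nominal 5%); model-selection
checks use 100 replicates of 4,000 pairs per scenario.  These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the default suite quick to run.

## Known limitations

* No sex-limitation models (distinct male/female genetic factors) and no
  opposite-sex pairs; no GxE moderation; no Bayesian or robust-SE variants.
* The chi-square reference for boundary constraints is conservative (see
  above); the mixture correction is available but not the default, to
  match common practice.
* Delta-method intervals for bivariate correlations can be inaccurate when
  an estimate sits near ±1 or when a component variance is near zero; such
  intervals are clipped to the parameter range.
* FIML handles member-level missingness but assumes missing-at-random;
  whole-pair exclusion (singletons) follows registry eligibility rather
  than being modelled.
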