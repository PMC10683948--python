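# Methods

## The analysis chain

`nephrocog` implements an epidemiological analysis pipeline linking kidney
function to cognitive level, cognitive decline and brain-MRI indices in an
older community-dwelling cohort, together with a synthetic cohort generator
that makes the whole chain testable against known ground truth.

### Kidney function

Five estimating equations convert serum creatinine (mg/dL, IDMS-aligned)
and cystatin C (mg/L) into eGFR (mL/min/1.73 m²): the CKD-EPI 2009
creatinine equation, the CKD-EPI 2012 cystatin C equation, the CKD-EPI 2012
combined equation, the IDMS-traceable 4-variable MDRD equation (175
constant), and the Berlin Initiative Study BIS1 equation. Each CKD-EPI
equation is a two-piece power law in the marker, continuous at its knot
(κ = 0.7/0.9 for creatinine by sex, 0.8 for cystatin C) and strictly
decreasing in marker and age. The race multipliers of the original
publications default to 1 (no adjustment) — the target population is an
Irish community cohort — but remain available as a switch. CKD is defined as
combined-equation eGFR strictly below 60. Cystatin C quartile strata use
sample quantiles (linear interpolation) of the wave-1 distribution, with a
value equal to a cut point assigned to the stratum below it, so tied blocks
produce the unequal group sizes typical of assay-rounded data.

### Composite scores

Biomarker scores are **sums** of z-standardised plasma concentrations
(inflammation: TNF-α, IL-6, IL-8, IL-1RA; cardiovascular: NT-proBNP,
GDF15); cognitive composites are **means** of z-scores (global: MoCA, MMSE;
memory: immediate/delayed recall; executive: Colour Trail 1/2 times and
SART mean RT). The sum-vs-mean asymmetry is deliberate and follows the
construction the scores are meant to reproduce. Standardisation uses the
sample SD (n−1). The reference sample is the wave-1 analysis sample; wave-3
cognitive tests are standardised against the wave-1 moments so wave
differences are measured on a fixed scale. Timing-based z-scores are
multiplied by −1 before averaging so that every composite reads "higher =
better"; this orientation makes kidney-impairment coefficients on all
cognitive outcomes comparable in sign.

### Association models

A strictly nested adjustment scheme: M1 = age, sex, education, depression
(+ baseline cognitive score in longitudinal models); M2 = M1 + smoking,
obesity, systolic and diastolic BP, number of CVD risk factors (count of
smoking/diabetes/hypertension/obesity flags), diabetes, total cholesterol,
HDL, CRP; M3 = M2 + the two biomarker scores. Continuous variables are
z-scored within the complete-case sample of each fit, so exposure
coefficients are standardised betas. Analyses are complete-case per tier;
every result carries its `n_used`. Pulse wave velocity is excluded from the
default covariate sets because its missingness is informative (enriched at
low eGFR); a switch forces it in.

Longitudinal decline uses a random-intercept linear mixed model on the
repeated z-scored global composite with a wave indicator and an
exposure × wave interaction (the decline association). With only two waves,
random slopes are unidentifiable, hence intercept-only. An ANCOVA
alternative (wave-3 score given wave-1 baseline) is available behind a
method switch; the two agree in direction on synthetic data.

The Jonckheere–Terpstra trend test is implemented directly: the statistic
sums pairwise Mann–Whitney counts over ordered group pairs, ties counting
½. For pooled n ≤ 9 the one-sided p-value is exact by exhaustive
enumeration of group reassignments; otherwise a tie-corrected normal
approximation is used. Variance inflation factors come from auxiliary
regressions, VIF = 1/(1−R²), with perfect collinearity reported as
infinite.

MRI outcomes: Scheltens WMH scores are binned 0–9/10–19/20–29/≥30 into four
ordered classes and modelled with a proportional-odds (ordered logistic)
model fitted by maximum likelihood; the exposure effect is reported as an
odds ratio with a Wald 95% CI. Regional grey-matter volumes are bilateral
sums divided by estimated intracranial volume and z-scored; regional
multiplicity uses a Bonferroni threshold (0.05 over 34 bilateral cortical
regions ≈ 1.5 × 10⁻³). Grey-matter CBF is contrasted for the top wave-1
cystatin quartile against the rest.

### Mediation

For exposure A (ln-cystatin C), mediator M, outcome Y and confounders C,
two linear regressions fitted by OLS on the identical complete-case rows —
M ~ A + C and Y ~ A + M + C — give NDE = θ₁(a−a*), NIE = θ₂β₁(a−a*),
TE = NDE + NIE, and proportion mediated = 100·NIE/TE. The default contrast
is one unit of ln-cystatin C. No exposure–mediator interaction is modelled;
with that restriction the product method and the difference method (the
exposure coefficient of the reduced model Y ~ A + C minus θ₁) coincide as
an exact algebraic identity, which the tests verify to 10⁻¹⁰ and which
serves as the core internal oracle. Uncertainty comes from a paired
nonparametric bootstrap (default 1000 replicates, seeded): rows are
resampled with replacement and all three regressions are refitted per
replicate (vectorised as batched normal-equation solves); intervals are
percentile-based and p-values use the bootstrap-SE normal approximation.
The proportion mediated is left as a raw signed value in the result object
(opposite-sign NDE/NIE can push it outside [0, 100]); truncation is a
display decision, and PM is flagged undefined when |TE| < 10⁻⁸. The
mediator screen crosses outcomes × mediators × tiers, removes the mediator
from its own confounder set, drops age from the adjustment set whenever age
itself is the mediator, and adds the wave-1 baseline score when the outcome
is a wave-3 − wave-1 difference.

## Synthetic cohort generator

The generator emulates a population cohort aged 50+ with a right-skewed age
distribution (Beta(1.2, 2.3) scaled to 50–85, mean ≈ 62), a log-normal
cystatin C rising with age (median ≈ 0.92 mg/L at the mean age), and
creatinine correlated with cystatin and sex. The structural chain is
linear-Gaussian: the latent cardiovascular burden M = β₁A + (confounders) +
ε_M with β₁ = 0.5 by default, wave-1 cognition Y₁ = θ₁A + θ₂M +
(confounders) + ε_Y with θ₁ = −0.3 and θ₂ = −0.4, and wave-3 cognition
Y₃ = Y₁ + d₀ + d₁A + d₂M + ε_D (d₁ = −0.15, d₂ = −0.10). Age confounds
A, M and Y, so age-mediation scenarios are constructible. NT-proBNP and
GDF15 load on M (making the cardiovascular biomarker score a noisy proxy of
the true mediator); inflammatory markers drift with age and kidney
function. An MRI subset (15% of participants, matching the relative size of
typical MRI sub-studies) carries a Scheltens score generated by cutting a
latent linear predictor with standard-logistic noise at fixed cutpoints —
so the proportional-odds assumption holds exactly in-distribution — plus
ICV, hemispheric grey-matter volumes and CBF decreasing in age and
exposure. Pulse wave velocity is blanked at a 12% overall rate with a
logistic weight in −eGFR renormalised to the target rate, making
missingness monotone in kidney impairment.

Randomness flows from a single seed through named substreams (one generator
per variable block, keyed by CRC-32 of the block name), so identical
seed + config gives a byte-identical table and adding a new column never
perturbs existing ones. The truth object reports the generating NDE, NIE,
TE and proportion mediated implied by the path coefficients, with
TE = NDE + NIE exact by construction.

What the generator does *not* emulate: survey sampling weights, item-level
test structure, measurement drift between waves, informative dropout
(everyone has both waves), non-linear exposure effects, and real-world
departures from proportional odds. Passing tests therefore demonstrate
that the estimators recover known linear-Gaussian truth and that the
decomposition identities hold — not that real cohort data meet those
assumptions.

## Numerical choices

- OLS inside the mediation engine uses normal equations (`solve` on XᵀX);
  designs are small and well-conditioned after complete-case filtering, and
  rank deficiency is checked explicitly beforehand.
- Bootstrap refits are batched with einsum-built XᵀX stacks, chunked to
  keep the resampled design tensor under ~200 MB.
- Mixed models use REML with L-BFGS; ordered logistic uses BFGS maximum
  likelihood with unconstrained-but-ordered cutpoints (statsmodels
  parameterisation).
- Zero-variance columns, constant ordinal outcomes, all-missing cystatin,
  non-positive markers/ICV and rates ≥ 1 raise immediately with named
  columns rather than propagating NaNs.
- Quartile ties go to the lower stratum; the CKD threshold is strict (<60).

## Problem sizes

Default validation runs use n = 4000 participants for point recovery
(matching the cohort scale the pipeline targets), 500 replicates of
n = 2000 with 400 bootstrap draws for interval calibration, and 30
replicates of n = 800 for the attenuation property — sizes chosen so the
full battery completes in a few minutes on one CPU while keeping
Monte-Carlo error well below the tolerances being checked.

## Known limitations

- Two waves identify only a random-intercept longitudinal model; decline
  estimates conflate within-person change with differential measurement
  error at wave 3.
- The bootstrap p-value uses a normal approximation on the bootstrap SE;
  for strongly skewed effect distributions the percentile interval is the
  more trustworthy summary.
- The mediation decomposition assumes correctly specified linear models, no
  exposure–mediator interaction, and no exposure-affected mediator–outcome
  confounding; the generator satisfies these by construction, real data
  need not.
- The proportional-odds fit does not test the proportional-odds assumption;
  on real data a score test should accompany it.
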