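# Methods

This note documents the models, defaults and design choices behind
`thermotk`, and what the synthetic-data tests do and do not demonstrate
about real compiled datasets.

## Models

**Arrhenius relation.** Uptake and elimination rate constants are modelled
as `k(T) = exp(ln_A + slope_K / T)` with `slope_K = −E_A/R` in Kelvin.
Both processes are transport-dominated in aquatic ectotherms, which is
the mechanistic justification for an Arrhenius form. The gas constant is
taken as R = 8.31 J K⁻¹ mol⁻¹ — the printed working precision of the
field's reporting — so `E_A = −slope_K × 8.31` matches reported
activation energies (slope −10,000 K ↔ 83.1 kJ mol⁻¹). Kelvin is the
internal temperature unit everywhere; Celsius appears only at the CSV
boundary (`T_K = T_°C + 273.15`).

**Allometric correction.** `mass_correct` implements `k* = k · m^(1/4)`,
i.e. division by the expected quarter-power scaling `m^(−1/4)`,
normalizing rate constants to a 1 kg organism. This is the only reading
consistent with the stated units of `k*` (L kg⁻¹ kg^(1/4) d⁻¹) and with
allometric theory (`k ∼ m^(−1/4)`); the pair
`mass_correct`/`mass_uncorrect` is exactly inverse.

**Bioconcentration factor.** `BCF = k_u / k_e`, the one-compartment
steady state. Writing `ln BCF = ln k_u − ln k_e` makes the
temperature-independence argument literal: the slope of `ln BCF` against
`1/T` is the difference of the two Arrhenius slopes, so the assessment
reports `Δslope = slope_u − slope_e` with SE `√(SE_u² + SE_e²)` and a
normal 95% CI, treating the two pooled fits as independent (they share no
records; this is an approximation in so far as study-level heterogeneity
correlates the two compilations). Verdict: temperature-independent iff
the CI contains zero. When paired `(k_u, k_e)` values per
organism/temperature exist, `ln(k_u/k_e)` is also regressed on `1/T`
directly.

## Regression and inference

The linearized fit is ordinary least squares of `y = ln k` (natural log
throughout) on `x = 1/T`, solved in closed form from centered sums; `x`
is centered before solving and the intercept back-transformed, which is
numerically exact here and stable for the tiny dynamic range of `1/T`.
Reported statistics follow the field's table format: coefficient SEs from
the residual variance (`df = n − 2`), CV% = 100·SE/|estimate|, 95% CIs as
`estimate ± t(0.975, df)·SE`, R², and the two-sided t-test p-value of the
slope (identical to the regression F-test for one predictor). The "± SD"
attached to published coefficients of this kind is interpreted as the
coefficient standard error — the printed CIs reproduce from
`estimate ± t·SD` to well under 0.05% relative, which fixes that reading.
No weighting across source studies is applied; duplicate averaging is the
pooling step. statsmodels is deliberately not used in the implementation;
it serves as an independent cross-check in the test suite.

Unfittable inputs (fewer than 3 records, zero variance in `1/T`, missing
masses under correction) raise typed errors; nothing is dropped silently
except in `compare_models`, whose contract is precisely to drop and count
mass-missing records for the corrected variant.

## Data treatment

Three rules mirror standard compilation practice:

1. **Duplicate averaging.** Records of the same (species, chemical, rate
   type) at the same temperature rounded to the nearest whole °C (ties
   away from zero; the tie rule is a documented choice, as is averaging
   `k` arithmetically on the natural scale rather than `ln k` — a
   geometric-mean alternative would shift means of duplicate pairs by at
   most a few percent at the observed duplicate rates) collapse to one
   record carrying the mean `k` and the mean exact temperature. The
   operation is idempotent because the mean of temperatures rounding to
   one degree rounds to that same degree.
2. **Mass imputation.** Missing masses are filled from a species
   reference table, preferring the record's life stage, then the
   species-level entry (a stage-free row, else the mean over the species'
   entries). Unmatched records are flagged and excluded only from
   mass-corrected analyses.
3. **Minimum distinct temperatures.** Chemical- and species-specific
   regressions require ≥ 4 distinct rounded temperatures per stratum
   (configurable); pooled fits are never filtered this way.

## Slope homogeneity across strata

Each chemical (one log D_ow value per substance) or species forms a
stratum. Slope equality is tested with the nested-RSS F-test comparing
per-stratum slopes + intercepts against a common slope with per-stratum
intercepts: `F = [(RSS_c − RSS_s)/(G−1)] / [RSS_s/(N−2G)]`. This is the
standard ANCOVA realization of a "slopes do not differ (p > 0.05)"
claim; a pairwise variant with Holm-adjusted p-values is available
(`pairwise_slope_tests`), and stratified result tables always carry a
Holm column alongside unadjusted p-values. Type-I error of the joint test
is verified by simulation to sit in the binomial band around 5%.

## Synthetic-data generator

The generator emulates the structure of a literature compilation whose
raw table is not redistributable, with defaults fixed at the published
study conditions:

- **True parameters**: uptake `ln A = 40.11`, `slope = −10,000 K`;
  elimination `ln A = 25.73`, `slope = −7888 K` (the published pooled
  uncorrected fits, bundled in `thermotk.reference`).
- **Counts**: 530 uptake, 958 elimination records; per-taxon composition
  drawn from the published per-taxon record counts per rate type, with
  synthetic species labels sized by the published species richness.
- **Temperatures**: uniform on 278–303 K (≈ 5–30 °C). The empirical
  temperature distribution of real compilations is unreported; uniform is
  the declared assumption and is exposed in the config.
- **Noise**: additive Gaussian on `ln k`, σ = 2.0 by default — keeps `k`
  strictly positive (lognormal), is homoscedastic on the fitting scale,
  and brackets the low pooled R² (≈ 0.04–0.12) characteristic of such
  heterogeneous compilations.
- **Hydrophobicity**: each of `n_chemicals` substances gets a log D_ow
  uniform on 0–8; D_ow shifts *intercepts* by default
  (+0.6 ln-units per log D_ow unit for uptake, −0.4 for elimination —
  direction from the reported chemistry, magnitude a documented choice),
  not slopes; a `dow_slope_coeff` knob exists for power studies of the
  homogeneity test.
- **Masses**: per-taxon log-uniform intervals (insects/crustaceans
  10⁻⁶–10⁻³ kg, molluscs/worms 10⁻⁵–10⁻² kg, fish 10⁻³–1 kg); no
  published mass table exists, so these are documented defaults. A
  `mass_exponent` knob (−0.25 for allometric data) controls whether mass
  enters the generating law; the default 0 generates mass-free data so
  that the uncorrected/corrected model comparison has a known null.
- **Duplicates**: 10% of each rate type's budget are copies of existing
  records (same species/chemical/exact temperature) with fresh noise, so
  duplicate averaging is exercised; total counts stay exact.

Everything derives from one integer seed via `numpy.random.default_rng`;
identical seeds give byte-identical frames.

**What passing tests do not show.** The generator's records are
exchangeable given taxon and chemical: real compilations have study-level
clustering, correlated uptake/elimination pairs from the same experiment,
non-uniform temperature coverage, reporting/rounding artifacts and
publication bias. Recovery and calibration results here validate the
estimators and pipeline plumbing under the declared generative model,
not the field reliability of any particular published coefficient.

## One-compartment experiment stand-in

Compiled rate constants originate upstream in accumulation/depuration
assays. `tk_experiment` implements the canonical constant-exposure
design: `C(t) = (k_u/k_e)·C_w·(1 − e^(−k_e t))` during uptake,
exponential decay after transfer to clean water, multiplicative lognormal
measurement noise. Estimation is least squares on `(ln k_u, ln k_e)`
(positivity by construction), by default in ln-concentration space where
the noise model is homoscedastic (`scale="natural"` is available);
starting values come from the log-linear depuration slope and the last
uptake-phase point; tolerances 10⁻¹⁰, ≤ 500 iterations, non-convergence
returned flagged. The `(1 − e^(−k_e t))/k_e` term uses `expm1`, so the
fit degrades gracefully toward the linear-uptake limit as `k_e → 0`.
Sample times must be strictly positive: a t = 0 sample has zero internal
concentration, carries no information about either rate constant, and is
undefined on the ln scale. Growth dilution, dietary uptake and
biotransformation are out of scope.

## Problem sizes and numerical conventions

Monte-Carlo suites use 500 replicates for recovery/coverage checks
(Monte-Carlo SE of the mean slope ≈ 45 K at the default conditions,
comfortably resolving bias at the ±3 MC-SE criterion) and 1000 replicates
for the F-test calibration band (3.6–6.4% at α = 0.05); these sizes make
the full test suite run in well under a minute while keeping binomial
bands meaningful. Degenerate cases are defined explicitly: R² is 1 for a
perfect fit with zero total variation; p-values are floored at the
smallest positive float; identical duplicated strata give F = 0, p = 1;
noiseless strata give F = 0 by the max(·, 0) guard on the RSS
difference.

## Known limitations

- The Δslope CI for the BCF ignores any correlation between the uptake
  and elimination compilations (independent-fits approximation).
- Arithmetic-vs-geometric duplicate averaging and the °C rounding tie
  rule are conventions; both are flagged above and trivially swappable.
- Mixed-effects or phylogenetically corrected regression, multi-
  compartment kinetics, time-varying (heat-wave) temperatures and
  pH-dependent D_ow computation are out of scope by design.
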