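# Methods

## The analysis model

The pipeline estimates group differences in DNA-methylation-derived
biomarkers while removing the dominant nuisance structure — chronological
age and sex — using a *reference-anchored* two-stage procedure rather than a
single pooled regression:

1. For biomarker *y*, fit `y = β₀ + β₁·age + β₂·sex + ε` by ordinary least
   squares using **only** the samples of a designated reference group
   (in the diabetic-neuropathy setting, the painless-neuropathy group).
2. Compute residuals `r_s = y_s − (β₀ + β₁·age_s + β₂·sex_s)` for **every**
   sample, reference included.
3. Compare groups on the residuals with two-sided equal-variance t-tests at
   α = 0.05.

Anchoring the fit on one group means the other groups' residuals measure
displacement from the *reference* aging trajectory, not from a pooled
average that the case groups themselves distort. The reference group's mean
residual is exactly 0 (OLS with intercept), which is a useful internal
check and the reason plots of residuals show the reference group oscillating
around baseline.

Assumptions: biomarker values are linear in age over the cohort's age range
with an additive sex offset; residual variances are comparable across groups
(equal-variance t; Welch available behind `welch: true`); observations are
independent.

## Stage order and QC

Stages run in a fixed, logged order: config validation → detection-p QC →
biomarker computation → Tukey-fence outlier removal → reference fit →
residuals → contrasts → correlations. Two ordering rules are contracts, not
accidents:

- **QC removes samples before probes.** A sample is dropped when its mean
  detection p-value is strictly above 0.05; afterwards a probe is dropped
  when its detection p is strictly above 0.01 in at least one *surviving*
  sample. A probe failing only in an already-removed sample is retained.
  The converse order would discard extra probes. Thresholds are config
  values with these defaults. If no detection-p matrix is supplied, QC is
  skipped with a warning (deposited processed matrices are usually
  pre-filtered upstream).
- **Outlier removal precedes the reference fit**, so fences are computed on
  raw biomarker values and the fit never sees gross outliers.

Beta values outside [0, 1] are hard errors, never clamped: silent clamping
hides upstream normalization faults.

## Outlier rule

Per biomarker, values strictly outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are
masked for that biomarker only; the sample stays in the table for other
biomarkers. Quartiles use linear interpolation between closest order
statistics (the numpy default) — the fence position depends on this
convention, so it is fixed and documented. Fences are computed over all
samples pooled; per-group fencing sits behind `per_group_fences: true`.
Exactly **one** pass is performed: the rule is deliberately not iterated,
because re-fencing trimmed data can flag ever more points.

Two subtleties worth knowing:

- A constant shift of a biomarker commutes with the whole pipeline
  (quantiles are translation-equivariant), so contrasts are exactly
  invariant under it. An age-proportional shift is absorbed by the age
  slope of the reference model — residuals are invariant from the
  regression stage on — but it can reorder the pooled values and thereby
  change which cells the fences flag.
- Under the null the light symmetric trimming leaves the t-test calibration
  essentially intact (verified by simulation; see below).

## Clock engine

Linear clocks are `g(β₀ + Σ wⱼ βⱼ)` with `g` identity or the piecewise
anti-log calibration used by Horvath-family clocks:
`x < 0 → (1+A)·eˣ − 1`, `x ≥ 0 → (1+A)·x + A`, with knot `A = adult_age`
(default 20 years) — continuous and strictly increasing. PC-clocks
(a linear CpG→component projection followed by a linear component→score
map) are algebraically one linear map, so they are stored pre-flattened;
no second coefficient format exists. Composite clocks are
`β₀ + Σ wᵢ·biomarkerᵢ + w_age·age + w_sex·sex`; no proprietary coefficient
sets ship with the package — definitions are user-supplied files, and the
engine only guarantees the structural form.

Missing data: clock CpGs absent from the matrix are dropped (counted in the
result); NaN cells among matched CpGs are imputed with the probe's cohort
mean by default (`missing_policy="impute-cohort-mean"`, the convention of
published calculators) or rejected with `"error"`.

Cell fractions solve `min ‖R·f − β_s‖², f ≥ 0` by NNLS over the shared
probes, then renormalize `f` to the simplex, keeping the pre-normalization
sum as a fit diagnostic. An equality-constrained quadratic program would be
marginally more faithful but needs a QP solver; NNLS + renormalization is
deterministic, dependency-light, and recovers noiseless mixtures exactly.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | PDN 99 / PLDN 132 / CTRL 84 | group sizes |
| `age_range` | 41–84 y (uniform) | chronological age |
| `male_fraction` | 0.74 | P(sex = 1) |
| `acceleration` | +3 / 0 / −2 y | mean epigenetic offset Δ_g per group |
| `accel_sd` | 3 y | between-individual spread of the offset |
| `n_cpgs` | 50 | probes |
| `baseline_beta`, `age_slope` | 0.2, 0.005 /y | β at age 0 and drift per year |
| `sex_effect` | 0.01 β units | additive probe offset for sex = 1 |
| `probe_noise_sd` | 0.01 β units | i.i.d. Gaussian probe noise |
| `detp_fail_rate` | 1e-4 | per-cell detection failures |

Betas are `clip₀¹(b₀ + s·(age + accel) + sex_effect·sex + ε)`; the clipped
fraction is reported and is < 1% (in fact 0) under the defaults, and a
warning fires when a configuration pushes expected betas outside
[0.05, 0.95]. Acceleration is additive **in years on an effective age**, so
the injected Δ is directly comparable to clock residuals downstream — the
cleanest testable encoding of "accelerated epigenetic aging". The matched
toy clock (`w = 1/(m·s)`, intercept `−b₀/s`) reads effective age back
exactly when noise and sex effect are zero; a nonzero sex effect adds
`sex_effect/s` years for sex = 1, absorbed by the sex covariate of the
reference model. Detection failures at 1e-4 per cell yield a few percent
probe loss under the "fails in ≥ 1 sample" rule at n ≈ 300 — a realistic
QC funnel.

Each sample draws from its own deterministically spawned substream of the
cohort seed, so enlarging the cohort or reordering probes never perturbs
existing samples.

**What the generator does not model:** real EPIC probe-beta distributions
(bimodality, heteroscedasticity), beadchip batch effects, cell-composition
confounding with age or phenotype, and correlated probe noise. Passing
tests therefore demonstrate the *procedure* is implemented correctly and is
calibrated under its own assumptions — not that any particular real cohort
satisfies those assumptions.

## Simulation checks and problem sizes

The acceptance suite and `scripts/acceptance.py` run the full pipeline at
the default conditions: 100 seeded cohorts of 315 samples for effect
recovery (mean recovered PDN−PLDN residual difference ≈ the injected 3 y;
contrast significant in ≥ 90% of seeds) and 400 null cohorts for type-I
error (rejection rate inside the exact binomial 99% interval around 0.05;
the rate runs very slightly above 0.05 because case-group residuals carry
the reference fit's estimation error). Oracle-equivalence checks use
n ≤ 25 cohorts against an independent flat re-derivation at 1e-8. These
sizes keep a full run in the tens of seconds on one CPU while leaving the
Monte-Carlo error well inside the tested bands.

## Numerical and design choices

- OLS via `numpy.linalg.lstsq` with an explicit rank check; a constant-age
  reference group is an error naming the degenerate column, while a
  single-sex reference group drops the sex covariate with a warning
  (it is collinear with the intercept) rather than failing.
- Sex is otherwise always retained in the reference model, significant or
  not; age-and-sex correction is the declared adjustment set, and dropping
  covariates by significance would make the residual definition
  data-dependent.
- Zero-variance t-tests: identical groups give `t = 0, p = 1`; distinct
  means with zero pooled variance are an error (the statistic is
  undefined), never a silent infinity.
- The age ANOVA is the classic fixed-effects one-way test (Welch's variant
  was considered; the classic form matches the equal-variance convention
  used for all pairwise tests).
- No multiple-testing correction by default — the raw α = 0.05 flag is the
  primary output; `bh_correction: true` adds a Benjamini–Hochberg q-value
  column alongside the raw p.
- Sample-sheet sex coding is a configurable map, default F→0, M→1.
- All thresholds (0.05, 0.01, the 1.5 IQR factor, α) are surfaced in the
  pipeline config with these defaults.

## Limitations

- The engine represents named clocks structurally; it does not ship or
  reproduce published coefficient values, and no normalization
  (functional/quantile) or IDAT parsing is included — the input is an
  already-normalized beta matrix.
- Only age and sex are adjusted for; no mixed models or additional
  covariates.
- The t-test calibration statement holds under the generator's Gaussian,
  independent-sample world; heavy-tailed or batch-structured real data may
  behave differently, which is precisely why the removal log and manifest
  make every masking and fitting decision auditable.
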