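# methaging

A pipeline for studying **epigenetic age acceleration between phenotype
groups** from Illumina-style DNA methylation data — motivated by cohort
studies of painful (PDN) versus painless (PLDN) diabetic neuropathy and
healthy controls (CTRL), but written for arbitrary group labels.

Given a probe × sample matrix of methylation beta values
(β ∈ [0, 1], the ratio of methylated to total signal), the pipeline:

1. **QC** — removes samples whose mean detection p-value exceeds 0.05, then
   probes with detection p > 0.01 in at least one *remaining* sample
   (order matters and is fixed: samples first).
2. **Biomarkers** — evaluates epigenetic clocks
   `score_s = g(β₀ + Σⱼ wⱼ β_js)` with `g` either the identity or the
   piecewise anti-log calibration of the Horvath clock family; composite
   (GrimAge-style) clocks over sub-biomarkers + age + sex; and blood
   cell-type fractions by constrained projection (non-negative least
   squares, renormalized onto the simplex) against a cell reference.
   PC-clocks are handled as pre-flattened linear clocks.
3. **Outlier removal** — Tukey fences per biomarker: values strictly
   outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (linear-interpolation quartiles)
   are masked for that biomarker only.
4. **Two-stage residual-outcome regression** — for each biomarker, OLS
   `y ~ age + sex` is fitted **on the reference group only** (e.g. PLDN);
   residuals from that fit are computed for every sample; groups are
   compared on the residuals with two-sided equal-variance t-tests
   (df = n₁ + n₂ − 2). One-way ANOVA and Pearson correlations are
   available for cohort description and biomarker cross-correlation.
5. **Reporting** — tidy CSVs (contrast table, residuals, removal log,
   reference-model coefficients) plus a run manifest for reproducibility.

A synthetic cohort generator with **known injected acceleration** makes
every stage testable without any data download: betas drift linearly with
an "effective age" `age + accel`, where `accel ~ Normal(Δ_group, σ)`, and a
matched toy clock reads the effective age back exactly in the noise-free
limit.

## Worked example

Simulate a cohort with a +3-year offset injected into PDN and −2 years into
CTRL (PLDN is the reference), then run the full analysis:

```bash
cat > sim.yaml <<'YAML'
n_per_group: {PDN: 40, PLDN: 50, CTRL: 35}
acceleration: {PDN: 3.0, PLDN: 0.0, CTRL: -2.0}
n_cpgs: 50
YAML
methaging simulate --config sim.yaml --out cohort --seed 11

cat > run.yaml <<'YAML'
beta_path: cohort/beta.tsv
detp_path: cohort/detection_p.tsv
sheet_path: cohort/samples.csv
clock_paths: [cohort/toy_clock.csv]
reference_group: PLDN
contrasts: [[PDN, PLDN], [CTRL, PLDN]]
YAML
methaging run --config run.yaml --out results
```

which prints:

```
2 contrasts tested; 2 significant at alpha=0.05
  toy_clock: PDN vs PLDN diff=+2.958 t=4.789 df=88 p=6.745e-06
  toy_clock: CTRL vs PLDN diff=-2.427 t=-4.142 df=83 p=8.247e-05
outputs in results
```

The recovered mean residual differences (+2.96 y for PDN, −2.43 y for CTRL)
estimate the injected offsets (+3 / −2); the PLDN mean residual is 0 by
construction since PLDN anchors the reference fit. `results/contrasts.csv`
holds the full rows (n, group means, t, df, p, significance flag);
`results/manifest.json` records the config hash and library versions needed
to reproduce the run byte-for-byte.

The same steps are available as library calls (`generate_cohort`,
`apply_linear_clock`, `remove_outliers`, `build_residual_table`,
`run_contrasts`) and as CLI subcommands `simulate`, `qc`, `biomarkers`,
`compare`, `run`, `report`.

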