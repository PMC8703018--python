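# Methods

This note documents the models, numerical choices and limitations behind
`smcvd`, in the order the pipeline runs them.

## Risk scoring

The 10-year CVD risk is the Cox-derived survival form
`p̂ = 1 − S₀^exp(L)` with linear predictor
`L = Σ βᵢ·gᵢ(xᵢ) − Σ βᵢ·x̄ᵢ`, where `gᵢ` is the natural log for factors
flagged `log` and the identity otherwise, and binary factors contribute
their coefficient when set. Scores are percent; `stratify` maps them onto
the partition LR = [0, 10), MR = [10, 20], HR = (20, ∞). MR is closed on
both ends so the three printed rules tile the half-line with no gap at
exactly 10 or 20.

Coefficients are configuration, not code. A `RiskModel` YAML holds per-sex
blocks `{s0, mean_sum, terms: [{name, factor, beta, mean, log, when}]}`:

* `when: bp_treated` / `when: "!bp_treated"` gates a term on a flag, which
  is how the treated/untreated systolic-BP split is expressed; an inactive
  term contributes nothing to either sum.
* `mean_sum` is the aggregate Σβᵢx̄ᵢ. The published general-CVD function
  reports only this aggregate (26.1931 for women, 23.9802 for men), so the
  default config uses it; per-term `mean` values are supported for toy
  models and custom calibrations.
* The default function's lipid coefficients were estimated on mg/dL values
  while clinical tables here carry mmol/L (the scale of the cohort
  tables this pipeline expects); the factor names `total_chol_mgdl` /
  `hdl_mgdl` apply the ×38.67 conversion internally.

The default coefficients are shipped for convenience and plausibility, not
as a recalibration to any particular population; all correctness tests run
on toy coefficient sets.

## Synthetic cohorts

`generate_cohort` emulates the data structure the analysis assumes, not any
particular real cohort.

* **Strata.** Each subject draws a target stratum from `strata_fractions`
  (default 84% / 11% / 5% low/moderate/high risk). Clinical covariates come
  from stratum-conditional distributions (age 35/51/57 ± 10/7/8 y;
  total cholesterol 4.9/5.4/5.4 mmol/L; HDL 1.43/1.19/1.12 mmol/L; SBP
  118/132/142 mmHg; smoking, diabetes and BP-treatment rates rising with
  stratum) and are rejection-resampled — up to 50 rounds — until the
  computed risk score lands in the target stratum. This keeps realised
  baseline fractions within a couple of points of the target for any
  requested mix; a subject still unresolved after 50 rounds keeps its last
  draw.
* **Counts.** Compositions are Dirichlet with a geometrically decaying
  concentration vector (total precision 30, ratio 0.85), giving a few
  dominant genera and a long tail; counts are multinomial at a library
  size uniform on `library_size_range` (default 2 000–10 000 reads).
  Lineages are Greengenes-style 7-rank strings over a pool of plausible
  oral genera.
* **Planted effects.** Binary-mechanism taxa have their per-subject
  presence probability set by a logistic function (slope 1.5) of the
  baseline log score, signed to match the effect, and add
  `effect × 1[count > 0]` to the log score. Continuous-mechanism taxa draw
  their proportion from a Beta with the Dirichlet marginal's mean but one
  tenth of its precision, and add `effect × arcsin√(relative abundance)`.
  The extra overdispersion encodes the assumption that taxa whose abundance
  tracks host phenotype vary far more between subjects than the neutral
  compositional background — under the neutral marginal the arcsin
  predictor has ≈0.09 sd, too narrow for any plausible coefficient to be
  identifiable against the cohort's baseline clinical variance (≈1.2 sd on
  the log-score scale).
* **Outcome.** `log score = ln(baseline risk) + Σ planted effects +
  N(0, noise_sd)`; the score is `exp(·)` clipped to (0, 100] with a 1e-6
  floor so the log outcome stays finite. Defaults: three planted taxa with
  effects (+0.8, −0.8) on the binary mechanism and +1.5 on the continuous
  one, `noise_sd = 0.3`.

What the generator does **not** emulate: real compositional correlation
structure between taxa, sequencing batch effects, zero-inflation beyond the
multinomial, or any specific population's covariate marginals. Passing
recovery tests therefore demonstrates that the machinery detects planted
signal under clean compositional noise — not that it would have equal power
on real data.

## Transforms

Binary is `1[count > 0]`; Arcsin is `arcsin√p` on relative abundance (the
variance-stabilising transform for proportions — the square-root variant is
used, as the plain arcsine of a proportion does not stabilise variance).
The outcome uses the natural log with a configurable floor `ε = 1e-6`
applied before the log so zero scores stay finite.

## Penalized regression

The solver minimises `(1/2n)‖y − β₀ − Xβ‖² + Σⱼ P(βⱼ; λ)` by cyclic
coordinate descent. Predictors are standardised internally to mean 0 /
population sd 1 (so each coordinate update is the exact univariate
minimiser), coefficients are returned on the original scale, and the
intercept is unpenalised. Univariate updates: soft threshold (lasso),
`S(z, λα)/(1 + λ(1−α))` (elastic net, mixing α = 0.5 by default since
α = 1 would duplicate the lasso), the three-regime SCAD rule (a = 3.7) and
the firm MCP rule (γ = 3.0) — the canonical shape defaults. Binary designs
are standardised like continuous ones (a positive rescaling cannot change
coefficient signs); this is a config-visible choice, not a claim about what
any other analysis did.

Numerics: convergence when the largest coefficient change in a sweep is
< 1e-7, capped at 10 000 sweeps; zero-variance features are excluded with
their coefficient pinned at 0; selection means |standardised coefficient|
> 1e-8. Cross-validation uses a 100-point log-spaced λ path from λmax
(the smallest λ with an all-zero solution; divided by α for the elastic
net) down to 0.001·λmax, seeded-shuffle folds, and picks the CV-minimum λ
(largest λ wins exact ties; no 1-SE rule). Nonconvex fits warm-start along
the decreasing path, which stabilises which local minimum is reached. Two
mathematically equivalent kernels exist: a residual-updating one (used for
single fits, and the one that tracks the per-sweep objective) and a
covariance-updating one on `(X'X/n, X'y/n)` used for CV paths, where each
sweep is O(p²) instead of O(np).

## Stability selection

Fifty seeded 80/20 splits; the identical partition is reused for every
method and transform within a split, so per-split MSE differences between
transforms are paired and a Wilcoxon signed-rank test applies. Per-split CV
folds are reseeded from that split's seed, making the report independent of
the order in which methods are run. Split seeds derive from a single master
seed via `SeedSequence`, so parallel or serial execution gives identical
results. A feature that is all-zero in a training portion is simply not
selected in that split (the denominator stays 50). "Pertinent" means
frequency ≥ 0.8 in **all** requested methods for a transform; a pooled mode
(mean frequency over methods ≥ threshold) is available behind a flag.
Direction calls take the majority over nonzero sign counts; exact ties
(including never-selected) are "mixed".

## Diversity statistics

All computed on raw counts (no rarefaction by default — a seeded
subsample-to-minimum-depth option exists on the roadmap but is
deliberately off, since the modelled libraries are uniform by
construction). Chao1 uses the bias-corrected form
`S + F₁(F₁−1)/(2(F₂+1))`, which never divides by zero; the classical
`S + F₁²/(2F₂)` form is available by flag and falls back to the
bias-corrected numerator when F₂ = 0. ANOSIM ranks the off-diagonal
distances with midranks and uses Clarke's statistic
`R = (r̄_between − r̄_within)/(n(n−1)/4)`, which is bounded in [−1, 1]; the
p-value uses the add-one convention `(1 + #{R* ≥ R})/(1 + n_perm)`, with an
exhaustive enumeration mode for small designs. Mann–Whitney uses midranks,
exact enumeration of all assignments when n₁ + n₂ ≤ 12, and otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction; two identical constant samples give p = 1.

## Pipeline and reproducibility

`run_pipeline` validates its config before any computation (paths exist,
threshold in (0, 1], known ranks/methods/transforms), then runs score →
stratify → collapse → transform → stability-select → diversity, writing
every table plus a `summary.json` that contains no timestamps — reruns with
the same config and master seed are byte-identical. Timestamps live only in
`run.log`. On any stage failure the partial outputs are kept next to a
`FAILED` marker file. Taxonomy collapse sums rows sharing the lineage
prefix through the chosen rank (default genus, since the markers of
interest are genus-level, with one family label handled by the optional
best-rank mode) and pools unnamed labels into one "unclassified" row, so
per-sample totals are conserved.

## Problem sizes

The bundled demo uses 240 subjects × 40 genera × 25 splits; the recovery
and null-control checks and `scripts/acceptance.py` use 400 subjects × 50
genera × 50 splits, the scale at which the planted-effect recovery
properties are calibrated. Larger cohorts work unchanged; runtime is
dominated by the CV paths and grows roughly linearly in splits × methods ×
transforms and in p² per sweep.

## Known limitations

* The sign and recovery guarantees are calibrated on the generator's clean
  Dirichlet-multinomial world; correlated taxa can share or split selection
  frequency in ways the tests do not probe.
* The nonconvex objectives are only guaranteed to reach a stationary point;
  the warm-started path makes the reached minimum reproducible, not global.
* The default risk coefficients are not recalibrated to any cohort, and
  competing-risk or time-varying extensions are out of scope.
* BIOM-format input is not supported; the reader takes the classic
  tab-separated taxa-by-samples layout with a lineage column.
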