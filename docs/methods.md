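# Methods

This note documents the statistical models, the synthetic-data generators
that stand in for screen data, the numerical choices, and the limits of
what the test suite demonstrates.

## Trajectory model and nested testing

Replicate-level climbing speed is modelled per genotype pair on a shared
tray (within-tray analysis avoids between-batch confounding). Technical
trials are first averaged within each (genotype, replicate, age) — the
biological replicate is the unit of analysis.

Three nested fixed-effect structures are fitted by least squares:

1. `speed ~ genotype` — a pure level shift;
2. `speed ~ genotype + S(age)` — adds a shared non-linear age trend;
3. `speed ~ genotype + S(age) + genotype:S(age)` — genotype-specific
   trend shapes.

`S(age)` is a cubic B-spline basis (Cox–de Boor, open knot vector) with 3
interior knots at empirical age quantiles by default; the basis forms a
partition of unity, so its first column is dropped against the intercept.
With *d* distinct ages the degree and knot count adapt downward so the
design stays full rank; with fewer than 3 distinct ages, models (ii)/(iii)
are disabled and selection falls back to (i).

Focal tests are term-wise sequential (Type-I) F statistics: the genotype
sum of squares in models (i) and (ii) (each against its own residual mean
square) and the interaction block in (iii). The reported result for a pair
is the most complex model whose focal p ≤ α, with α = 5×10⁻⁵ as the
screen-wide threshold. The alternative reading of the three p-values —
sequential model-vs-model comparisons — gives identical genotype tests on
balanced panels (genotype is orthogonal to age there) and is not
separately implemented.

**Engines.** The default engine is OLS on replicate-level records. Because
the same vial of flies is tracked across ages, replicate intercepts induce
within-replicate correlation that OLS ignores; its genotype main-effect
tests are therefore anti-conservative whenever the replicate-intercept
variance is non-zero (the interaction test is unaffected, since intercepts
cancel from within-replicate contrasts). The `random_intercept` engine
adds a per-replicate random intercept fitted by profiled maximum
likelihood — the fixed effects and residual variance are profiled out
analytically, leaving a bounded 1-D search over the variance ratio
λ = σ_b²/σ_ε² (block structure makes each evaluation a closed-form
whitening); focal tests are likelihood-ratio χ². Its log-likelihood matches
`statsmodels` MixedLM (ML) to ~1e-6 on test fixtures. A per-*replicate*
(not per-genotype) intercept is used: a genotype-level intercept would be
confounded with the genotype fixed effect and leaves the repeated-measures
correlation unmodelled.

Screen-level recovery experiments in this package are analysed with the
random-intercept engine because the generator includes replicate
intercepts; the OLS engine's type-I calibration is demonstrated on
flat-trajectory null data, which matches its independence assumption. On a
*trending* null, model (i)'s focal test is conservative (the shared age
trend inflates its residual), which is inherent to a genotype-only model
and not a defect.

## Modifier calling

Per allele, two contrasts: modifier+αSyn vs αSyn (`p_enh`, reported-model
p-value) and modifier alone vs driver-only control (`p_alone`). Direction
is the sign of the unweighted mean difference of the model (iii) fitted
curves over the observed-age grid (enhancer = slower). Standalone severity:
`no_mild` if `p_alone` > α; otherwise `severe` if the standalone curve
falls below the αSyn curve at ≥2 consecutive grid ages (a single-point dip
is noise-prone; `any` and `terminal` rules are available), else
`moderate`. A contrast with zero residual variation (e.g. literally
duplicated records) is flagged degenerate and called non-significant
rather than fitted.

Gene calls require ≥2 significant alleles of equal direction
("consistent evidence"); opposite-direction significances never combine.
Class is `synergistic` if any supporting allele is `no_mild`, `additive`
if all supporting alleles are `moderate`/`severe`. Suppressors are
supported throughout even though enhancer-only screens exist; the
consistency rule squares the per-allele false-positive rate, so false
modifier genes are rare even at moderate per-contrast error.

## Synthetic trajectory generator

Mean speed: `μ_g(t) = s0 − k_age·t − β_tox·u(t) − [αSyn]·(1+β_int)·Δ(t)`,
with `u(t)` a unit logistic ramp (midpoint day 12, scale 3 d),
`Δ(t) = A·u(t)` the αSyn deficit, `A = 4` speed units on a baseline
`s0 = 10` with aging slope `k_age = 0.1`/day. `β_tox` is a standalone
deficit amplitude (additive toxicity); `β_int` scales the αSyn deficit
multiplicatively when co-expressed (synergy). Noise: a persistent
per-replicate intercept (σ_b = 0.25) plus independent per-trial residuals
(σ_ε = 0.5); speeds truncate at zero. Defaults: 8 biological replicates of
15 flies, 5 technical trials, 11 ages at days 1, 3, 6, …, 30. The speed
unit is configuration metadata (assay units are rig-specific).

These parameter choices reproduce the qualitative curve families of real
screens — controls decline slowly, αSyn flies sigmoidally, enhancers
faster still — with replicate scatter small relative to the αSyn deficit,
as in a well-powered assay of 15-fly vial means. What the generator does
*not* emulate: fly-level kinematics, tray-position effects beyond the tray
label, age-dependent variance, or dropout of dead flies; recovery results
on it therefore demonstrate the statistical machinery, not robustness to
those real-data features.

## Proteomics

Preprocessing drops proteins with any missing value and sums rows sharing
a FlyBase id. Size factors are median-of-ratios against the per-protein
geometric-mean reference (zero-containing proteins excluded from the
reference).

**Cross-sectional (NB-Wald) path.** Reporter intensities are rounded to
integers and modelled per protein by a negative-binomial GLM (log link,
intercept + genotype, log size factors as offsets). Dispersion: per-protein
maximum likelihood with a Cox–Reid adjustment (−½ log det X′WX), then
moderation toward a log-linear mean–dispersion trend by a weighted
geometric average (weight 0.5 by default). The Wald statistic is referred
to a t distribution with residual df; with 8v8 designs the asymptotic
normal reference is visibly anti-conservative in the far tail that BH
thresholds probe (observed FDR up to ~0.25 without the correction, ≤0.09
with it). Applying a count model to TMT intensities follows screen
practice; a Gaussian path (t-tests on normalized abundance) is provided
for users who prefer not to. The moderation here is a deliberate
simplification of full empirical-Bayes MAP shrinkage, so discovery counts
need not exactly match those of DESeq2; unshrunken effect sizes agree with
it closely (r > 0.99 on test fixtures). Effect-size (lfc) shrinkage is
display-only and out of scope.

**Longitudinal (LRT) path.** Gaussian linear models on
log2(normalized + 1) abundance: `expression ~ genotype + age` vs
`expression ~ age`, 2Δℓ against χ²₁, BH adjustment; the genotype
coefficient (log2 units) is the reported effect. Constant or noiseless
rows return statistic 0, p = 1.

The proteome generator draws NB counts with mean
`exp(β0 + ln2·log2FC·[asyn] + slope·(age − mean age))`, per-protein
dispersion, and base abundances spanning 2⁷–2¹³ — emulating summed
reporter-ion scales, not spectral processing, batch/channel structure, or
missingness mechanisms (missingness is exercised by explicit fixtures).

## Vacuole quantification

Vacuoles are segmented as pixels above a threshold (Otsu within the tissue
mask by default; fixed thresholds for calibrated rigs), hole-filled, and
labelled with 8-connectivity. A region qualifies when its equivalent
circular diameter 2√(area/π) exceeds 4 µm strictly (max-Feret diameter
available by flag; the measurement convention behind the 4 µm rule is
unstated in screen protocols, so both are exposed). The fraction is the
qualifying area sum over the tissue area (mask area, or full frame).
Boundary-touching vacuoles are included. Pixel-center rasterization keeps
disk areas within 2% of πr² for radii ≳10 px; accuracy claims are
validated on synthetic disks only — real H&E sections need a tissue mask
and stain-robust thresholding that automatic Otsu on synthetic images does
not exercise. Group comparison: unpaired t statistics with Monte-Carlo
Dunnett adjustment (below), requiring ≥3 sections per genotype by default.

## Shared statistics

- **BH**: step-up with capping, original order preserved (statsmodels
  backend; validated against a brute-force step-up oracle).
- **Dunnett**: two-sided many-to-one comparisons; adjusted p-values are
  tail probabilities of max|T| under the joint multivariate-t with
  correlation ρ_ij = √(n_i/(n_i+n₀))·√(n_j/(n_j+n₀)), evaluated by seeded
  Monte Carlo (default 10⁵ draws; ±0.005 agreement with quadrature at
  10⁶). Monte Carlo was chosen over numerical quadrature for simplicity
  and seedability; adjusted values are floored at the raw p.
- **2^−ΔΔCt**: technical replicates averaged on the Ct (cycle) scale —
  standard practice — then ΔCt against the mean of the reference genes and
  ΔΔCt against the calibrator sample.
- **Standard curves**: piecewise-linear interpolation between standards
  (monotone-cubic available), dilution factor applied afterward, and no
  extrapolation outside the standards — out-of-range readings raise.

## Problem sizes and determinism

Calibration and recovery experiments run at desk scale: 1,000 null
contrasts for type-I error (α scaled to 0.05 so the rate is estimable),
200 simulations for detection power, a 20-gene screen (5 synergistic +
5 additive + 10 null, 2 alleles each) for recovery, 500 proteins for the
NB-Wald operating characteristics, and 6 synthetic sections for vacuole
accuracy. All generators take mandatory seeds and never touch global RNG
state; identical configurations reproduce byte-identical outputs. Output
tables carry a provenance comment (tool version, config hash).

## Known limitations

- OLS genotype tests on replicate-correlated data are anti-conservative;
  use the random-intercept engine when σ_b > 0 matters.
- The NB dispersion moderation is trend-shrinkage, not full MAP; exact
  parity with DESeq2 discovery counts is not guaranteed.
- The likelihood-ratio focal tests are asymptotic; with very few
  replicates their small-sample behavior is untested.
- Automatic vacuole segmentation is validated only on synthetic disks;
  real histology requires masks and threshold review.
- Homolog maps are consumed as static tables; ortholog prediction is out
  of scope.
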