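# Methods

This document records the generative model, the quality-control (QC)
rules and their operating characteristics, the estimators, and the
numerical choices behind `growthgwas`. Ages are always the 12-point grid
birth, 6 w, 3 m, 6 m, 8 m, 1 y, 1.5 y, 2 y, 3 y, 5 y, 7 y, 8 y
(indices 0–11); "before two" means indices 0–6 and "at/after two"
indices 7–11.

## 1. Synthetic-cohort generator

### Clean growth curves

For child *c* of sex *s*, measure *m* ∈ {height, weight} and age *i*:

```
log x_i = log median[s, 0] + u_c + C_i + eps_i
C_i     = Σ_{k<i} dlogm[s, k] · (1 + tanh(g_k))
```

- `median[s, ·]` are fixed per-sex median tables (height in metres,
  weight in kilograms) and `dlogm` their consecutive log increments.
- `u_c ~ N(0, re_sd²)` is a per-child size intercept
  (defaults 0.035 for height, 0.12 for weight on the log scale).
- `g` is a per-child AR(1) *tempo* process (lag-1 correlation 0.9,
  marginal sd 1.0 for height and 0.7 for weight), mean-centred within
  each child. The tempo factor `1 + tanh(g)` was chosen deliberately:
  it is strictly positive, so clean height curves are strictly
  increasing (heights never decrease without injected errors), and it
  is point-symmetric around 1 under the symmetric law of `g`, so the
  population median at every age sits exactly on the median table —
  an earlier multiplicative `exp(g)` factor was right-skewed and
  shifted medians upward by several percent. The tanh also compresses
  amplitude, so the tempo sds above are calibrated jointly with it.
- `eps_i ~ N(0, noise_sd²)` is measurement noise (0.008 height, 0.02
  weight).

Cells go missing independently with probability 0.10; 5.5 % of children
are preterm (gestation below 259 days, drawn from a shifted
distribution). Seeds fully determine every draw.

Calibration targets (verified at n = 5,000 over multiple seeds during
design, before any thresholds were frozen): under defaults, full growth
QC excludes < 0.5 % of observed cells; under a stress configuration
(noise 0.02 on both measures plus 1 % injected spikes/gaps of ≥ 30 %)
clean-cell removal stays ≤ 1 % while ≥ 90 % of injected spikes/gaps are
caught.

### Error injection

`inject_errors` corrupts a clean cohort and returns a truth log (child,
age, measure, kind, original value): unit errors (height recorded in cm,
weight in g), isolated multiplicative spikes (×1.4) and gaps (×1/1.4),
and spurious height decreases. All rates and magnitudes are
configurable; the truth log enables exact sensitivity/specificity
accounting.

### Genotypes and effects

Hard genotypes are Binomial(2, EAF); dosages add clipped Gaussian noise
whose sd controls the recorded info score (observed dosage variance over
2p̂(1−p̂)). Info is monotone decreasing in the noise sd over the
pipeline's operating range [0, 0.3]; beyond ~0.35 the [0, 2] clipping
bends it back up, which is why noise draws are capped at 0.3. Causal
variants carry an age-profiled effect (a Gaussian bump over log-age,
e.g. peak 0.162 sd-BMI per allele at 6 m for the infancy profile) added
to the standardized phenotype via the dosage.

## 2. Growth QC

Applied in order, twice (two passes with the reference panel rebuilt
between passes); cell status codes distinguish observed, imputed,
missing, and each exclusion rule.

1. **Preterm exclusion** — children with gestation < 259 days are
   dropped entirely.
2. **Unit harmonization** — values outside the plausible ranges
   (0.2–2.5 m, 0.2–120 kg) are divided by 100 (height) or 1000
   (weight) when that lands them inside; otherwise excluded as
   implausible. Non-positive values are excluded.
3. **Extreme outliers** — per sex × age cell (minimum 20 children),
   bounds are median ± Φ⁻¹(0.99)-scaled robust spread from the 1st/99th
   percentiles; values outside are excluded.
4. **Curve rules** — per child, consecutive log₂ ratios are scaled
   robustly against the panel's per-interval ratio quantiles
   (value 0 at the median, ±1 at the 1st/99th percentile anchors).
   A *peak* is a scaled up-ratio > 1 followed by a down-ratio < −1
   (a *gap* the mirror image); the shared age is excluded. Endpoints
   are never flagged by this rule.
5. **Height decreases** — for an observed decrease h_{i+1} < h_i with
   ≥ 3 other observed heights, both values are compared against ratio
   interpolations from every other age: a value above (below) all
   interpolations is excluded; otherwise both values are moved
   geometrically (factor 0.9 per move, larger-residual value first)
   toward their interpolation targets until non-decreasing, with an
   iteration cap (cap hit ⇒ both excluded). Because targets derive
   from strictly increasing height medians they are strictly ordered,
   which guarantees termination; with *exactly* equal targets the
   iteration can stall one float ulp on each side of the target and
   fall back to the cap — unreachable in practice and safe (both
   excluded) if it ever occurred. With < 3 anchors a quantile-bound
   test is used, and unresolvable pairs are recorded.
6. **Imputation** — missing cells are imputed as the median of ratio
   interpolations from the child's other observed values, for children
   with ≥ 3 observations before two and ≥ 2 after (before-two ages only
   when just the first criterion holds), and only where ≥ 2 non-imputed
   observations exist both earlier and later. Imputed values are
   flagged and never serve as anchors.

**Metric conventions.** "Removed" counts cells whose *final* status is
excluded — a cell flagged and then repaired (unit fix) or replaced
(imputation) is not removed. "Caught" for an injected error means the
corrupted value is no longer present: excluded, missing, or changed.

**Idempotence scope.** The empirical-quantile rules are scale-free: on a
noisy cohort each rebuild of the panel re-flags a fresh tail (~4 % of
cells per extra pass), so iterating to a fixed point is not meaningful
there and the pass count is fixed at two. On deterministic (noise-free)
cohorts a third pass is a verified state-level no-op.

### BMI and standardization

BMI = weight / height² wherever both cells survive (provenance records
whether either was imputed). Standardization is per sex × age with the
same robust scaling: 0 at the median, ±1 at the 1st/99th percentile
anchors — chosen over z-scores for robustness to residual outliers, and
making the acceptance-checked anchor properties exact.

## 3. Association

- **Marker/sample QC**: variant call rate ≥ 0.98, exact Hardy–Weinberg
  p > 10⁻⁶, then sample call rate ≥ 0.98 and heterozygosity within
  4 sd of the sample mean.
- **Exact HWE**: the conditional-on-allele-counts exact test, computed
  in log space with a max-subtraction for stability; probability ties
  within a 1 + 10⁻¹² factor are included in the tail. It agrees with a
  full rational-arithmetic enumeration to < 10⁻¹² relative error for
  every configuration with n ≤ 200 (≈ 692 k configurations).
- **Per-age OLS**: sd-BMI on dosage plus sex, batch dummies and PCs;
  complete cases per age; t-reference p-values by default. Estimates
  match the statsmodels oracle to 10⁻¹⁰ relative. Null calibration:
  empirical type-I error 0.051 at nominal 0.05 over 24,000 null tests;
  standard errors match the analytic 1/√(2np(1−p)) within 0.2 % on
  average in the known-effect recovery experiment.
- **Forwarding**: any variant with p < 10⁻⁷ at any age is forwarded
  (replication in the motivating design); conditional analysis adds the
  forwarded dosages as covariates.
- **Trajectories**: per-genotype, per-sex medians (single variant) or
  means with standard errors (two-variant strata) across all ages.

## 4. Meta-analysis and polygenic scores

- **Fixed-effect inverse-variance pooling**: weights 1/se², pooled
  se = (Σ 1/se²)^{-1/2}, normal p. Applied to the packaged two-cohort
  lead-SNP table it reproduces the published pooled columns to one unit
  in the last printed decimal (betas and ses to ≤ 10⁻³); pooled
  p-values are compared within a factor of two because the inputs are
  only printed to three decimals and p is hypersensitive to that
  rounding.
- **Polygenic scores**: dosages hard-called (boundaries 0.5/1.5,
  ties away from the heterozygote by default), variants matched by id
  with allele-flip handling (effect allele equal to the other allele ⇒
  count 2 − call), info ≤ 0.7 dropped, missing calls contribute 0.
  With the true simulated weights the score's r² with sd-BMI equals the
  realized heritable fraction var(score)/var(phenotype) within Monte
  Carlo error (0.0367 vs 0.0368 at n = 20,000 in the seed-1 acceptance
  run).

## 5. Reproducibility and numerics

- Every stage derives its seed from the master seed via SHA-256 (mod
  2³¹), so stages are independently reseedable and the whole pipeline
  is bit-reproducible (identical SHA-256 manifests across runs).
- Delimited outputs are re-read with round-trip float parsing, so
  cohort tables round-trip bit-exactly; VCF text carries ~6 significant
  digits (~10⁻⁵ relative round-trip).
- Ratio interpolation works in log space; unusable intervals are
  zeroed *before* the cumulative sum so a missing interval only blocks
  paths that actually cross it.
- Robust scaling divides by the anchor-to-median distance on the side
  of the value; degenerate (zero-width) anchors yield ±inf scaled
  values, which the callers treat as unusable.

## 6. Limitations

- The generator is a calibration instrument, not a demographic model:
  no secular trends, no twins/siblings, no correlation between
  missingness and health, preterm growth is not modelled beyond the
  gestation flag.
- Tempo deviations are stationary AR(1); real growth has puberty- and
  adiposity-rebound-specific dynamics that the 12-point grid only
  sketches.
- QC thresholds (quantile anchors, ±1 scaled-ratio flags, 259-day
  preterm cut) were frozen from the design-phase calibration runs;
  they are appropriate for the simulated error model and would need
  re-validation on real registry data.
- The two QC passes are a pragmatic fixed point for noisy data (see
  idempotence scope above); exact idempotence holds only on
  deterministic cohorts.
- Fixed-effect meta-analysis assumes homogeneous true effects across
  the two cohorts; no heterogeneity statistic is computed because the
  packaged table has only two studies.
- Polygenic scoring matches variants by id only (no position/allele
  harmonization across builds) and ignores linkage disequilibrium,
  which is absent in the simulated genotypes.
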