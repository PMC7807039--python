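# Methods

## Model

The classifier variable (serum PSA in the motivating case) is strictly
positive and right-skewed; after a natural-log transform it is modelled as
Gaussian within each class. The population density of `x = ln(value)` is
then the binormal superposition

```
y(x) = a (1-pr)/σ₁ φ((x-μ₁)/σ₁) + a pr/σ₂ φ((x-μ₂)/σ₂)
```

with the negative class at (μ₁, σ₁), the positive class at (μ₂, σ₂), the
positive-class prior (prevalence) `pr`, and a free scale `a`. `a` converts
a probability density into relative-frequency bin heights; for a histogram
with bin width `h`, a well-normalized fit lands near `a ≈ h`, but `a` is
estimated freely rather than imposed. This is a genuine two-component
superposition at every point, not the two-half-Gaussian "binormal" variant
sometimes used for ROC modelling.

Biological assumptions behind the stratified analysis: normal prostate
tissue is a homogeneous cell population whose PSA output rises with age, so
μ₁ drifts upward across age bands; malignant tissue is genotypically
heterogeneous with an age-invariant PSA distribution, so (μ₂, σ₂) is shared
across bands. Only the two-component case is fit; the data model notes the
general n-component form but nothing else uses it.

## Histogram construction

- Plausibility filter on the raw scale first (defaults 0.1–100, in the
  variable's original units), then the log transform. Exclusions are
  counted and logged.
- Freedman–Diaconis bin width `h = 2·IQR/n^{1/3}` with the IQR computed by
  linear interpolation of order statistics (quantile type 7 — the
  convention is fixed so the rule is reproducible).
- `n_bin = ceil((max−min)/h)`, bins anchored at the sample minimum, no
  "nice number" rounding. Interior bins are half-open `[left, right)`; the
  last bin is closed so the maximum is never lost. When the range is an
  exact multiple of `h` this means the maximum folds into the final bin.
- Zero IQR is an error, not a fallback: the decomposition is meaningless on
  near-constant data.

## Fitting

Unweighted least squares of the model curve evaluated at bin centers
against the relative frequencies, minimized with bounded
Levenberg–Marquardt (lmfit). Constraints: `a ≥ 0`, `0 ≤ pr ≤ 1`, and both
sigmas ≥ 1e−6 (a small floor that turns non-negativity into numerically
safe positivity). Starting values come from rel-freq-weighted quantiles of
the bin centers (μ₁ at the 25th, μ₂ at the 90th, both sigmas at the
weighted SD, pr = 0.3, a = h). If the first run fails or lands on a bound,
five deterministically seeded jittered restarts are attempted and the
lowest residual sum of squares wins, ties broken toward smaller `pr`.
Because the superposition is invariant under swapping the components along
with `pr ↔ 1−pr`, free fits are relabelled so the negative component has
the smaller mean. Histograms with fewer than 8 bins are rejected
(insufficient resolution for up to six parameters).

Goodness of fit is reported as `r² = 1 − SS_res/SS_tot` with `SS_tot` about
the mean bin height — the convention of the R nonlinear-fitting ecosystem;
no canonical r² exists for a nonlinear model.

**Two-pass strategy.** The free six-parameter fit is well conditioned only
where both components carry comparable weight. The pipeline therefore fits
the anchor stratum (default: age ≥ 65, where the prevalence approaches one
half) with all six parameters free, then refits every other stratum with
(μ₂, σ₂) frozen to the anchor estimate — a four-parameter model whose
per-stratum `pr` is the prevalence estimate for that band. Whether `a`
should be re-estimated per stratum is not dictated by the model; it is
re-estimated here, since bin widths differ across strata. Freezing the
positive component can only increase the residual sum of squares relative
to the free fit on the same histogram (nested models), which is tested.

Identifiability caveat: with realistic overlap (component means ~1.5 pooled
SDs apart) the least-squares surface has a shallow ridge trading `pr`
against (μ₂, σ₂). Single-fit estimates of the positive component therefore
scatter widely (SD of the fitted μ₂ ≈ 0.17 at n = 20,000 in the anchor
regime) even though the estimator is nearly unbiased; recovery claims in
the tests are about the mean over seeded replicates, not about any single
fit. This is intrinsic to histogram least squares, not an optimizer
artefact: fitted solutions reach lower residuals than the generating
parameters themselves.

## Indices

All closed-form, evaluated on the log scale and exponentiated only at the
reporting boundary:

- `Se(t) = 1 − Φ((t−μ₂)/σ₂)`, `Sp(t) = Φ((t−μ₁)/σ₁)`.
- ROC: 512 thresholds spanning μ₁−6σ₁ … μ₂+6σ₂; the trapezoid AUC appends
  exact (0,0) and (1,1) endpoints. Closed form
  `AUC = Φ((μ₂−μ₁)/√(σ₁²+σ₂²))`; both routes agree to ~1e−3 at the default
  grid. For the worked 54–59 PSA components both give 0.876, slightly above
  the 0.874 conventionally quoted for that example (which traces to a
  coarser discrete cut-off series and parameter rounding); both are
  reported, and the closed form is used in `IndexReport`.
- Optimal cut-off: Youden mode solves the density-crossing condition
  `f₂(t) = f₁(t)`; cost mode solves `LR(t) = (1−pr)/(C·pr)`, the
  first-order condition of minimizing the expected misclassification cost
  `C·pr·(1−Se) + (1−pr)·(1−Sp)` with `C = cost(FN)/cost(FP)`. With
  `C = (1−pr)/pr` the two coincide. Equating log-densities gives a
  quadratic in `t`; the root inside (μ₁, μ₂) is returned, with a bracketed
  bisection fallback when root selection is ambiguous, and an error when no
  admissible cut-off exists between the means.
- Likelihood ratios: `LR⁺ = Se/(1−Sp)`, `LR⁻ = (1−Se)/Sp`; interval LR
  `−(Se(t₁)−Se(t₂))/(Sp(t₁)−Sp(t₂))` (equal to the ratio of class masses in
  the interval); point LR `f₂(x)/f₁(x)` computed in log space so deep tails
  do not underflow.
- Reference range `exp(μ₁ ± 1.96σ₁)` and 95th percentile `exp(μ₁ + 1.645σ₁)`
  of the negative class, in original units.
- PPV/NPV via Bayes at the fitted prevalence; a generic Bayes-posterior
  helper covers arbitrary evidence (e.g. "value below 4"), rejecting
  incoherent inputs whose posterior would exceed 1.

Proportions are carried at full precision; any rounding (e.g. percent with
one decimal) happens in the caller's report.

## Synthetic cohorts

The generator emulates the assumed population structure: six age bands
(20–39 … 80+), band-wise constant negative-class mean rising with age,
shared positive component, band-specific prevalence, Bernoulli labels, and
log-normal values truncated to the plausibility window by resampling
(keeping n exact at the cost of a slight tail perturbation relative to the
untruncated model). Default band prevalences (0.03, 0.08, 0.165, 0.406,
0.545, 0.50) and negative means (−0.55 … 0.25) follow the fitted PSA age
profile where one is reported and are otherwise illustrative
interpolations; the 50–59 band matches the worked example exactly
(pr = 0.165–0.198, μ₁ = −0.124, σ₁ = 0.643), and the positive component is
(1.033, 0.766) throughout. Everything is deterministic under a fixed seed.

What passing tests on these cohorts do **not** show: robustness to assay
measurement error, inter-laboratory calibration drift, non-Gaussian
within-class shape, or age trends inside a band — none of which the
generator simulates.

The hidden labels make each cohort its own gold standard:
`empirical_indices` computes contingency-table Se/Sp/PPV/NPV at any
cut-off, the oracle against which the label-free estimates are validated
(they agree to Monte-Carlo precision at n = 10⁵).

## Problem sizes and tolerances in the test suite

Recovery checks use cohorts of n = 20,000 per stratum and 10–20 seeded
replicates (seeds derived via `numpy.random.SeedSequence.spawn`), enough to
pin the mean recovery error of `pr`, μ₁, σ₁ below 0.02 and of μ₂, σ₂ below
0.05 while keeping the whole suite under a few seconds. Monte-Carlo
comparisons use 10⁵–10⁶ draws with 3-standard-error bands. CDF assertions
are made at 1e−10 against erf-based oracles; mixture normalization at
relative 1e−8 by quadrature. CLI outputs are byte-identical across reruns
with the same seed; strata with fewer than 200 samples (configurable) are
skipped rather than fitted, since Freedman–Diaconis binning plus a
six-parameter fit is unstable below that.

## Known limitations

- The decomposition presumes exactly two log-Gaussian classes; it cannot
  detect misspecification beyond a poor r².
- Estimates of the positive component from a single stratum are noisy under
  realistic overlap (see the identifiability caveat); downstream indices
  inherit that uncertainty, and no confidence intervals are provided.
- The anchor assumption (age-invariant positive component, anchor
  prevalence near 0.5) is a modelling choice, not something the data can
  verify from a histogram alone.
- Inconclusive-zone handling (two-graph ROC) and empirical label-based ROC
  analysis are out of scope.
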