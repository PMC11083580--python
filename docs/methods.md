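# Methods

## Model and assumptions

`radrepeat` treats each (transformed) lesion-level feature measurement as
one draw from a three-level Gaussian hierarchy: repeats about the true
lesion value (`sigma_r`), lesion values about the patient value (`sigma_p`),
patient values about the population value (`sigma_0`), plus an additive bias
`eps` on the second repeat.  All three SDs are population-wide.  The model
assumes additive homoscedastic noise on the modelling scale — which is why
features are variance-stabilised first (log for most, `1−x` or `1−x` then
log for normalised co-occurrence features, identity for sign-changing ones
such as skewness) — exchangeable lesions within a patient, and no
repeat-by-lesion interaction beyond `eps`.

Standardisation uses the baseline-1 convention: both repeats are centred on
the mean and scaled by the SD (unbiased) of the first repeat only, so the
second repeat retains any bias signal; the constants are stored and draws
are mapped back afterwards.  `eps` and the SDs are rescaled without the mean
shift, since they are differences/scales.

## Sampling

Posterior draws come from a blocked Gibbs sampler.  Location conditionals
(`mu_ij`, `mu_i`, `mu_0`, `eps`) are Gaussian; each half-Cauchy prior on an
SD is represented as the inverse-gamma scale mixture
`sigma² | a ~ IG(1/2, 1/a)`, `a ~ IG(1/2, 1/scale²)`, making the variance
updates conjugate inverse-gamma as well.  The sampler is exact for the
stated joint density (no tuning, no divergences), deterministic given a
seed, and costs O(total lesions) per sweep — a full 3-chain default fit of
80 lesions takes ~0.2 s.

Defaults follow the study configuration this pipeline is designed around:
3 chains, 2000 iterations per chain of which 500 are warmup (4500 retained
draws), no thinning, half-Cauchy scale 5, prior SD 10 for `mu_0` and `eps`.
`n_samples` is read as the per-chain total including warmup;
`samples_include_warmup=False` selects the other reading.  Initial values
are the closed-form moment quantities (lesion pair means; RMS of half the
pair differences for `sigma_r`; within/between decompositions for `sigma_p`,
`sigma_0`); chains beyond the first (and every chain on a retry) are
deterministically jittered so the between-chain diagnostic is informative.
A validation step checks all initial values fall inside the central 99.9 %
prior mass, i.e. that the priors genuinely cover the data range.  When every
patient has exactly one lesion the `sigma_p` initialisation is undefined and
`sigma_r`'s value is substituted (any positive start is admissible); zero
initial SDs are floored at 1e-3 for the first sweep only.

Convergence uses the classic Gelman–Rubin R̂ on full post-warmup chains
(pooled-variance over mean within-chain variance), applied to **all**
sampled parameters (5 globals + per-patient + per-lesion means); a run
passes when ≥ 99 % of parameters have R̂ ≤ 1.02, and otherwise is repeated
with fresh seeds — a pure function of (master seed, attempt) — up to 10
times before a hard failure with diagnostics.  A split-chain rank-normalised
R̂ (via arviz) is available behind `rhat_method="rank"`.

## Derived statistics

Every statistic (RC, both ICCs, the three CVs, LoA, `eps`) is computed per
posterior draw and then summarised by median, IQR and central 95 % interval,
propagating the joint posterior rather than plugging in point estimates; the
`mu_ij`/`mu_i` values inside the CVs come from the same draw as the SDs.
The 1.96 multiplier is kept literal rather than the exact normal quantile.
Limits of agreement are only defined for features on a log scale; for
identity-scale features they are reported as not applicable (never silently
computed).  A zero mean draw makes a CV undefined: the feature is flagged
and its CVs withheld.  Bias is "significant" when the central 95 % interval
for `eps` excludes 0.

## Feature front-end

Lesion eligibility implements the target-lesion rule: volume ≥ 1 mL, mean
fat fraction < 20 %, and mean ADC < 1400×10⁻⁶ mm²/s unless the lesion shows
unequivocal (≥ 30 %) interval change.  Discretisation is fixed-bin-width
(`floor((x − anchor)/width) + 1`) with the anchor at 0, since ADC and
fat-fraction maps are inherently normalised and non-negative; widths are
100×10⁻⁶ mm²/s for ADC and exactly 100/30 % for fat fraction (the rounded
form 3.333 % would open a sliver 31st bin at the top of the range), giving
exactly 30 grey levels over the nominal ranges.

The default registry holds 106 features: 19 first-order, 14 shape, 22 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM.  (Class-wise counts elsewhere can sum
to 105 depending on which first-order variant set is enabled; this registry
follows the 106 total with 19 first-order features.)  Transforms: identity
for skewness, minimum, GLCM correlation and cluster shade (sign-changing),
and for IMC1 (typically ≤ 0); `1−x` for IDN/IDMN; `1−x` then log for IMC2
(range [0,1)); log for everything else.  Only first-order features are
computed natively, using IBSI conventions — population moments, Pearson
(non-excess) kurtosis, entropy/uniformity on the discretised grey levels.
Texture and shape mathematics are deliberately out of scope: they enter
through a pluggable extractor protocol that must declare its matrix
aggregation mode (3D vs per-slice), because published texture values depend
on it.  The in-repo `ReferenceFirstOrderExtractor` is an independent
scipy-based first-order implementation used to cross-validate the native
path (agreement to 1e-6 relative); it is not a texture extractor.

## Synthetic cohorts

The generator draws exactly the hierarchy the model assumes, with ragged
per-patient lesion counts (real designs have "up to ~10" lesions per
patient), optional log-normal output, and per-patient seed substreams so
extending a cohort never perturbs existing patients.  Default bias is 0
(test–retest protocols of this kind typically show none).  The reference
simulation conditions used throughout the tests — 10 patients × 8 lesions,
`(sigma_r, sigma_p, sigma_0) = (0.1, 0.3, 0.5)` on a mean of 2 — mirror a
~10-patient whole-body-MRI repeatability study with moderate biological
heterogeneity and small measurement error (generating ICCδ = 0.90,
ICCΔ ≈ 0.96).  The voxel-level lesion generator produces quasi-spherical
masks with an exact voxel count for a requested volume and log-normal
in-mask intensities with optional Gaussian-smoothed texture.

What the synthetic data do **not** emulate: scanner noise physics, partial
volume and segmentation variability, spatial correlation between lesions,
non-Gaussian tails, or heteroscedasticity beyond what the log transform
removes.  Passing tests therefore demonstrate correctness of the estimator
chain under its own assumptions, not robustness to real-world violations of
them.

## Verification strategy

Two independent routes to the variance components are kept separate: the
Gibbs-sampled posterior and a closed-form method-of-moments estimator
(within-pair RMS for `sigma_r`; within/between mean-square decompositions
with harmonic-mean lesion count on unbalanced designs; negative components
truncated to 0 and flagged).  On a 40-patient × 10-lesion balanced design
their `sigma` estimates agree within a few percent, which is the principal
model-correctness gate.  Recovery of a between-patient SD from only 10
patients is intrinsically noisy (sampling SD ≈ 24 % of the true value — the
moment estimator misses a ±30 % band in the same replicates the posterior
median does), so replicate-level recovery checks at that size are expected
to fail occasionally per replicate regardless of estimator quality.

## Redundancy grouping and reporting

Pairwise feature distance is `1 − ρ²` (Spearman) across lesions pooled over
patients, computed on the mean of the two repeats; anticorrelation counts as
redundancy and rank correlation makes monotone transforms immaterial (so the
choice of repeat handling and scale is inconsequential by construction —
both were genuinely open choices).  Average-linkage agglomerative clustering
is cut at cophenetic distance 0.51 (configurable; linkage was an open choice
and is exposed).  Constant features are flagged out of clustering.  Each
group's representative is its maximum-median-ICCδ member, ties broken
lexicographically.

Bland–Altman tables report pair means and differences on the transformed
scale with ±RC limits; for log-scale features the limits are additionally
expressed as percentage bounds via the LoA back-transformation (the
established treatment for proportional-error data).  The ICC overview sorts
features waterfall-style and flags those whose posterior-median ICC reaches
a chosen reference metric; an interval-overlap variant is offered because
ICC posteriors (especially inter-patient) can be wide.  Reports are
byte-deterministic given the seed; plots are optional artifacts.

## Known limitations

- Texture/shape feature values require an external IBSI-conformant
  extractor; only first-order is native.
- The moment estimator loses efficiency on strongly unbalanced designs.
- Per-patient `sigma_p`, REML fitting, frequentist ICC intervals, and
  posterior-predictive checking are out of scope.
- `eps` destandardisation assumes a pure additive bias (scale-only
  inversion).
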