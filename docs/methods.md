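# Methods

## The radiative model and its inverse

Over optically shallow water, the at-sensor radiance of band *i* is modelled
as

    L_i = Ls_i + a_i · r_i · exp(−f · k_i · z)

where `Ls_i` is the deep-water radiance (atmosphere + surface glint, the
signal that remains when no bottom is visible), `a_i` a dimensionless
surface/atmosphere constant, `r_i` the bottom reflectance in [0, 1], `k_i`
the diffuse attenuation coefficient (m⁻¹), `z` the depth (m) and `f` a
geometric path-length factor, 2 for a two-flow (down-and-up) model. The
synthetic generator uses exactly this forward model; the analysis inverts
it only up to quantities that matter for classification:

* `Ls_i` is estimated from the image itself (dark-pixel subtraction), so
  after correction `ln(L_i − Ls_i) = ln(a_i r_i) − f k_i z` is linear in
  depth with slope `−f k_i`.
* Over calibration pixels of a single bottom type spanning a depth range,
  the second moments of two log-corrected bands give
  `a = (σ_ii − σ_jj) / (2 σ_ij)` and `k_i/k_j = a + √(a²+1)`. With one
  bottom type and no noise, `σ_ii = (f k_i)² Var(z)`,
  `σ_ij = f² k_i k_j Var(z)`, so the estimator returns the true ratio to
  machine precision — this exactness is a test invariant.
* The depth-invariant index
  `DII_ij = ln(L_i − Ls_i) − (k_i/k_j) ln(L_j − Ls_j)` removes the depth
  term; per bottom type it is constant in a noiseless scene (variance
  ≤ 10⁻¹⁸ is asserted in tests). Absolute `k_i` values are never needed.

All three pairs of the three visible bands are used as features
(blue–green, blue–red, green–red); the sample (n−1) convention is used for
variances and covariances.

## Numerical safeguards

**Non-positive residuals.** Pixels with `L − Ls ≤ ε` (ε = 10⁻⁶ radiance
units) after subtraction carry no usable bottom signal; they are flagged
invalid and excluded from all log-domain work rather than clipped, because
clipping fabricates extreme DII values.

**Detection limit.** A strongly attenuated band — red above all, with
`f·k ≈ 0.7 m⁻¹` — loses its bottom signal into the sensor noise within a
few metres of water. Log-transforming such pixels produces values dominated
by noise; left in place they corrupt both the moment-based ratio estimate
and the feature maps. Each band therefore has a per-scene detection limit:
when a deep-water region is available, 3× the sensor-noise standard
deviation estimated from that region (zero for a noiseless scene);
otherwise 2 % of the band's bright (95th-percentile) calibration signal.
Corrected radiance below the limit makes the pixel invalid for every DII
layer using that band. The practical consequence is physically correct:
red-pair layers cover only the depth range the red band penetrates, and the
fully valid feature stack is the optically shallow zone. Classification,
ground-truth sampling and change analysis all operate there, which is what
"shallow benthic area" means in the reports.

**Deep-water estimation.** Two strategies: `"region"` averages over a
supplied deep-water polygon and is unbiased (error ~ noise_sd/√n, asserted
within 3 σ/√n); `"darkest"` averages the darkest p % (default 1 %) of water
pixels and needs no polygon, at the cost of an order-statistic bias of a
couple of noise standard deviations. The orchestration layer defaults to
`"region"` because simulated sites always carry a deep strip; the
module-level default for standalone use without a polygon remains
`"darkest"`. At least 30 supporting pixels are required either way.

**Water mask.** Default NIR land/water threshold comes from Otsu's method
on the NIR histogram (water absorbs NIR almost completely); an explicit
threshold overrides it, and a constant NIR band is rejected rather than
guessed at.

## Classification choices

* Ground-truth rows (percent cover of Sand, Rock, Mud, Rubble, Coral,
  Seagrass, Seaweed summing to 100) are binarized by a plurality rule —
  coral iff Coral's percentage is ≥ every other category's, ties to coral —
  with a percent-threshold rule available in configuration.
* Class balance by stratified undersampling of the majority class,
  deterministic under the run seed.
* RBF-kernel SVM; default tuning grid γ ∈ {2⁻⁷…2³}, C ∈ {2⁻³…2⁷} (log-2
  spaced), 5-fold stratified CV maximizing mean accuracy, ties broken
  toward smaller C then smaller γ so the least flexible of the best models
  wins. Survey-sized evaluation sets can be a few dozen points, so the fold
  count caps at the minority-class count (never below 2). Features are
  z-scored with training-set statistics stored on the model — nothing from
  a test site ever enters standardization or tuning.
* Posterior probabilities come from the fitted SVM's probability
  calibration; the class map thresholds them at 0.5 by default, ties to
  coral; invalid pixels carry nodata through every product.

## Evaluation and change accounting

Coral is the positive class. Precision, recall, specificity, accuracy,
F-measure and Cohen's kappa are computed from the confusion counts;
metrics with empty denominators are reported as explicit `undefined`
markers, never silent zeros. Kappa uses marginal-based expected agreement;
with balanced truth classes it reduces to `2·accuracy − 1`, an identity the
survey-scale worked examples rely on. ROC curves sweep the unique score
values; AUC is trapezoidal and equals the Mann–Whitney pairwise-win
probability (asserted against brute force in tests). Reported metrics are
rounded to 4 decimals.

Change analysis intersects both epochs' valid masks, tabulates the four
transitions (coral→coral, coral→non, non→coral, non→non; everything else
invalid), converts counts to km² via `count · pixel_size² / 10⁶` (reported
to 2 decimals), and reports percent change `(initial − final)/initial · 100`
and the coral share of valid shallow pixels to 1 decimal. Raw counts are
always retained alongside the rounded figures.

## What the synthetic scenes emulate — and what they do not

The generator reproduces the statistical structure the method assumes:
exponential attenuation with band-dependent rates, distinct per-class
bottom reflectances, a smoothed random depth field on [0.5, 12] m, a
contiguous deep strip (z = 45 m) for dark-pixel subtraction, NIR-bright
land, cloud patches flagged in a bit-flag quality band, additive Gaussian
sensor noise (default 0.5 % of the brightest shallow signal), and an
exactly bookkept coral→non-coral conversion between epochs
(`round(fraction × coral pixels)`, deterministic per seed). Bottom patches
come from a seeded nearest-centroid tessellation.

Not emulated: directional sun-glint geometry (glint is folded into `Ls`),
adjacency effects, tides, sensor MTF, mixed pixels, spatially correlated
noise, and within-class reflectance gradients. Passing tests therefore
demonstrate the correctness of the algorithms under the stated model, not
the accuracy attainable on real Landsat products, where radiometric
calibration, atmosphere and benthic complexity dominate the error budget.

## The reference three-site study

`three_site_study()` fixes the conditions used by the multi-seed
experiments: 128×160-pixel scenes at 30 m; site A is the baseline; site B
has 30 % higher attenuation everywhere (turbid water), +3 radiance units on
every deep-water constant (different atmosphere) and 10 % multiplicative
bottom-reflectance jitter (between-reef benthic variation); site C has 20 %
lower attenuation and its own 10 % jitter. 400 survey points per site are
drawn in the optically shallow zone, clamping to the available pool when a
turbid site offers fewer. The tuning grid is trimmed to γ ∈ {2⁻⁵…2²},
C ∈ {2⁻¹…2⁵} for these replicated runs. Under these conditions the
A-trained model keeps a median balanced accuracy well above 0.70 on site B
with a measurable drop from its within-site accuracy, pooling A+B is not
worse than A alone on held-out C (median over 10 seeds), and a programmed
10 % coral loss is recovered within 2 percentage points (exactly, in the
noiseless configuration).

## Reproducibility

Every stochastic step derives its seed deterministically from the run seed
and the site name (SHA-256 based, below 2³¹), so a fixed configuration
reproduces bit-identical reports; each report carries a provenance block
with the configuration hash, seed and package version.

## Known limitations

* Real GeoTIFF georeferencing is carried as plain metadata (geotransform in
  the TIFF description tag), not as CRS-aware geodesy; co-registration of
  real scenes is out of scope.
* Radiometric calibration of real Landsat products (DN → radiance) is not
  implemented; inputs are assumed to be in consistent radiance-like units.
* The pipeline is binary (coral vs non-coral); multi-class benthic mapping
  and texture features are out of scope.
* Attenuation ratios are re-estimated per scene; no cross-epoch sharing of
  calibration is attempted.
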