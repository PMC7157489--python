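# Methods

This note documents the estimators, the modelling chain, the
synthetic-data generators, and the numerical conventions behind them —
including the choices that were genuinely open and why they were made.

## Preprocessing

Images are cropped to the largest central square (odd margins lose the
extra pixel on the trailing side), resized to a fixed square side
(default 1024) with a Catmull-Rom-class bicubic kernel (Pillow's
`BICUBIC`, anti-aliased when downsampling), and converted from sRGB to
CIELAB under the D65 white point (scikit-image `rgb2lab`).  Statistics
are computed on the L, a and b planes of this standard representation,
so they are unaffected by the original pixel dimensions or aspect
ratio.  Images already square are not cropped, and images smaller than
the target are upsampled.  No ICC colour management is attempted; pixel
values are taken as sRGB.

The exact bicubic kernel differs slightly across implementations
(Pillow, Matlab `imresize`, OpenCV); the estimator tolerances below
absorb kernel-level differences, and no test depends on exact resized
pixel values.

## Spectral slope (SL)

The plane mean is subtracted, the 2-D FFT amplitude spectrum is
computed without a window function, amplitudes are averaged within
integer radial-frequency bins r = 1 … side/2 − 1 (cycles/image), and
an ordinary least-squares line is fit to log10 amplitude versus
log10 r over r ∈ [2, side/4].  The fitted slope is SL.

* *Fit range.* The DC-adjacent bin (r = 1) and the octave below
  Nyquist are excluded: both are dominated by discretization and
  binning artifacts rather than the spectral law.  The range is a
  config parameter (`spectral_fit_range`).
* *No window.* Synthetic validation images are circularly periodic,
  so leakage is absent there; on natural images leakage mostly
  perturbs the excluded extreme bins.
* *Degenerate input.* A constant plane has zero amplitude at every
  non-DC frequency; SL is undefined and reported as a flagged missing
  value (NaN), which downstream analyses drop pairwise (correlations)
  or listwise (PLSR).

Calibration: on spectral-synthesis images whose radial amplitude is
exactly f^β, the estimator recovers β with mean absolute error below
0.01 across β ∈ [−2, 0] at size 512 (the tested guarantee is < 0.05).

## Fractal dimension (FD)

Image content is treated as a surface in the (x, y, intensity) volume.
Intensities are affinely rescaled so the occurring range spans
[0, side], making the volume a cube.  For each box side s in a dyadic
ladder, the plane is partitioned into s×s spatial cells; a cell whose
intensity range is δ occupies ⌈δ/s⌉ boxes, and a cell with zero range
occupies none.  FD is the least-squares slope of log N(s) versus
log(1/s), clamped to the theoretical range [0, 3] (clamping beyond
numerical noise is logged).

* *Zero-count convention.* A cell of zero intensity range contributes
  zero boxes, so a uniform field gives N(s) = 0 at every scale and
  FD = 0 by definition.  The more common "+1 per cell" floor would
  assign a flat field dimension 2, which contradicts the 0–3
  convention this analysis uses.
* *Ladder endpoints.* The default ladder runs from side/16 up to
  side/2 (e.g. 32, 64, 128, 256 at side 512).  Scales below side/16
  are excluded because band-limited (interpolated) images are
  effectively smooth there: cell ranges then reflect the local
  gradient rather than fractal structure and drag the fitted slope
  toward the smooth-surface regime.  The ladder is exposed as a
  config parameter (`box_sizes`) since estimates at fixed resolution
  depend on it.
* *Known bias.* Range-based box counting at finite resolution
  underestimates the dimension of very rough surfaces: the expected
  cell range converges to its asymptotic c·s^H law only slowly.
  Measured on 512-sided fractional-Brownian surfaces (10 seeds), the
  estimator recovers the theoretical dimension 3 − H with errors of
  about −0.14 (H = 0.2), −0.05 (H = 0.5) and +0.08 (H = 0.8) — within
  the ±0.15 band the tests assert, and strictly monotone in H.  For
  near-smooth surfaces (H → 1) the estimate approaches 2 from above
  (≈ 2.20 at H = 0.999).
* Uniform i.i.d. noise saturates every cell and yields FD = 3.0
  exactly at side 512; a constant field yields 0 exactly.

## Entropy (EN)

The plane is quantized to 256 levels by affinely mapping a *fixed
reference range* onto bins 0…255 (values outside are clipped), and EN
is the Shannon entropy −Σ p_k log2 p_k of the bin histogram, in bits.
Reference ranges are per plane type: [0, 100] for L and [−128, 127]
for a and b, so entropies are comparable across images.  The
alternative — per-image min–max binning — would make EN invariant to
contrast and incomparable across a collection.  A constant plane
scores exactly 0; i.i.d. uniform 8-bit noise scores 8 − O(10⁻⁴) at
1024² samples (the plug-in estimator's small-sample deficit).

## Correlations and FDR

Pearson correlations between ratings and each statistic are reported
as Cd = 100·r² with two-sided p-values; pairs with flagged statistics
are dropped pairwise.  Significance is screened with the
Benjamini–Hochberg step-up procedure at q = 0.05.  The FDR family is,
by default, the full genre × statistic grid computed in one run
("table" family); a per-genre family is available via config, since
either reading of "adjusted for multiple tests" is defensible.

## PLSR, component selection and VIP

Ratings are regressed on the z-scored (mean 0, sd 1 with ddof = 1)
nine-statistic matrix with partial least squares regression
(scikit-learn's `PLSRegression`, no internal rescaling).  For a
univariate response, the NIPALS algorithm used there coincides with
SIMPLS (de Jong 1993): scores, weights and fitted values agree, so the
convention question that matters for multi-response PLS does not arise
here.  Two invariants pin the implementation down: with all nine
components on full-rank predictors, the fit equals the OLS R² to
1e−6; and fitted Cd is non-decreasing in the component count.

The component count is the smallest k whose in-sample Cd reaches 85%
of the asymptotic value, defined as the Cd at k_max = min(n − 1, 9).
This elbow rule avoids over-fitting without cross-validation.

VIP scores use the standard formula

    VIP_j = sqrt( p · Σ_k SS_k (w_jk/‖w_k‖)² / Σ_k SS_k ),

with p the number of predictors, w_k the k-th predictor-weight vector
and SS_k the rating variance explained by component k.  The mean of
the squared scores is exactly 1 by construction (asserted to 1e−10),
and predictors with VIP > 1.25 are flagged as model-relevant — a
threshold appropriate for selecting a small subset from highly
collinear predictors.

*Limitation.* With a single component, VIP reduces to a monotone
function of the predictor–rating correlations, so collinear inactive
predictors can tie with genuinely active ones; reliable separation of
actives needs as many components as active directions.  The recovery
battery therefore fixes the model order at the true signal rank
(k = 3 for 3 active predictors); at the asymptote-selected k the
top-3 recovery rate drops from 90% to ≈ 84% on the same datasets.

Degenerate predictor columns (all-missing, or zero variance — e.g.
chroma entropy of a greyscale collection) are excluded from the PLSR
fit with a logged warning; `zscore_predictors` itself refuses
zero-variance columns.  The minimum genre size for a PLSR fit is 10
records (configurable): real genre subsets can be as small as ~14,
and the floor only guards clearly degenerate fits.

## Genre comparisons

One-factor fixed-effects ANOVA per statistic (luminance-plane
statistics by default; the colour planes via config), Tukey HSD over
all unordered genre pairs at family level 0.05 (28 pairs for eight
genres), and per-genre boxplot summaries with linear-interpolation
quartiles and 1.5×IQR whiskers.  Tukey HSD is the conventional choice
after a significant omnibus F; the quartile convention is recorded
because whisker and outlier sets depend on it.

## Synthetic data: what it emulates, what it does not

* `gen_powerlaw_image(beta, size, seed)` sets the FFT amplitude at
  radial frequency r to exactly r^β with random (Hermitian) phases,
  so the rotationally averaged amplitude slope equals β by
  construction — the oracle for SL.
* `gen_fbm_surface(hurst, size, seed)` synthesizes a
  fractional-Brownian surface with power-spectrum exponent
  −(2H + 2).  The power at each lattice frequency is the continuum
  law summed over spectral replicas (alias folding, 3 replicas per
  axis), as in a point-sampled continuum field; plain truncation at
  Nyquist leaves the surface too smooth at small lags (lag-1
  structure-function exponent ≈ 0.48 instead of 0.2 at H = 0.2),
  which corrupts box-counting validation.  Theoretical dimension:
  3 − H.
* `gen_entropy_image(target, size, seed)` draws pixels i.i.d. from a
  256-symbol mixture (uniform over 2^⌈target⌉ symbols against a point
  mass) whose mixing weight is solved numerically so the distribution
  entropy equals the target to 1e−6 bits.
* `gen_rating_dataset(n, weights, noise_sd, seed)` draws the nine
  statistic columns from a two-latent-factor model — one factor loads
  on the SL block, one on the FD+EN block, within-block correlation
  0.5 — echoing the empirical collinearity of the statistic families,
  then forms ratings = z(X)·weights + N(0, noise_sd), affinely mapped
  into [0, 100] (affine maps leave correlations and PLSR fits
  unchanged).  `noise_sd_for_r2` computes the noise level for a
  target population R² from the factor covariance.
* `gen_genre_dataset` adds per-genre mean shifts and per-genre rating
  weights; `simulate_genre_images` writes actual sRGB PNG textures
  whose lightness spectral exponent varies by genre (abstracts
  distinctly shallower, mirroring the qualitative pattern in real
  collections) and whose ratings follow the exponent.

All generators are bit-reproducible under a fixed seed.  The
generators emulate the *statistical* structure of artwork collections
— power-law spectra, fractal roughness, histogram entropy, collinear
statistic families, genre shifts — and nothing semantic: no faces,
scenes or composition.  Passing tests therefore demonstrate that the
estimators and the modelling chain are correct and calibrated on
fields with known ground truth, not that any particular statistic
explains ratings of real paintings.

## Problem sizes and determinism

Validation batteries run at sizes chosen to keep the full suite fast
while leaving the estimators in their calibrated regime: slope
recovery at 512 (20 seeds × 5 exponents), fractal recovery at 512
(10 seeds × 3 Hurst values), entropy at 1024, the null-ANOVA
calibration at 8 genres × 50 records × 100 seeds, and the end-to-end
determinism check on 200 synthetic images at side 256.  The pipeline
itself contains no randomness: given the same config and inputs the
report CSVs are byte-identical across runs (fixed float formatting,
fixed line terminators).  All randomness in the synthetic module flows
through explicit integer seeds.
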