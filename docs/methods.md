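# Methods

## The measurement model

A laser-induced-fluorescence hyperspectral acquisition is a rows × cols ×
bands cube of detector counts. The band axis is a uniform, endpoint-inclusive
wavelength grid; the package's convention is 128 bands spanning 400–1000 nm,
giving a spacing of 600/127 ≈ 4.7244 nm. This is the only uniform grid
consistent with a 17-of-128 split below a 480 nm cutoff, which downstream
stages depend on; camera datasheet figures quoting ≈5.1 nm resolution are
recorded as metadata but never used in computation.

Raw counts mix the fluorescence signal with instrument terms. The two-point
radiometric model assumes a gain/offset relation per pixel and band:
`R_f = (R_o − R_D)/(R_B − R_D)` with a white reference `R_B` (diffuse
reflectance panel under the measurement illumination) and a dark reference
`R_D` (capped lens). The correction is exactly invariant under any affine
rescaling of the detector (a property test pins this). Bands where
`|R_B − R_D|` falls below `1e-6 · max(R_B)` carry no radiometric
information; they are set to 0 and counted in the cube metadata rather than
propagated as infinities.

## Spectral preprocessing

Five steps run in a fixed order per pixel spectrum; the order is part of the
contract (a regression test asserts a scrambled order gives different
output):

1. **Laser-band removal** (`cutoff_nm = 480`, half-open: the 480 nm band is
   kept). Bands below the cutoff are dominated by excitation scatter, not
   emission. On the 128-band grid this removes 17 bands and retains 111.
2. **Baseline subtraction** (`percentile = 10`). The 10th-percentile
   intensity of each spectrum — linear-interpolation definition, position
   `q(p−1)` between order statistics, stated so tests can be exact — is
   subtracted from all of that spectrum's bands. A scalar per spectrum:
   this removes additive background (dark drift, broadband
   autofluorescence) while leaving peak shapes untouched.
3. **Negative clipping.** Fluorescence is non-negative; overcorrection
   artifacts are clamped at zero.
4. **Area normalization.** Each spectrum is divided by its trapezoid
   integral over the (possibly truncated) grid, removing multiplicative
   intensity variation (surface roughness, illumination, concentration
   scale) and retaining spectral shape. Rows then integrate to exactly 1; a
   zero-integral row is a degenerate spectrum and raises an error naming
   the row. A flat spectrum on the 480–1000 nm grid normalizes to
   1/520 ≈ 1.92×10⁻³ per nm.
5. **Savitzky–Golay smoothing** (order 3, window 11). Interior points use
   the standard convolution weights; edges are filled by evaluating the
   polynomial fitted to the terminal window (`scipy` mode `interp`), not by
   mirror padding — this preserves peak shape next to the 480 nm cut. The
   filter reproduces cubics to machine precision and perturbs the unit
   integral only through edge effects (< 1 % on peaked phantom spectra).

The decibel transform `20·log10(x)` (amplitude convention) is provided for
display and export only; inputs ≤ 1e-6 map to a −120 dB floor so exports
stay finite. It is not part of the classification path: the pipeline's
training features are the area-normalized, smoothed spectra.

## Sparse PCA with an adaptive relative threshold

The package's core is a sparse principal component estimator designed for
fluorescence spectra, where diagnostic information is confined to a few
narrow bands but components differ in variance by orders of magnitude.

Given the n × p matrix of preprocessed spectra, columns are centered and
scaled to unit variance (`scale=False` gives center-only fitting; the
standardization is stored on the model so new spectra project
consistently). Zero-variance columns keep scale 1 and thus stay zero. For
each of k components:

- power step: `z = Xᵀ(X v_old)`;
- adaptive threshold: `τ = λ·max|z|`, recomputed every iteration from the
  current proxy vector;
- shrink and renormalize: `v_new = S(z, τ)/‖S(z, τ)‖₂`, with
  `S(z, τ) = sign(z)·max(|z| − τ, 0)`.

Convergence is declared when `min(‖v_new − v_old‖, ‖v_new + v_old‖) < 1e-6`
(the sign ambiguity of a direction estimate is quotiented out), with a cap
of 500 iterations and per-component convergence flags on the model. After
each component the matrix is deflated by Hotelling's rule
`X ← X − (Xv)vᵀ`, which maps the extracted direction exactly to zero
(`‖X_next v‖ = 0` algebraically; a test bounds it at 1e-9·‖X‖).

Numerical choices:

- **Initialization** is the leading right singular vector of the current
  (deflated) matrix — deterministic, so fits are bit-reproducible without
  an RNG.
- **Sign convention**: each returned loading has its largest-magnitude
  entry positive.
- **λ ≥ 1 fallback**: there `τ ≥ max|z|` and the shrinkage annihilates
  every coefficient; the estimator keeps the single largest-|z| coefficient
  and warns instead of aborting, so grid scans over wide λ ranges stay
  total.
- **Explained variance** is the variance (ddof = 1) of each training score
  column `Xv`. Sparse components are not orthogonal, so these values do not
  partition total variance and are documented as non-additive.
- At `λ = 0` the iteration is plain power iteration; an oracle test checks
  the loadings against an independent eigendecomposition (|cosine| >
  1 − 1e-6) on dozens of random matrices. The dense-PCA baseline
  (`fit_standard_pca`) is computed by exact eigendecomposition and recorded
  with λ = 0.

Hyperparameter scans mirror standard practice: `select_k` scans k over
1–12 with 5-fold stratified cross-validation (sparse PCA and SVM refit
inside each training fold — the held-out spectra never touch the loadings)
and picks the smallest k within one standard error of the best mean
accuracy, the usual operationalization of an accuracy plateau;
`scan_lambda` scans the grid {0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 2}
and picks the *largest* λ within one standard error of the best — maximal
sparsity at no accuracy cost. Refitting inside folds is deliberate: fitting
the feature extractor once on all labeled spectra would leak held-out
information into the CV estimate.

## Classification

A soft-margin RBF SVM (box constraint `C = 1`) on the component scores.
Features are standardized; the "auto" kernel scale σ is resolved as the
median pairwise Euclidean distance among the standardized training points,
computed deterministically on the full training set (subsample-based
heuristics vary between environments; the median heuristic is the
reproducible standard). The RBF is `exp(−‖a−b‖²/(2σ²))`; the quadratic
program is solved by scikit-learn's SVC. Decisions are hard labels from the
sign of the decision function — the application needs maps, not calibrated
probabilities. Class coding is 0 = clean, 1 = contaminated everywhere.

Whole-cube classification flattens the cube, runs calibration →
preprocessing → projection → prediction per pixel, and reshapes; a test
asserts the map equals row-wise prediction on the flattened cube. Pixels
whose preprocessed spectrum has zero integral (dead pixels; or noiseless
flat spectra that baseline subtraction zeroes exactly) cannot be
area-normalized and are assigned the clean class rather than crashing the
map.

## Ground truth and evaluation

The positive class is "contaminated" throughout. Ground-truth hygiene
mirrors pixel-wise segmentation practice: the contaminated region is eroded
by a 3 × 3 square structuring element (radius 1, 8-connectivity; the image
border counts as background), and eroded-away pixels become *unlabeled*
(255) — they are ambiguous mixed pixels, not clean. Balanced subsets are
drawn uniformly without replacement per class, reproducibly under a seed.

Metrics are the four standard ratios from TP/TN/FP/FN over labeled pixels.
A zero-denominator precision or recall is reported as a flagged null, never
silently coerced to 0 or 1, so cross-validation summaries are not biased by
degenerate folds. Export formatting is accuracy in percent to 2 decimals
and precision/recall/F1 to 4 decimals. Class fractions are computed over
labeled pixels by default, with an `include_unlabeled` mode exposing the
full-raster denominator. Error maps color TP blue, TN green, FP yellow,
FN red, unlabeled black; a test asserts the color histogram equals the
confusion counts.

## The phantom generator

The generator renders the study conditions the pipeline is designed for:

| parameter | default | meaning |
|---|---|---|
| `clean_baseline_range` | 200–400 counts | flat clean-salt background level, drawn uniformly per pixel |
| `laser_center_nm` / `laser_fwhm_nm` / `laser_amplitude` | 450 nm / 12 nm / 1500 counts | residual excitation line (removed by preprocessing) |
| `main_peak` | 500 nm, FWHM 40 nm, 4100 counts | dominant emission band; maximum inside 480–520 nm |
| `secondary_peaks` | 575/50/350, 750/60/300, 990/20/250 | weaker emission and photoproduct-absorption analogue bands (≈6–9 % of the main amplitude) |
| `concentration_scale` | 1.0 | linear amplitude scaling; ≈0.5 emulates the near-detection-limit regime for stress tests |
| `amplitude_jitter` | 0.25 | per-pixel, per-peak truncated-normal amplitude multiplier `max(0, 1 + 0.25·N(0,1))` |
| `contamination_fraction` | 0.578 | target contaminated-pixel fraction of the truth mask |
| `correlation_length_px` | 10 | Gaussian smoothing width of the random field that clusters contamination |
| `noise_sd` | 20 counts | additive Gaussian sensor noise |
| `dark_level` | 50 counts | dark-current offset (also the dark frame's level) |
| `white_level` / `white_nonuniformity` | 10 000 counts / 2 % | spectrally flat white frame with a smooth spatial gain field |

Peaks are Gaussians parameterized by FWHM — the simplest family matching
the band locations involved. Amplitudes are linear in concentration. The
amplitude jitter is the generator's heterogeneity mechanism: residue
concentration and photochemical aging vary across a surface, which gives
each emission band an independent variance factor. That independence is
what makes the deflated components band-localized: component 1 captures the
broad clean-vs-contaminated contrast, components 2–4 each lock onto one
jittering band. Without jitter, all spectral variation would be collinear
with the class contrast and sparse components would have nothing separate
to find. The contamination mask is a thresholded smoothed Gaussian random
field, thresholded at the empirical quantile so the realized fraction hits
the target to within a pixel. All randomness flows from one seed through
`numpy.random.SeedSequence.spawn`, so scenes are bit-reproducible. The
draw order inside the spectrum generator (baseline, noise, jitter) is
fixed so that a zero-concentration spectrum is bit-identical to a clean
one under the same stream.

What the phantom does *not* emulate — and hence what passing tests do not
show about instrument data: radiative transfer and TiO₂ scattering in a
granular crystalline matrix, spatially correlated (non-i.i.d.) sensor
noise, wavelength-dependent white-reference structure, specular glints,
focus/keystone distortions, and annotation error in the ground truth.
Phantom class separation at default settings is strong; real acquisitions
sit closer to the decision boundary, and accuracies measured on phantoms
are upper bounds, not forecasts.

## Problem sizes and regimes

Default test and acceptance scenes are 200 × 200 × 128 (40 000 pixels), the
canonical training design is 900 + 900 spectra, and cross-validation is
tenfold stratified — sizes chosen so the full stack (including CV with
refit-per-fold) completes in seconds while keeping every class count large
enough for stable stratification.

On the sparse-vs-dense comparison: at moderate noise (up to ~5× the default
`noise_sd`) both feature sets saturate near-perfect map accuracy on
phantoms and their ordering is decided by single pixels; the regime where
band selection demonstrably matters is severe noise (~20× default), where
dense loadings integrate noise into every score and sparse features hold a
consistent accuracy margin. The comparison tests check non-inferiority in
the first regime and strict superiority in the second.

## Known limitations

- The ENVI I/O supports the minimal dialect the pipeline needs
  (little-endian, float32/uint16, BSQ/BIL/BIP read, BSQ write) — not
  vendor-native formats or georeferencing.
- `select_k`'s one-standard-error rule degenerates when fold accuracies
  have zero variance (it then returns the smallest candidate k that ties
  the best); on strongly separated data most k tie at 100 %.
- The erosion radius is interpreted as a square structuring element;
  a disc would differ at radius ≥ 2.
- Whether the white panel should be averaged spatially before calibration
  is acquisition-dependent; both per-pixel frames and broadcast single
  spectra are supported, and the choice is the caller's.
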