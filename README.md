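# lifhsi

Pixel-wise mapping of organic contaminants (sunscreen UV filters) on
crystalline food matrices — sea salt in particular — from laser-induced
fluorescence (LIF) hyperspectral images.

Residues of UV filters such as ethylhexyl methoxycinnamate fluoresce
strongly at 480–600 nm under 450 nm excitation, while the salt matrix is
optically silent there. A hyperspectral camera turns that contrast into a
rows × cols × bands data cube in which every pixel carries a full emission
spectrum, so contamination can be detected *and localized* without
destroying the sample. This package implements the full analysis chain for
such cubes, aimed at chemometricians and food-safety labs working with
fluorescence imaging:

1. **Radiometric calibration** — two-point correction
   `R_f = (R_o − R_D)/(R_B − R_D)` against white (Spectralon-style) and
   dark reference frames.
2. **Spectral preprocessing** — laser-band removal (< 480 nm), per-spectrum
   10th-percentile baseline subtraction, negative clipping, area
   normalization over 480–1000 nm, and Savitzky–Golay smoothing
   (order 3, window 11). An amplitude decibel transform
   (`20·log10`) is available for display.
3. **Sparse PCA feature extraction** — the package's core. Each loading
   vector `v` is found by power iteration with an *adaptive relative*
   soft-threshold: per update, `z = Xᵀ(Xv)`, `τ = λ·max|z|`, and
   `v ← S(z, τ)/‖S(z, τ)‖₂` where `S(z, τ) = sign(z)·max(|z| − τ, 0)`;
   components are removed by Hotelling deflation `X ← X − (Xv)vᵀ`. Because
   τ rescales with each component's own signal magnitude, weak secondary
   emission bands survive the shrinkage that a static threshold would
   apply. At `λ = 0` the method reduces exactly to ordinary PCA.
4. **Classification** — a soft-margin RBF SVM (`C = 1`, kernel scale
   "auto" = median pairwise distance, standardized predictors) on the
   sparse scores, applied per pixel to produce a green/blue contamination
   map.
5. **Evaluation** — ground-truth hygiene (1-pixel erosion of the
   contaminated region, balanced sampling), confusion counts, accuracy /
   precision / recall / F1, class fractions, and color-coded spatial error
   maps (TP blue, TN green, FP yellow, FN red).

Because no public instrument data exist for this problem, the package ships
a first-class **phantom generator** (`lifhsi.phantom`) that renders
synthetic scenes — clean-salt spectra (~200–400 counts flat background plus
the 450 nm laser line), contaminated spectra (dominant Gaussian emission
peaking in 480–520 nm at ~4100 counts plus secondary bands near 575, 750
and 990 nm), spatially clustered contamination, sensor noise, dark current,
and white/dark reference frames — so every stage is testable end to end.

## Worked example

Render a 200 × 200 phantom, train the canonical stack (900 + 900 labeled
spectra, k = 4 sparse components at λ = 0.5, SVM at C = 1), classify every
pixel and score the map against the eroded ground truth:

```python
import json
from lifhsi import RunConfig, run_pipeline

config = RunConfig(phantom={"rows": 200, "cols": 200}, seed=7, run_crossval=True)
report = run_pipeline(config)
print(json.dumps({
    "metrics": report["metrics"],
    "class_fractions": report["class_fractions"],
    "sparsity": {k: report["sparsity"][k] for k in
                 ("nonzero_counts", "overall_sparsity_pct")},
    "crossval_accuracy": report["crossval"]["accuracy"],
}, indent=2))
```

prints

```json
{
  "metrics": {
    "accuracy_pct": 99.98,
    "precision": 1.0,
    "recall": 0.9997,
    "f1": 0.9998
  },
  "class_fractions": {
    "clean": 0.422175,
    "contaminated": 0.577825
  },
  "sparsity": {
    "nonzero_counts": [97, 9, 9, 4],
    "overall_sparsity_pct": 73.2
  },
  "crossval_accuracy": {"mean": 1.0, "sd": 0.0}
}
```

Reading the numbers: the pixel map recovers the planted contamination
almost perfectly (99.98 % of labeled pixels, one missed pixel in ~38 000);
57.8 % of the scene is classified contaminated, matching the generator's
target fraction; component 1 is a broad class-contrast direction (97
non-zero loadings of 111 bands) while components 2–4 are extremely sparse
(9, 9, 4 non-zero), each locked onto one planted emission band; tenfold
stratified cross-validation of the 1800 training spectra is perfect at this
signal-to-noise ratio.

The same pipeline is scriptable from the shell:

```sh
lifhsi simulate --out scene/ --seed 7
lifhsi calibrate --raw scene/cube.hdr --white scene/white.hdr \
    --dark scene/dark.hdr --out scene/calibrated.hdr
lifhsi run --config run.json          # full pipeline from a JSON config
lifhsi compare --config run.json      # sparse vs dense PCA features
```

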