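# Methods

## Problem and approach

Skin-lesion images are classified from hand-crafted texture features rather
than learned representations. Each image is decomposed into intensity
planes; a histogram-based local descriptor encodes every pixel of a plane
as a small integer code derived from its neighborhood and summarizes the
plane as a histogram of codes; histograms from the three channels of a
color space are concatenated into a *colored* feature (and optionally two
descriptors are concatenated into a *hybrid* feature); a standard
classifier (SVM or XGBoost, library defaults) is trained on the vectors.
The hypothesis under test is representational: per-channel color
histograms carry strictly more class information than their grayscale
projection.

"+" in the colored/hybrid constructions is vector concatenation, not
element-wise addition — the latter is dimensionally impossible when mixing
descriptors of different lengths (256 vs 3072), and concatenation is the
standard reading in descriptor fusion.

## Color conversions

All planes are 8-bit, rounded half away from zero and clipped, so every
downstream histogram is bit-exact and reproducible:

* **GRAY** — BT.601 luma `0.299R + 0.587G + 0.114B`.
* **YCbCr** — full-range BT.601 (JPEG constants, +128 offsets). Full range
  rather than studio swing so descriptors see the whole [0, 255] dynamic
  range. For any achromatic image the GRAY and Y planes are identical.
* **HSV** — hue rescaled from [0°, 360°) to [0, 255], S and V to [0, 255].
  Hue is circular but is treated as an ordinary scalar plane; codes near
  the red wrap-around are therefore distorted. This matches naive
  per-channel extraction and is accepted as a known approximation.
* **LAB** — sRGB → XYZ (D65) → CIELAB; `L*·255/100`, `a*+128`, `b*+128`.

## Descriptors

Border pixels lacking a full 3×3 neighborhood are excluded rather than
padded, so an unnormalized code histogram sums exactly to the interior
pixel count `(H−2)(W−2)` — the simplest testable mass contract. Histograms
are L1-normalized by default (per descriptor segment, and per block for
MBC) because margin classifiers are scale-sensitive; raw counts are
available with `normalize=False`.

* **LBP** (256 bins). Neighbors are visited clockwise from the top-left
  corner; bit *i* (weight 2^i) is set iff neighbor ≥ center. The ≥
  convention is the dominant one in the descriptor literature; a constant
  plane maps every pixel to code 255. LBP is invariant under any strictly
  increasing intensity transform.
* **Kirsch responses.** Mask 0 is East, `[[−3,−3,5],[−3,0,5],[−3,−3,5]]`;
  each next mask rotates the ring 45° counterclockwise. Coefficients sum
  to zero, so responses are invariant to additive intensity offsets.
* **LDN** (56 bins). Code = (argmax, argmin) of the 8 responses, packed as
  `i_max·7 + (i_min if i_min < i_max else i_min − 1)`. Ties break to the
  lowest index; if argmax = argmin (flat neighborhood, all responses
  equal) the argmin is reassigned to the lowest index ≠ argmax, so a
  constant plane deterministically yields code 0. Invariant under positive
  affine maps `aI + b, a > 0`.
* **LDiP** (56 bins). Bits set at the 3 directions of largest |response|
  (ties to the lower index); the C(8,3) = 56 valid codes are binned in
  ascending code value. Rank order is invariant to positive scaling. On a
  flat plane ties select directions {0,1,2} → code 7.
* **PHOG** (168 = 8·(1+4+16)). Centered-difference gradients (one-sided at
  borders), signed orientation in [0°, 360°), 8 bins of 45°, levels 0–2
  with a 2^l × 2^l cell grid (cell of pixel r: ⌊r·2^l/H⌋),
  magnitude-weighted, L1-normalized over the whole vector. All pixels
  contribute rather than a Canny edge mask: this removes two free
  thresholds and keeps the operation deterministic, at the cost of a
  possible divergence from edge-gated PHOG variants. A zero-gradient plane
  returns the zero vector. The 8-bin/3-level geometry is pinned by the
  printed 168-length contract.
* **MBC** (3072 = 3·4·256). The plane is band-passed with a log-Gabor
  filter (wavelength 4 px, σ/f = 0.65 — standard monogenic-filtering
  defaults) and extended to the monogenic signal via the frequency-domain
  Riesz transform; amplitude `A = √(e²+r1²+r2²)`, phase
  `φ = atan2(√(r1²+r2²), e)` and orientation `θ = atan2(r2, r1)` maps are
  each coded with the LBP neighbor comparison and histogrammed over a 2×2
  block grid, 256 bins per block, each block L1-normalized. Among the MBC
  layouts in circulation, 3 components × 2×2 blocks × 256 bins is the one
  that reproduces the 3072-length contract with a plain 8-bit code; only
  the total length is externally pinned. With `scales > 1`, per-scale
  histograms are summed bin-wise before normalization (wavelength doubles
  per scale), so the length is scale-invariant.

## Balancing

SMOTE: each class is oversampled to the majority count by
`x + u·(x_nn − x)` with `u ~ U[0,1]`, `x` a random class member and `x_nn`
one of its `k = 5` nearest same-class neighbors (Euclidean;
`k_eff = min(k, n_class − 1)`). Originals are preserved verbatim and one
seeded RNG drives all draws. Balancing is applied to the **training
partition only**, after the split, to avoid leaking synthetic points
derived from test samples; `k = 5` is the canonical SMOTE default.

## Evaluation

Classifiers are delegated to `sklearn.svm.SVC` and
`xgboost.XGBClassifier` with library defaults (the representation, not the
classifier, is the object of study); the delegate version and effective
hyperparameters are recorded in every run report.

Binary metrics treat label 1 ("malignant") as positive. Multi-class
metrics are one-vs-rest, combined by **weighted** averaging by default
(macro available): weighted F1 tracks accuracy closely, which matches how
aggregate F1 behaves in this literature. Division-by-zero cells (a class
never predicted, or absent) contribute 0 with a logged warning — degenerate
classifiers must produce a report, not a crash.

Two prediction vectors are compared with a two-tailed Welch t-test at
α = 0.05, with class indices cast to numerics (the established, if crude,
reading for multi-class label vectors; it measures agreement of label
means, not per-sample agreement). Identical vectors give t = 0, p = 1
exactly; if both vectors are constant the statistic is defined as 0 with
p = 1. Degrees of freedom via Welch–Satterthwaite.

## Synthetic fixtures

The generator renders a skin-toned background plus an elliptical lesion
with class-dependent mean color, sinusoidal texture (frequency,
orientation, and a mostly-chromatic modulation axis), eccentricity and
border irregularity (low-order sinusoidal radius perturbation), plus
additive Gaussian noise (σ = 8 gray levels by default — enough to avoid
degenerate constant planes, small enough to keep classes separable).
Images are pure functions of `(seed, class_id, index)`.

Default study conditions: the 2-class set has 100 images per class at
224×224; lesion means (140, 90, 90) vs (70, 122, 118) are ~82 RGB units
apart but nearly isoluminant (BT.601 luma ≈ 105 for both), with texture
frequencies 0.10 vs 0.22 cycles/px, so the class signal lives mainly in
chroma and texture — by design, since the point of the fixtures is to let
colored features demonstrate their advantage over grayscale ones. The
7-class variant spreads means, frequencies and shapes across classes and
defaults to 28×28.

What the fixtures do **not** emulate: hair, rulers, specular highlights,
vignetting, acquisition variation, or realistic lesion morphology. Passing
fixture experiments shows the pipeline is correct and the representations
can exploit color and texture; it does not predict accuracy on clinical
dermoscopy archives, which additionally depends on the reference feature
implementations and datasets.

## Pipeline and numerical choices

* One top-level seed drives split, SMOTE and classifier; reports are
  JSON-serializable and runs with equal config+seed are identical.
* Both predefined train/test manifests and stratified fractional splits
  (default 80/20) are supported.
* Feature matrices can be cached keyed by a hash of (data identity,
  descriptors, space, normalization); cached runs are bit-identical to
  cold runs.
* All integer plane conversions round half away from zero; descriptor
  arithmetic is exact integer work except PHOG/MBC, which are float64.
* The acceptance script uses the default fixture set (200 images, 224²)
  and the full 5-descriptor × 4-space XGBoost grid — a few minutes on one
  CPU; problem sizes in the test suite are smaller (28² planes, ≤ 8×8
  oracle planes) to keep brute-force verification fast.

## Known limitations

* Hue circularity is ignored (see above).
* The exact MBC and PHOG variants used by reference Matlab feature
  libraries are not fully published; only the histogram lengths are
  externally verifiable, so cross-implementation feature values may differ
  at the margin even where both are internally consistent.
* The Welch test on categorical label vectors is a blunt instrument; it is
  provided because it is the field's reporting convention.
* SMOTE interpolates in feature space; for histogram features the
  synthetic points remain valid (non-negative, ~L1-normalized) only
  because the operation is convex.
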