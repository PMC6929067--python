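# Methods

This note documents the models, parameter choices and known limitations of
`ermmap`, in the order the pipeline runs.

## Synthetic phantom volumes

Real ERM-annotated OCT volumes are clinical data without a public accession,
so the study conditions are defined by a generator (`ermmap.phantom`) that
emulates the gross structure the method exploits:

- **Geometry.** The ILM surface is a parabolic foveal dip of amplitude
  `ilm_curvature_amp` (default 12 px, deepest at the lateral center) plus a
  low-frequency sinusoidal undulation (`ilm_wobble_amp`, default 2 px) whose
  phase drifts smoothly across slices. Below the surface lies a uniform
  retinal band (`retina_thickness`, 70 px); above and below is dark
  vitreous.
- **Intensities.** Mean 8-bit levels: vitreous 25, tissue 120, ERM 230 —
  the ordering (ERM brightest, vitreous darkest) is the defining contrast of
  the problem and is asserted as a generator invariant under speckle.
- **ERM bands.** Each requested region `(slice_start, slice_end, col_start,
  col_end, detach_px)` renders a 1–3 px thick band `detach_px` above the
  surface (0 = attached). Thickness is drawn once per region from the
  volume's seeded generator. The en-face truth map marks exactly the
  requested extents — no blur or morphology is applied to the mask.
- **Noise.** Multiplicative Gaussian speckle, `pixel · (1 + N(0, σ))`
  clipped to [0, 255], default σ = 0.08. This stresses the intensity and
  texture features without simulating physical speckle statistics
  (correlated, Rayleigh-family), motion artifacts or vessel shadowing.

Default volume size is 32 slices of 160×128 px — a deliberately reduced
scale chosen so a full multi-volume study (segmentation, ~50k window
extractions, a 5-classifier × 10-count CV sweep) runs in minutes on one
CPU. What passing tests on phantoms show is that every stage does its job
under the stated contrast and noise model; they do not certify clinical
accuracy on real scans, where layer texture, vessel shadows and acquisition
artifacts are far richer.

## ILM segmentation

The surface is single-valued in a B-scan, so the snake is parameterized as
one row value per column and moves vertically only. The discrete energy is

    E(r) = Σ_c α (r[c+1]−r[c])² + β (r[c+1]−2r[c]+r[c−1])² + P(r[c], c)

with free (natural) end conditions, and the image potential

    P(y, c) = −|∇(G_σ ∗ I)|(y, c) / max|∇(G_σ ∗ I)|  +  balloon · (H−1−y).

The second term is a constant downward pressure (a balloon force): a purely
edge-attracted contour initialized at the top of the image sits in the
featureless vitreous where the gradient is zero and would never move. The
pressure slope (default 0.15 per pixel of depth) is small relative to the
normalized edge-valley slopes (~0.3–0.5), so the contour descends through
the vitreous and is captured and held at the first strong edge.

Updates use the classic semi-implicit step `r ← (I + γK)⁻¹ (r + γ F)` where
`K = α D₁ᵀD₁ + β D₂ᵀD₂` and `F` is the interpolated downhill force of `P`.
Each step is accepted only if the discrete energy does not increase,
otherwise the step size is halved (up to 12 times); this makes the energy
non-increasing by construction and the whole iteration deterministic.
Convergence is declared when the mean per-column movement drops below
`conv_tol` (0.05 px) or after `max_iters` (500). Defaults α = 0.1, β = 1.0,
γ = 2.0, σ = 2 px were chosen against the phantom oracle (sub-pixel MAE on
noiseless surfaces) and are all exposed in `RunConfig`.

Degenerate inputs: a constant scan has no edge and raises an error rather
than returning an arbitrary contour. On slices with an attached or detached
ERM the first bright edge from above is the membrane, so the contour rides
on it rather than on the anatomical ILM; this is the intended behavior —
the feature window is meant to straddle whatever sits at the surface.

## The 452-feature descriptor

The window is a vertical rectangle of five stacked squares (`sub_side` = 15
px, so 15×75) centered laterally on the point and vertically on the rounded
contour row: sub-windows 1–2 sample the space above the surface, 3
straddles it, 4–5 sample the retina below. Points whose window would clip
an image border are excluded from sampling and predicted as background.
The category composition is fixed (10 + 16 + 160 + 64 + 28 + 75 + 13 + 5 +
81 = 452, asserted at registry construction) and the internal definitions
are:

- **PCA (10):** projection of the mean-centered vectorized window onto the
  10 leading components fitted once, globally, on the training windows; the
  basis is stored with the model and reused at prediction time.
- **GLCM (16):** contrast, correlation, energy, homogeneity at distance 1
  for 0°/45°/90°/135° on a 16-level quantization (16 levels keep the
  co-occurrence matrix populated in a 15×75 window).
- **Gabor (160):** 4 wavelengths (2, 4, 8, 16 px) × 8 orientations; mean
  response magnitude per sub-window.
- **LBP (64):** full 64-bin normalized histogram of P = 6, R = 1 codes.
- **Laws (28):** the 5×5 kernels from {L5,E5,S5,W5,R5}; the 10 symmetric
  cross pairs are averaged (|AB| + |BA|)/2 and the 4 non-level diagonals
  kept, giving 14 energy maps; mean and standard deviation of each.
- **Window (75):** per sub-window mean, std, min, max, median, range,
  skewness, kurtosis, entropy (32-bin Shannon), histogram energy Σp², and a
  5-bin normalized histogram. These are the domain-specific features: an
  ERM band raises the intensity statistics of the sub-windows at and above
  the surface.
- **Global intensity (13):** the same 10 statistics over the full rectangle
  plus the 25th/75th percentiles and the variance.
- **GLIH (5):** 5-bin normalized gray-level histogram of the rectangle.
- **HOG (81):** 3×3 spatial cells × 9 unsigned orientation bins, one
  L2-normalized block.

Histogram bins are fixed over [0, 1] (not min-max of the patch): the
features are intensity-sensitive by design, since hyper-reflectivity is the
phenomenon being detected. Skewness/kurtosis are population moments defined
as 0 on constant patches; any residual non-finite value is mapped to 0 so
vectors are always finite.

Implementation note: Gabor, Laws and LBP responses are computed once per
B-scan (FFT convolution / full-scan code image) and pooled over the window
slice. This is both faster by an order of magnitude and free of
window-border convolution artifacts; category outputs and counts are
unchanged.

## SURF feature ranking

All instances are used (no k-NN sampling): the neighbor threshold T is the
mean Euclidean distance over all unordered pairs of min-max-scaled
instances, and instance i's neighbors are all j with d(i,j) < T. A
feature's weight accumulates `+diff/(n·m_i)` over different-class neighbors
and `−diff/(n·h_i)` over same-class neighbors, with `diff` the absolute
scaled value difference. The algorithm is deterministic and invariant to
sample order; ranking ties break toward the smaller feature index. A
constant feature scores exactly 0. Correctness is pinned by a brute-force
triple-loop reference implementation kept in the test suite.

## Classification protocol

Training points are drawn class-balanced (⌈n/2⌉ positive) without
replacement from all eligible ILM points of the training volumes, using the
snake contours (not the generator's true surface — the pipeline is
automatic end to end) and the per-pixel truth map for labels. The default
sample size is 800 points, a reduced scale consistent with the phantom
study size.

The feature ranking is computed once on the full training sample and applied
inside cross-validation as a fixed index prefix. This mirrors a
single-global-ranking protocol and carries a known optimistic bias relative
to re-ranking per fold; on phantoms the gap is negligible because the
classes are strongly separated.

Ten stratified folds; min-max scaling fitted per training fold; accuracy is
the model-selection metric. Classifiers: random forest (100 trees), RBF SVM
(C = 10, γ = "scale" by default, hyper-parameters exposed), k-NN with
k ∈ {2, 6, 8} (Euclidean, unweighted votes; a 2-NN tie resolves to class 0,
the conservative no-ERM call). The feature-count sweep evaluates
k ∈ {20, 40, …, 200} and can refine the argmax by unit steps within a
configurable radius (off by default; the coarse grid is sufficient at
phantom separability).

## Map reconstruction and refinement

Per-slice label vectors stack row-wise into the en-face map. Refinement
applies, in order, (1) removal of connected components with area below
`min_area` (8-connectivity by default, so diagonal slice-to-slice adjacency
counts) and (2) binary closing with a disk of `closing_radius`. The map is
zero-padded by the radius before closing so the operation is extensive
(never loses foreground) and idempotent, including at borders. The en-face
grid treats slice spacing and lateral pixel pitch as equal; anisotropy
correction is out of scope.

Both parameters are chosen by exhaustive search over
{0, 10, 25, 50, 100, 200} × {0, 1, 2, 3, 5, 7}, maximizing mean Dice over
the evaluation volumes with ties toward the smaller area threshold, then
the smaller radius. Because the identity (0, 0) is in the grid, the
refined mean Dice can never fall below the raw mean Dice on the volumes the
search saw. Volumes without true ERM have undefined Dice and are skipped by
the optimizer; if every volume is membrane-free the optimizer refuses and
points to specificity-based selection.

## Metrics

Sensitivity, specificity, Dice and Jaccard are computed from pixel-level
confusion counts on the en-face maps (an optional slice-level mode — a
slice is positive if any column is — exists for comparison). Metrics with a
zero denominator are reported as undefined (`None`), not coerced; on
membrane-free volumes only specificity is aggregated. Aggregation uses the
arithmetic mean and the sample (n−1) standard deviation; single-volume
aggregates report std 0 with n = 1.

## Known limitations

- The phantom's retina is texture-free inside; texture features (GLCM,
  Laws, LBP) therefore carry less discriminative load than they might on
  real tissue, and the measured feature-importance mix should not be read
  as clinical.
- Phantom separability is high, so cross-validated accuracies saturate near
  0.99 and the feature-count sweep is flatter than it would be on clinical
  data.
- The snake assumes a single-valued surface; full retinal detachment, where
  the first bright edge is not the retina, is out of scope.
- No registration to fundus/NIR imagery; map overlay on other modalities is
  limited to naive rescaling.
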