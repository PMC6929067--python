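# ermmap

Automatic detection and en-face mapping of the epiretinal membrane (ERM) in
spectral-domain OCT volumes.

The ERM is a hyper-reflective fibrocellular sheet that grows on (or slightly
above) the inner limiting membrane (ILM), the top surface of the retina in an
OCT B-scan. Left untreated it distorts the macula and degrades visual acuity,
so ophthalmologists want to know not just *whether* a membrane is present but
*where* it extends over the retinal surface. `ermmap` turns a stack of 2D
B-scans into a single 2D top-down (en-face) map of ERM presence, with one map
row per B-scan and one column per lateral scan position.

## Method

For a volume of B-scans the pipeline runs five stages:

1. **ILM segmentation.** A vertical active contour (snake), initialized as a
   horizontal line at the top of each scan, descends under a constant
   pressure force and locks onto the first strong dark-to-bright edge — the
   retinal surface. The contour r(x) minimizes
   `E = Σ α r′² + β r″² + P(r(x), x)` with
   `P = −|∇(G_σ ∗ I)| + balloon·(H−1−y)`.
2. **Feature extraction.** Around every surface point a 15×75 px window of
   five stacked 15×15 sub-windows (two above the surface, one straddling it,
   two below) yields a fixed-order 452-value descriptor: PCA projections
   (10), GLCM statistics (16), Gabor bank responses (160), LBP histogram
   (64), Laws texture energies (28), per-sub-window intensity statistics
   (75), global intensity statistics (13), gray-level histogram (5) and HOG
   (81).
3. **Feature selection.** SURF (Spatial Uniform ReliefF) ranks the 452
   features: every instance pair closer than the mean pairwise distance is a
   neighbor; a feature gains weight when it differs across classes among
   neighbors and loses weight when it differs within a class.
4. **Classification.** A random forest, an RBF SVM and k-NN (k = 2, 6, 8)
   are compared by 10-fold cross-validated accuracy over a sweep of
   top-k feature counts; the best configuration labels every ILM point of
   every slice as ERM / background.
5. **Map reconstruction and refinement.** Per-slice label vectors stack into
   the en-face map; connected components smaller than an area threshold are
   removed and a morphological closing unifies neighboring ERM regions. The
   two parameters are grid-searched to maximize mean Dice overlap
   (`D = 2TP/(2TP+FP+FN)`, with Jaccard `J = D/(2−D)`).

Because no public ERM-annotated OCT dataset exists, the package ships a
phantom generator that renders synthetic volumes — dark vitreous, bright
curved retina with a foveal dip, multiplicative speckle, and a thin
hyper-reflective band over a known extent — with per-pixel ground truth, so
every stage is testable end to end.

## Worked example

```bash
python examples/01_phantom_and_segmentation.py
```

prints

```
volume: 8 slices of 160x128 px
true ILM depth range: rows 53.0 to 68.6
snake mean absolute error on slice 0 (membrane-free): 0.29 px
snake mean absolute error on slice 3 (with ERM band): 2.32 px
```

On a membrane-free slice the snake recovers the surface to a fraction of a
pixel; on an ERM slice the first bright edge is the membrane itself, so the
contour rides a few pixels higher — exactly where the analysis window should
sit. `examples/02_features_and_selection.py` shows the descriptor and the
SURF ranking; `examples/03_full_study.py` runs a small study end to end and
prints the map-quality scorecard (CV accuracy, raw vs refined Dice,
specificity).

The same pipeline is available from the shell:

```bash
erm phantom --out vol/ --seed 3      # synthetic volume + ground truth
erm segment vol/ --out ilm.csv       # ILM contours
erm demo --out run/                  # full synthetic study
erm evaluate run/maps/test_erm_00_refined.png vol/true_map.png
```

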