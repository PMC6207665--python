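# Methods

This note documents the models, parameter choices and conventions behind
`fibrostage`, and what the synthetic experiments do and do not show.

## Synthetic SHG phantoms

The generator emulates the appearance that matters to collagen
morphometry: sparse bright tubular fibers on a dim parenchymal
background inside an elliptical tissue section, on a dark glass
surround.  Each fiber is a quadratic Bezier stroke with a Gaussian
cross-profile (sigma = width/2) rendered by maximum compositing of
sub-pixel stamps; end caps are clipped flat against the local tangent so
that the rendered tube's extent matches its centerline length (round
caps would otherwise overhang by ~2-3 sigma and bias length recovery).
Septa are chains of 3-5 connected strokes; with probability
`bridging_prob` a fiber starts on a previously drawn one, creating the
bridging networks typical of F2-F4.

Per-stage defaults (fibers / length / bridging / septa) rise
monotonically from F0 (6 fibers, no bridging, no septa) to F4 (60
fibers, bridging 0.7, 12 septa), mirroring the Metavir progression from
no fibrosis through bridging fibrosis to cirrhosis.  The frame is
512x512 at 8-bit depth — large enough for three wavelet levels and
distance-8 co-occurrence statistics, small enough for desk-scale runs.
The parenchyma level is 28 of 255 with its edge feathered over 12 px
(section edges are not razor sharp at 20x); read noise is additive
Gaussian with sd 0.5 clipped at zero, with an optional Poisson
shot-noise toggle.  The noise default is deliberately conservative: the
contrast-stretch step amplifies background noise strongly whenever
collagen is sparse (the high percentile then falls inside the parenchyma
mode), and a heavier default would swamp F0/F1 phantoms with
speckle that real acquisition averaging removes.  Setting
`background_level=0` yields dark-field phantoms (fibers only) used for
ground-truth recovery experiments.

Determinism: every image is a pure function of `(params, seed)`;
dataset images use `SeedSequence([master_seed, index])`, so any subset
is reproducible independently.

What the phantoms do **not** model: SHG photophysics (phase matching,
polarization), 3-D sectioning, tile mosaics, intensity inhomogeneity,
and real inter-animal variability.  Passing tests on phantoms
demonstrates that the pipeline measures what it claims on objects with
known geometry — not that staging accuracy transfers to real tissue.

## Preprocessing

Chain: percentile stretch (1st/99th percentiles to the full dynamic
range) → local-mean adaptive threshold (window 65 px, reflected borders,
offset = 0.1 x global intensity SD) → morphological closing (disk radius
1) → removal of 8-connected components under 5 px (strict: size >= 5
survives) → intersection with the tissue mask, then a re-check of the
5-px rule.

The tissue mask thresholds a heavily smoothed image (Gaussian sigma 10)
and fills holes.  Plain Otsu is used when the histogram is glass-vs-
tissue bimodal; when bright collagen is abundant the histogram is
trimodal and Otsu latches onto the fiber mode, so a 3-class Otsu split
is consulted: if its middle class holds more than 20% of the pixels
(genuine parenchyma rather than an edge ramp), the lower threshold is
used.  Before intersection the tissue mask is shrunk by `border_trim`
(default 64 px ≈ one window): within half a window of the section edge
the local-mean neighborhood straddles tissue and glass, and the
threshold there detects the edge itself rather than collagen.  For
dark-field phantoms (no section edge) `border_trim=0` is appropriate.

## Fiber morphometry (features 1-21)

A fiber is an 8-connected component of the clean collagen mask — the
simplest reading consistent with counting "fibers" after the sub-5-px
cleanup.  Measurements per fiber:

* **length** — geodesic diameter of the skeleton (longest shortest path,
  diagonal steps sqrt(2)), plus 1 px of endpoint extent.  Skeletons grow
  short Y-arms toward the corners of blunt ends; terminal spurs no
  longer than a first-pass width estimate (area / raw diameter) are
  pruned before the final measurement.  On noise-free single-fiber
  phantoms this recovers centerline length within 10%.
* **width** — area / length (mean width of a tubular object).  Note the
  segmented width exceeds the nominal profile width whenever the
  threshold sits far below the fiber peak (the mask captures the
  profile's tails); width-based features are therefore consistent
  within a pipeline run but are not calibrated estimates of physical
  diameter.
* **orientation** — major-axis angle from pixel second moments, degrees
  in (-90, 90] measured from the image x-axis.
* **area, perimeter, mean intensity** — pixel count, boundary-traced
  perimeter, mean enhanced intensity.

The 21-vector aggregates these as medians, totals and population
variances, long/short and thick/thin counts split at configurable cuts
(default: the pooled per-fiber median length and width of the dataset,
so the cuts adapt to magnification), their ratios (0/0 → 0; x/0 capped
at 100), plus the collagen mean intensity and CPA = |collagen ∩ tissue|
/ |tissue|.  Empty images yield all-zero features so classifiers never
see missing values.  Skeleton branch-point counts are retained on each
`Fiber` as optional cross-link descriptors but are not part of the
21-vector.

## Texture (features 22-130)

Computed on the contrast-enhanced grayscale cropped to the tissue
bounding box (co-occurrence statistics on a binary mask are degenerate).
Layout: entropy (1) | GLCM (12) | Fourier (6) | wavelet (60) | Gabor
(30).

* **GLCM**: 32 gray levels (linear quantization of the observed range),
  symmetric, averaged over the four standard offsets, distances
  {2, 4, 8}, distance-major output of Haralick contrast, correlation,
  energy, homogeneity.  Zero-variance correlation is 0 by convention.
* **Fourier**: statistics of the DFT magnitude spectrum, DC excluded
  (with DC included the spectral mean is a brightness proxy duplicating
  feature 20); energy is scaled so that, by Parseval, it equals the
  pixel variance.
* **Wavelet**: 3-level Daubechies-4 — the unique depth giving ten
  sub-images with one retained approximation.  The orthogonal
  (periodization) boundary form is used: it is the only form in which
  sub-band energies sum exactly to the image energy, which doubles as a
  built-in correctness check.  Detail bands are ordered level-major
  (finest first), approximation last.
* **Gabor**: five scales on the ladder f0/2^k with f0 = 0.25 cycles/px,
  1-octave bandwidth, four orientations (0/45/90/135 degrees) whose
  magnitude responses are averaged — the feature list indexes scale
  only, so orientation must be pooled.  Convolution uses periodic
  boundaries, which keeps a constant image's response exactly flat and
  the features invariant under circular shifts; low-frequency kernels
  larger than the image wrap onto the grid.

Every coefficient collection is summarized by six statistics: energy
(sum of squares for sub-band decompositions, mean of squares
otherwise), Shannon entropy of the L1-normalized magnitudes, mean,
standard deviation, and standardized skewness and (Pearson) kurtosis,
both 0 for zero-variance collections.

## Classifiers

All families standardize features with training-fold statistics only
(constant features pass through with scale 1) and are deterministic
under a fixed seed.

* **ANN**: tanh hidden layers (stock architectures 10, 20, 20+20),
  softmax output, cross-entropy, full-batch gradient descent (rate 0.05,
  2000 epochs).  Implemented in-package; the analytic gradient is
  exposed and verified against central finite differences.
* **MLR**: multinomial logit by maximum likelihood (lbfgs, cap 500
  iterations), optional ridge penalty.  Three conditions flag
  `converged=False`: hitting the iteration cap; standardized
  coefficients beyond 15 (an MLE drifting to infinity under separation
  can still meet a gradient tolerance at enormous coefficients); and a
  rank-deficient design (e.g. 130 features on 100 samples), where the
  unpenalized likelihood has flat directions and no unique maximum.
  The flagged model still produces scores — non-convergence is a
  finding, not a crash.
* **SVM**: RBF kernel exp(-|x1-x2|^2 / (2 sigma^2)), one machine per
  stage (one-vs-rest), C = 1; default sigma = sqrt(p/2) on standardized
  features.  Decision values are squashed through a logistic and
  L1-normalized per row — ROC needs a continuous per-class score and
  any monotone squashing leaves the ROC unchanged.
* **RF**: 100 trees, entropy (information-gain) splits with continuous
  thresholds, bootstrap resampling, sqrt(p) feature subsampling; scores
  are per-class vote fractions.  Feature importance is permutation
  importance (seeded, ties broken by feature index) — impurity-based
  importances are biased toward high-cardinality features.

## CNN

Input 224x224x3 (bilinear resize of the processed image, replicated
across channels, scaled to [0, 1]).  Five convolutions — (11x11, 96,
stride 4, pad 2), (5x5, 256, pad 2), then three 3x3 layers of 384, 384,
256 (pad 1) — with 2x2/stride-2 max pools after the first, second and
fifth, then FC6/FC7 at 4096 and a 5-way softmax; the shape chain
224→55→27→27→13→13→13→13→6 (9216 flat) is verified at build time.
Training is mini-batch SGD with momentum 0.9, weight decay 5e-4, batch
16.  The engine is a compact numpy implementation (im2col convolution
with analytic backprop).

No pre-trained weights are used: the network trains from scratch.  The
full 60M-parameter geometry is only sensible with far more data and
compute than a synthetic desk study provides, so a documented
reduced-scale variant (64x64 input, channel widths divided by 8,
128-wide FC layers, identical layer plan) is used for the trainable
experiments.  On the default cohort it reaches far-above-chance staging
(5-fold CV), but reduced-scale results say nothing quantitative about
full-scale AlexNet performance.

## Evaluation

Leave-one-out cross-validation refits everything per fold, including
standardization.  ROC curves are built from the pooled out-of-fold
scores (one curve per model and dichotomy); the positive-class score at
cutpoint k is the summed class score over stages >= k.  AUROC follows
the Mann-Whitney midrank convention (ties count 1/2), cross-checked in
the tests against exhaustive pair enumeration.  Sensitivity,
specificity, PPV and NPV are taken at the argmax-label operating point,
with 0/0 reported as 0 and flagged.

Model comparison: Kruskal-Wallis across per-model performance samples,
then all C(5,2) = 10 pairwise two-sided Wilcoxon-Mann-Whitney tests
against the Bonferroni-adjusted critical p = 0.05/10 = 0.005.  The
performance sample for each model is 200 seeded bootstrap resamples of
its pooled LOO AUROC — a replicate unit chosen because it is
reproducible and uses exactly the data the ROC uses.  Identical samples
short-circuit to p = 1 (rank tests are undefined on all-tied data).

## Problem sizes

The default study conditions are 5 x 20 images at 512x512 — a balanced
five-stage cohort of 100 — used by the acceptance script and the
heavier tests; unit tests run on 128-256 px phantoms and miniature
cohorts.  At these sizes the full feature extraction over the cohort
takes about a minute and the complete acceptance run a few minutes on
one CPU.

## Known limitations

* Phantom realism is heuristic (no SHG physics, simplified noise); all
  quantitative claims are about pipeline correctness, not clinical
  staging accuracy.
* Stage separability of the default phantoms is higher than in real
  cohorts; near-ceiling AUROCs here indicate the features capture the
  generator's monotone morphology, not that real F2/F3 boundaries are
  easy.
* Fiber width is a mask-derived quantity, threshold-dependent as noted.
* The MLR coefficient-magnitude flag (|beta| > 15 standardized) is a
  heuristic for separation; it cannot distinguish true separation from
  extremely strong genuine effects, which are implausible at these
  scales but not impossible.
* No confidence intervals on AUROC (DeLong) and no curve averaging
  across folds; pooled-LOO curves only.
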