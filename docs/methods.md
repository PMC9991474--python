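# Methods

## Problem and model

The pipeline classifies a fixed 300×400-pixel trabecular ROI from a
periapical radiograph as *osteoporosis* vs *nonosteoporosis*. The working
assumption is that osteoporotic bone loss changes the grayscale composition
of the ROI: more and larger marrow pores mean more dark pixels. The feature
is therefore the segmentation histogram — partition the pixel intensities
into K clusters and count the pixels per cluster. No spatial information is
used: clustering operates on the scalar intensity alone, so the feature is
a K-bin adaptive re-binning of the intensity histogram.

Ground-truth labels derive from DEXA T-scores using the WHO cut-offs
(normal T ≥ −1.0, osteopenia −2.5 < T < −1.0, osteoporosis T ≤ −2.5);
normal and osteopenia are pooled into the negative (nonosteoporosis) class.
Boundary values follow the closed bounds: T = −1.0 is normal, T = −2.5 is
osteoporosis.

## Segmentation

**K-means.** In 1-D the within-cluster-SSE-optimal clusters are contiguous
intervals of the sorted intensities, so the global optimum is computable by
dynamic programming over the ≤256 unique intensity values, weighted by
their pixel counts (O(U²K) with U ≤ 256 — a few milliseconds per ROI). This
exact solver is the default (`ClusterConfig(algorithm="exact")`): it is
deterministic, needs no initialization, and always attains the SSE optimum.
Classical Lloyd iteration (`algorithm="lloyd"`) is kept for comparison; it
can converge to local optima (measured on uniform-random test images, a
substantial fraction of runs from quantile initialization end above the DP
optimum), which is why it is not the default. Lloyd details: quantile
initialization places centroid i at the (i+0.5)/K intensity quantile
(seeded random initialization is available); iteration stops when the
largest centroid movement is ≤ tol (default 1e−4) or after max_iter
(default 300); an empty cluster is repaired by moving its centroid onto
the intensity farthest from its current centroid; a pixel equidistant to
two centroids joins the lower-indexed cluster.

**Fuzzy C-means.** Standard FCM with fuzzifier m = 2 (configurable, m > 1):
memberships u_ik = 1 / Σ_j (d_ik/d_ij)^(2/(m−1)), centroids as
u^m-weighted means, stopping when the largest membership change is ≤ tol.
The ratio form of the membership update is used for numerical stability at
small m (an overflowing ratio only drives a far cluster's membership to 0).
A pixel coinciding exactly with a centroid receives full membership in that
(first such) cluster, avoiding division by zero. Hard labels are the
membership argmax. Published variants of FCM with additional modifications
exist; this package implements the standard algorithm, so numeric agreement
with any particular modified variant is not claimed.

**Canonicalization.** Clusters are always reported in ascending-centroid
order, so cluster i means "the i-th darkest compartment" in every image —
without this, feature index i would not be comparable across images and no
classifier could learn from the counts. Renderings map pixels to their
centroid (grayscale) or to a fixed K-step HSV hue wheel (color), so
segmentation images are reproducible byte-for-byte.

## Features

The feature vector of one ROI is (n₁, …, n_K), the pixel count of each
canonical cluster; counts always sum to the pixel count (120,000 for the
standard ROI). Tables are persisted as tab-delimited DAT text with a header
`id c1..cK label` and `?` for a missing label; counts are stored raw —
normalization is the classifier's concern.

## Classifiers

All three operate on the count vectors; the class order is fixed
(nonosteoporosis, osteoporosis) and prediction ties resolve to
nonosteoporosis — the conservative choice for a screening tool.

- **Decision tree** (C4.5 family): numeric splits at midpoints between
  consecutive distinct feature values, chosen by information gain ratio
  among candidates with positive gain; growth stops at pure nodes or when
  a child would fall below min_leaf (default 2); pessimistic-error pruning
  with confidence 0.25 (Wilson upper bound on the leaf error rate) is on by
  default. Exactly symmetric XOR-type layouts have zero gain on every
  split and yield a majority leaf — an inherent property of gain-guarded
  top-down induction.
- **Gaussian naive Bayes**: class priors by frequency, per-class
  per-feature means and variances; variances floored at 1e−9 × the mean
  overall feature variance so constant (degenerate) clusters do not produce
  singular densities.
- **Multilayer perceptron**: K → K → ⌈K/2⌉ → 2, sigmoid throughout,
  half-squared-error loss, per-sample stochastic backpropagation with
  learning rate 0.3 and momentum 0.2 for 500 epochs (defaults). Inputs are
  normalized to [0,1] by dividing each count vector by its total — raw
  counts up to 120,000 would saturate the sigmoids immediately. Weights and
  biases initialize uniformly in [−0.5, 0.5] from one seeded generator that
  also drives the per-epoch shuffle, so training is bit-reproducible. The
  hidden sizes and epoch count are package defaults chosen to scale with
  the feature dimension; on separable toy data the net may need more than
  the default epochs to reach 100 % training accuracy, depending on the
  initialization seed.

## Evaluation protocol

Osteoporosis is the positive class: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/total, reported in percent to
two decimals. Two reporting conventions are supported because published
clinical tables are not always internally consistent: round-half-up
(default) and truncation (20/22 → 90.90 instead of 90.91). On a
class-balanced split, accuracy = (sensitivity + specificity)/2 exactly.

The *average performance* of a (segmentation, classifier) pair is the mean
of its 3 metrics × |K list| cells; the *global performance* of a
segmentation method is the mean over all its classifiers' cells. Both are
computed from the unrounded cell mean and then rounded, avoiding compounded
rounding error.

Model selection follows the train/test protocol: every (segmentation, K,
classifier) combination is trained and scored on the training split; the
highest training accuracy wins (ties: higher sensitivity, then lower K,
then configuration order); only the winner is evaluated on the test split.

## Phantom generator

Each phantom emulates the statistical structure the pipeline relies on, not
X-ray physics. White Gaussian noise is smoothed with a Gaussian kernel of
scale `correlation_length` (default 3 px — the trabecular texture scale),
thresholded at the `porosity` quantile (so the pore fraction hits the
target exactly, up to integer rounding, before degradation), pores darkened
by `pore_darkness` (default 60 intensity units below the trabecular level
of 170), then blurred (`blur_sigma` = 0.8 px) and corrupted with additive
Gaussian noise (`noise_sd` = 8) to emulate the noisy, blurred, dark
character of dental radiographs. Intensities are rounded and clipped to
0–255. Class defaults: porosity 0.25 (nonosteoporosis) vs 0.45
(osteoporosis), giving a mean-intensity gap of ≈12 units.

Per-image seeds derive deterministically from (cohort seed, class, index),
so cohorts are reproducible and extensible without disturbing existing
images.

What the phantoms do **not** capture: anisotropic trabecular architecture,
cortical bone, tooth roots, periapical lesions, scanner-specific noise
spectra, exposure variation, and inter-patient anatomical variability. At
the default porosity separation the two classes are easily separable, so
near-perfect phantom accuracies demonstrate that the pipeline's plumbing
and learning machinery work end to end — they do not predict clinical
performance on real radiographs, where reported accuracies are far from
100 %.

## Numerical and design choices

- Grayscale conversion uses BT.601 luma weights (0.299, 0.587, 0.114),
  round-half-up; ROI coordinates are 0-based (row, col), top-left origin,
  half-open windows, corner-anchored.
- The standard ROI is 300×400 (height × width); all window sizes are
  configurable for testing.
- The exact K-means DP pads with duplicate top centroids (empty clusters)
  when an image has fewer distinct intensities than K, keeping the feature
  length at K.
- Experiment problem sizes: the shipped demo uses 16 train / 12 test
  phantoms at K = 10; the full configuration reproduces the study shape
  (60 train / 42 test, K ∈ {8, 10, 12, 15}, both segmenters, three
  classifiers) and runs in well under a minute on one CPU.

## Known limitations

- Standard FCM only; no spatially regularized variants.
- No cross-validation, ROC analysis, or significance testing — evaluation
  mirrors the single train/test protocol described above.
- The MLP uses squared error with sigmoid outputs (the classical
  configuration) rather than softmax/cross-entropy.
- Phantom realism limits are listed above; phantom parameters are
  calibration-free stand-ins, as no quantitative texture statistics of the
  original radiographs are available.
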