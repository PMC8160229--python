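# Methods

## The classification framework

`gliograd` implements a two-phase, gradient-based classifier for aligned 3D
structural brain MRI, aimed at two binary tasks: separating lesioned from
healthy brains (detection) and separating two lesion texture classes
(grading, emulating high- versus low-grade glioma).

**Inputs and preprocessing.** Volumes must already be spatially registered to
a common template, so that voxel (and cell) positions are anatomically
comparable across subjects; the package performs no registration itself.
Intensities are standardized per volume: z-score over all voxels
(population standard deviation, divide-by-N), clipping of z to [−4, 4], and
linear rescale to [0, 1]. Statistics use every voxel by default; a
`mask_nonzero` option restricts them to nonzero voxels for data whose
background air is exactly zero. Per-cell descriptors are invariant to the
affine part of this rescaling; the clip bounds only matter for extreme
outlier voxels.

**Descriptors.** Each volume is sliced along a configurable axis (default
the third axis, axial for typical acquisitions). Each 2D slice is divided
into a dense, origin-anchored, non-overlapping grid of square cells of side
`cell_size` (trailing partial cells discarded, so the grid is identical for
every subject of an aligned cohort). Per pixel, gradients are computed with
the 1-D kernel (−1, 0, 1) per axis (one-sided at borders); per cell, a
histogram of N = 8 signed orientation channels (centers at k·45°) is
accumulated with magnitude-weighted votes, bilinearly interpolated between
the two nearest channel centers by default (`hard` nearest-center voting is
available and is what the brute-force oracle tests pin down). Background
cells with zero gradient produce the zero histogram, keeping descriptor
length constant across subjects. A subject is the ordered concatenation of
all cell histograms, slice-major then row-major: P = m·R·Q cells of N
numbers.

**Histogram normalization is off by default.** `l2` and `l2hys` per-cell
normalization are implemented, but the default is `none`: the phenomenon
this method targets is *abnormal gradient energy* (lesions add edges and
internal texture), and per-cell normalization discards exactly that
magnitude information. On the synthetic cohorts this is decisive — with
per-cell L2 the detection CV tops out near ACC 0.80, with raw magnitudes it
is ≈ 0.95 under identical conditions. Normalization remains available for
data with illumination-like nuisance, where the trade-off can reverse.

**Phase 1 — per-position fuzzy C-means.** At every cell position p, the
training subjects' descriptors form one small point cloud; fuzzy C-means
(FCM) with K = 2 clusters and fuzzifier m = 2 partitions it softly,
minimizing J = Σᵢ Σₖ u_ik^m ‖xᵢ − v_k‖² with row-stochastic memberships.
Updates alternate the weighted centroid mean and the closed-form membership
u_ik = 1/Σⱼ(d_ik/d_jk)^{2/(m−1)}; a point coinciding with a centroid takes
full membership there; convergence is max |Δu| < 1e−5 (cap 300 iterations);
3 seeded random restarts keep the best objective. All P positions are fitted
as one batched computation with an active-set convergence mask. A pooled
`global` scope (one FCM over all positions) is provided for study; on the
synthetic cohorts it carries no signal, because the informative comparison
is *across subjects at a fixed position*, which is also the reading the
per-position default follows.

Cluster identity is arbitrary, so a deterministic convention designates the
feature cluster: clusters are ordered by descending centroid norm, and the
membership of the first cluster is the feature. Any stable convention is
equivalent — the phase-2 linear SVM learns a sign per position — it must
only agree between training and prediction. Positions whose training
descriptors are all identical, or whose fitted centroids coincide, are
flagged degenerate and always emit membership 0.5 (no information, constant
vector length).

At test time the default `soft` mode evaluates the FCM membership formula
against the frozen centroids, producing a continuous probability like the
training features; `hard` mode implements literal nearest-centroid 0/1
assignment (ties to the designated cluster). Feeding the SVM hard labels at
test time while training on soft memberships would distribution-shift the
classifier, hence `soft` is the default.

**Phase 2 — SVM and localization.** The P-dimensional membership vector is
the subject-level feature for an SVM (linear kernel, C = 1, balanced class
weights; rbf available). The baseline comparator concatenates all raw
histograms (P·N dimensions) into the same SVM. For the linear kernel the
primal weight vector w (one weight per cell position in the two-phase mode)
is materialized; |w_p|, thresholded or top-k, painted over each kept cell's
pixel footprint on its slice, yields a discriminant map in native voxel
space, written as NIfTI. A decision score of exactly zero predicts the
positive class.

**Evaluation.** Repeated stratified k-fold CV with subject-level splits:
within each class, subjects are shuffled with the run's seed and dealt
round-robin, so per-class fold counts differ by at most one. For every
(cell size, run, fold), phase 1 and the SVM are fitted strictly on the
training folds; descriptor extraction is split-independent and shared. ACC,
SEN and SPE come from fold confusion counts; AUC is computed per run from
the pooled out-of-fold decision scores (stabler than per-fold ROCs at
double-digit cohort sizes; a per-fold mode exists). Mean and SD are across
runs. The single printable confusion matrix per cell size is the
element-wise median across runs of per-run fold-summed counts, rounded —
one of several defensible aggregations; it is recorded in the output
manifest. All nested seeds derive from one master seed via SHA-256 hashing,
making every number in a report bit-reproducible.

## The synthetic cohorts

The generator provides aligned phantoms in which the *gradient structure*
is controlled, since gradients are what the method measures: an ellipsoidal
"brain" (semi-axes 0.42 of each dimension) of uniform tissue intensity 100
on a zero background, global Gaussian noise (sd 5, SNR ≈ 20 — conservative
for modern 3T acquisitions), and an optional bright spherical lesion
(+60 by default). Lesion variants:

* `smooth_bright` — constant plateau: edge gradients only (low-grade
  analogue);
* `rough_bright` — plateau modulated multiplicatively by a seeded, spatially
  correlated random field (white noise smoothed with σ = 1.5 voxels, unit
  variance, relative amplitude 0.8): strong heterogeneous internal
  gradients (high-grade analogue). The amplitude is the separability dial:
  the between-class difference in mean in-lesion gradient magnitude is
  strictly monotone in it.

Across a cohort, lesion centers jitter by ±10% of each dimension and radii
by ±20% (rejection-sampled to stay inside the brain), so boundary cells see
both lesioned and unlesioned descriptors — the ambiguity soft clustering is
meant to absorb. Per-subject seeds derive from the cohort seed; identical
specs give bit-identical volumes, and NIfTI output is byte-deterministic.

**Geometry choices.** The default 60×60×12 slab emulates thick-slice axial
clinical acquisitions; it caps the inscribable lesion radius at ≈ 5 voxels,
so the default radius is 4. Such a lesion is nearly all edge, which suits
detection but leaves no interior for texture: the grading study therefore
uses a 64×64×32 volume with radius-9 lesions, where interior cells exist at
cell size 10.

**Two auxiliary cohorts.**

* *Null cohort* — lesion-free phantoms with randomly permuted labels, the
  pipeline's negative control. Repeated CV runs on one fixed null cohort
  share that cohort's chance correlations (per-cohort null CV AUC has
  sd ≈ 0.13 at n = 20+20), so the null check averages over independent
  cohorts, not runs.
* *Texture-organization cohort* — both classes carry identical lesion
  plateaus plus internal texture normalized to the same mean gradient
  magnitude; they differ only in texture *organization*: spatially coherent
  anisotropic ridges along a random per-subject orientation (class 1)
  versus isotropic texture (class 0). Because the dominant histogram bins
  are random per subject, the class signal is *radial* in descriptor space:
  no fixed linear weighting of raw bins separates the classes, while the
  distance-based membership ("far from the normal cluster in any
  direction") captures it. This is the regime in which the two-phase
  transform demonstrably beats raw concatenation (CV AUC ≈ 0.78 vs ≈ 0.69
  at the sizes below); on simple energy-difference phantoms the baseline is
  at least as good, because an energy signal is already linear in histogram
  space.

**What the phantoms do not model.** No anatomy (tissue classes, sulci,
skull), no partial-volume or bias-field effects, no Rician noise, no
registration error. Passing tests therefore demonstrate the machinery —
descriptor correctness, leakage-free evaluation, the geometry of when
membership features help — not clinical performance; cohort sizes
(15–20 per class) and volumes are chosen so the full suite runs on one CPU
in minutes.

## Study conditions used by `scripts/acceptance.py`

* Detection: 20+20 subjects, 60×60×12, cell size 10, 3×10-fold CV.
* Null control: 5 independent lesion-free cohorts of 20+20, 1×10-fold each.
* Grading: 15 rough + 15 smooth, 64×64×32, radius 9, cell size 10,
  3×10-fold CV.
* Method comparison: 5 texture-organization cohorts of 15+15, 40×40×40,
  radius 10, cell size 8 (P = 1000 cells), 1×10-fold per method.
* Localization: 20+20 detection cohort with jitter disabled; fraction of
  the top-10 |w| cells whose footprint intersects the true lesion mask.
* Descriptor oracle: max deviation between module histograms and a naive
  per-pixel loop over 20 random slices (exactly zero up to float error).

## Numerical conventions

* Population (divide-by-N) standard deviation in z-scoring.
* Gradient kernel (−1, 0, 1) without the ½ factor; one-sided borders.
* Zero-gradient pixels take direction 0°; angular ties in hard voting go to
  the lower channel index (argmin order).
* FCM coincidence threshold d² < 1e−24; degeneracy spread threshold 1e−12;
  centroid-coincidence flag below 1e−9 separation.
* SVM decision ties (score exactly 0) predict class 1.
* Aggregate SD uses ddof = 1 across runs (0 when a single run).

## Known limitations

* K > 2 clusters are mechanically supported but the membership vector keeps
  only the designated cluster's probability, which loses information for
  K > 2; the framework is intended for K = 2.
* The rbf kernel offers no weight back-projection, hence no discriminant
  maps.
* Per-position FCM with very few training subjects (< ~10 per fold) is
  noisy; restarts mitigate but do not remove this.
* The membership transform discards within-cluster magnitude detail; on
  tasks whose signal is purely a gradient-energy difference, the raw
  concatenation baseline can match or exceed it (see the texture-
  organization discussion above).
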