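# Methods

## Scope and assumptions

The package classifies two-class neuroimaging cohorts (patients vs
healthy controls) from volumetric texture. It assumes volumes arrive
already motion-corrected, spatially normalised to a common grid and
smoothed — the canonical grid is 79×95×68 voxels of 2 mm with origin
(−78, −112, −50) mm — and therefore implements no spatial registration
of its own. Arrays are used in stored (x, y, z[, t]) order without
reorientation; gradient differences are taken in voxel-index units, so
anisotropic voxel sizes are not rescaled to physical units.

## Preprocessing

Intensities are standardised per subject: one global mean and SD over
every voxel (and every time point, for 4D scans), then z-scored. This
removes site- and scanner-specific intensity scaling; it deliberately
does **not** mask background voxels, so air voxels participate in the
moments. Z-scoring precedes temporal averaging, matching the order in
which the two steps are conventionally applied; the two commute up to
an affine rescaling, and the mean of a z-scored scan's time-average is
exactly zero. Constant (zero-variance) images are rejected rather than
mapped to zeros — silent zeros would propagate meaningless descriptors
downstream. SD is compared against `1e-12·max(1, |mean|)` rather than
exact zero because a constant image's computed SD is accumulation
round-off.

## 3D HOG descriptor

Gradients are central differences `(f(·+1) − f(·−1))/2` per axis;
boundary voxels have no central difference and are excluded. Each
voxel's gradient is assigned by hard argmax of the cosine overlap
`α(g, b) = g·b/(|g||b|)` over the direction set — all 3^D − 1 nonzero
offset vectors with components in {−1, 0, 1}, in lexicographic order
(8 in 2D, 26 in 3D). Ties take the lowest index in that fixed order;
zero-gradient voxels contribute to no bin (α is undefined there). Hard
assignment, rather than the soft trilinear interpolation of classic 2D
HOG implementations, is used because the argmax formulation is the
one being reproduced.

Cells are 8³ voxels (derived from blocks of 16³ voxels containing
2×2×2 cells); trailing partial cells are discarded by floor division,
which on the canonical grid yields a 9×11×8 cell grid. Blocks of 2×2×2
cells are taken at a stride of one cell — the only stride consistent
with the 116,480-feature total on the canonical grid (8×10×7 = 560
blocks × 208 values). Each block vector is normalised by
`v → v/√(‖v‖₂² + ε²)` with ε = 10⁻⁵ by default (configurable); no
re-normalisation or clipping (L2-Hys) follows, since only the single
formula is specified. Every normalised feature lies in [0, 1).

Feature layout is fixed and documented so indices are invertible:
blocks in x-fastest grid order, cells within a block in the same
order, orientation bins innermost. `map_feature_to_space` returns the
geometric centre of a feature's 16³-voxel block in voxel and mm
coordinates (mm = origin + voxel_size ⊙ index).

## mRMR ranking

Mutual information uses the plug-in estimate from empirical joint
frequencies, in bits — no bias correction, since only the ranking
matters, not the MI values. Continuous features are discretised into
three states at mean ± SD (sample SD, inclusive thresholds), the
scheme of the original mRMR software; already-discrete columns with at
most three integer levels pass through. The greedy criterion is the
difference (MID) form, relevance minus mean redundancy, the canonical
default; the quotient (MIQ) form is available via `mrmr_variant`. Ties
break to the lowest feature index for determinism. The ranking has the
prefix property: the top-k list is a prefix of the top-(k+1) list.

## Learner bank

Thirteen base learners in fixed order: linear SVM; RBF SVMs with
σ = 1…9 under the convention K(u,v) = exp(−‖u−v‖²/(2σ²)) (so
scikit-learn's γ = 1/(2σ²)); Gaussian naive Bayes; CART decision tree
at default depth; KNN with k = 5. SVM cost C = 1. KNN k, tree depth
and C are not dictated by the procedure being reproduced and use these
documented defaults. SVMs and KNN standardise features with
training-fold statistics inside the estimator pipeline, so no
test-fold information reaches the scaler.

## Selection procedure

Folds are one seeded, class-stratified 5-way partition computed once
per run and reused for every (learner, k) pair, so all records are
comparable. Features are added one at a time in mRMR order; each
learner's best CV mean so far is tracked, and the loop stops when no
learner has improved for `patience` = 20 consecutive additions
(interpreting "no accuracy increase in any learner" as a plateau
criterion — the CV curves are non-monotone, rising to an interior peak
before declining — a one-step test would stop almost immediately), or
when k reaches `k_max` = min(d, 1000) with a warning. Per learner the
visited k with the largest mean is kept; the five learners with the
largest best means are retained (ties at the fifth place break to
smaller feature-set size, then bank order); the winner is the retained
learner with the smallest fold range, ties again to bank order. The
winner is refit on the whole training set restricted to its feature
set, and scored once on the hold-out subjects.

The mRMR ranking is computed on the full training set before
cross-validating on that same set, as the procedure prescribes; this
leaks feature-selection information into the CV estimates (the
hold-out evaluation remains clean, since the hold-out set touches
nothing at training time — verified by a poisoning test). A strict
variant that re-ranks features inside each training fold is available
(`strict_per_fold=True`), off by default.

Sensitivity and specificity need a "positive" class; the default is
the healthy-control label (0), the convention under which published
confusion arithmetic of this kind is self-consistent, and it is
configurable.

## Phenotypic tables

Handedness: positive signed scores → 1 (right), negative → 0 (left);
already-categorical 0/1 passes through (auto-detected for columns);
a signed score of exactly 0 (ambidextrous) maps to 1 with a warning,
configurable, since the sign rule does not cover it. Columns missing
for ≥30% of subjects are dropped (ids and labels are protected).
Remaining numeric gaps are mean-imputed; categorical gaps take the
mode, since a mean is undefined there. Sex and eye status are encoded
0/1; site as a single integer code (a one-hot option exists) —
treating site as one feature matches numeric-feature toolchains, and
which encoding is "right" is genuinely open. Diagnosis-related columns
(symptom scores, medication status) are removed by an explicit
blocklist before anything else.

## Synthetic cohorts

`generate_volume` produces white Gaussian noise (SD `noise_sd`); the
patient class additionally carries a sinusoidal grating along (1,1,0)
with an 8-voxel wavelength, a per-subject uniform random phase, and
amplitude `effect`, confined to the central half of the volume per
axis. A grating was chosen because HOG is by construction sensitive to
oriented gradients: its gradient field points along ±(1,1,0), so the
class signal lands in two specific orientation bins of the central
blocks. `effect = 0` gives an exact null (both classes identically
distributed). One global seed fans out to per-subject streams
`(seed, index)`, so cohorts extend without regenerating. Phenotypic
tables emulate multi-site metadata (age, sex, signed handedness, IQ
with planted missingness, 4 sites, eye status).

What the generator does **not** emulate: brain morphology, spatial
intensity structure, site/batch effects, haemodynamics, or correlated
noise. Passing recovery tests therefore shows the pipeline detects
oriented-texture class differences at realistic sample sizes — not
that it reaches any particular accuracy on real cohorts.

## Problem sizes and numerical choices

Tests and the recovery checks run cohorts of 100 subjects per class on
32³ grids (27 blocks → 5,616 features per subject) with effect 3× the
noise SD for signal cohorts, a 20% hold-out, `patience` = 5 and
`k_max` = 15 — sizes at which the selection visits every learner
across the useful range of k while each end-to-end run stays in the
seconds range. The monotonicity sweep uses 50 subjects per class over
effects {0, 1, 2, 3}× noise SD, three seeds each. The null-control
check uses the 95% binomial interval of chance accuracy at the
hold-out size (±15.5 points at n = 40).

Worked-example tolerance: the printed magnitude 27.22 of the 2D
gradient example is √741.25 = 27.2259 truncated to two decimals, so it
is checked to |Δ| < 0.01 rather than by rounding.

## Known limitations

- No masking: background voxels contribute to z-score moments and
  (zero-gradient aside) to cell histograms.
- Anisotropic voxels are not unit-corrected in gradients.
- The plug-in MI estimator is biased upward at small n; adequate for
  ranking, unsuitable for reporting MI values.
- mRMR is O(d) per selected feature with a Python-level loop over
  columns; fine up to ~10⁵ features, not tuned beyond that.
- The selection's CV means are optimistically biased (feature ranking
  sees the CV data); trust only the hold-out numbers, which are
  computed on subjects untouched at training time.
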