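# Methods

`stablerec` implements an early-prediction pipeline for three-year breast
cancer recurrence (BCR) in patients treated with neoadjuvant chemotherapy
(NACT), using paired DCE-MRI examinations: one pre-treatment exam (T1) and
one early-treatment exam (T2, after the first chemotherapy cycle). The
prediction target is the binary recurrence-free-survival indicator — RFSi
(no recurrence within three years of chemotherapy initiation) versus
non-RFSi (recurrence), with non-RFSi as the positive class.

The pipeline has five stages: ROI standardization, low-level convolutional
feature extraction, dynamic (resampling-based) feature selection, optimal
subset construction, and linear-SVM classification with optional clinical
covariates (age, ER, PgR, HER2 positivity). This note records the model
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## ROI standardization

Input per patient and timepoint: a 2D grayscale slice, a binary lesion
mask, and the tumor's largest diameter (LD) in pixels. Callers holding LD
in millimetres convert with the pixel spacing from the image header —
physical-unit handling stays at the I/O boundary.

1. The tumor center is the centroid of the largest 8-connected foreground
   component of the mask, rounded with ties toward the lower index.
2. A square window of side LD is cropped around the center (0-based,
   half-open `[r0, r0+LD)`, `r0 = center − LD//2`). A window crossing the
   slice boundary is shifted inward; only if LD exceeds the slice itself is
   the slice edge-padded symmetrically. Shifting is preferred to padding
   because it keeps real tissue in the window.
3. The crop is resized to 227×227 by bicubic interpolation. The kernel is
   fixed to the Keys cubic-convolution kernel (a = −0.5), half-pixel-center
   grid mapping, no anti-aliasing. "Bicubic" names a family of dialects
   (Keys vs B-spline, with or without anti-aliasing, different grid
   alignments); fixing one in code makes the preprocessing reproducible to
   the bit. Cubic interpolation can over/undershoot the input range by a
   bounded amount (≤ ~10% of the range; tested); downstream per-image
   min-max scaling makes this harmless.

## Feature extraction (pool2 transfer descriptor)

Each 227×227 ROI passes through the first two stages of an AlexNET-style
convolutional network:

    227 ─conv 11×11×96 /4─► 55 ─ReLU, LRN, maxpool 3×3 /2─► 27
        ─conv 5×5×256 pad 2─► 27 ─ReLU, LRN, maxpool 3×3 /2─► 13×13×256

The flattened second-pooling output gives 43 264 features per ROI and
86 528 per patient (T1 block then T2 block, channel-major flattening; the
convention is stored in output metadata so indices stay portable). These
are low-level features — lines, edges, blobs — chosen deliberately over
late-layer features: they respond to the local structure of the lesion
(margins, internal texture) rather than global object identity, and being
taken after pooling they inherit translation tolerance.

Local response normalization uses the original AlexNET constants (depth 5,
α = 1e−4 applied to the raw window sum of squares, β = 0.75, k = 2).
Grayscale ROIs are min-max scaled to [0, 255], replicated to three
channels, and centered to [−1, 1] (`input_scaling` is a backend property;
this is the recorded default since MRI intensity scaling ahead of a
network pre-trained on photographs has no canonical answer).

Backends supply the convolution weights behind a small protocol. The
shipped backend draws filters from a seeded Gaussian: random convolutional
filters are themselves a recognized family of low-level feature extractors
(random projections of local patches followed by rectification and
pooling), they exercise the identical architecture and satisfy the same
contracts — dimensionality forced by the layer chain, non-negativity,
determinism, receptive-field geometry — and they keep the repository fully
reproducible offline. Every selection and classification component is
agnostic to which backend produced the matrix. Feature indices map back to
(channel, row, col) positions and to receptive-field rectangles on the ROI
(size 67, stride 16, computed by the standard recurrence over the layer
chain and clipped to bounds), which powers the activation-map and
receptive-field visualizations.

## Dynamic feature selection

Selection hunts for features that are *stable* under perturbation of the
training sample, per held-out patient (leave-one-patient-out, LOO):

- per iteration, 10 class-stratified random subsets are drawn, each with
  90% of the training patients per class (rounded up, preserving the
  severe class imbalance);
- each subset applies a two-sided Wilcoxon rank-sum filter at p < 0.001
  (raw cutoff, no multiple-testing correction — the stability machinery
  is what controls false selections), then the forest-based embedded
  criterion below;
- the 10 per-subset selections are unioned into the iteration set, and
  iteration sets are intersected cumulatively across iterations (so a
  feature must reappear in every iteration's union to survive);
- all folds advance in lockstep; iteration stops when fewer than 10
  features were discarded between consecutive iterations for ≥ 95% of
  folds, or at 20 iterations. (Whether the original stopping rule was
  evaluated in lockstep or per fold is ambiguous; lockstep is the default
  and a per-fold variant sits behind `per_fold_stopping`.)

Rank-sum p-values are exact when both class sizes are ≤ 12 and the column
is tie-free (a cached dynamic program over the exact U distribution,
validated against full enumeration); otherwise the normal approximation
with midranks, tie-corrected variance and continuity correction. Constant
columns carry no information and get p = 1.

The **optimal subset of features (OSF)** is the patient-by-patient
intersection of all per-fold cumulative sets: what survives every
resampling, every iteration, and every fold. Each set carries provenance
(the patient ids that influenced it), which the evaluation stage uses as a
leakage guard.

A feature must appear in the union of every one of roughly
`n_folds × n_iterations` (~200+) resampling rounds to enter the OSF, so
per-round retention probabilities are raised to a large power: retention
≈ 1 for genuinely informative features and ≈ 0.99 for borderline ones are
separated into OSF probabilities of ~1 versus ~0. This cliff is what makes
the construction at once powerful and self-calibrating, and it dictates
the embedded-criterion design below.

### The embedded criterion and its threshold

The filter's survivors are re-ranked by a 100-tree bootstrap CART forest
using Gini importance (mean decrease in impurity, per-tree normalized and
averaged, the standard convention). The threshold applied to those
importances is the one genuinely open design choice of the whole
procedure, and the naive reading — keep features *strictly above the mean
importance* — interacts badly with the filter: at p < 0.001 the survivor
pool is almost exclusively informative features, per-tree importances are
normalized so the pool mean is exactly the uniform share 1/K, and an
above-mean cut permanently discards the weaker half of a uniformly
informative pool (measured directly: ~0.4 of planted features recovered;
sklearn's forest shows the identical above-mean split). Greedy split
choice compounds this: with many strong candidates, importance measures
"frequency of winning the argmax", concentrating mass on the few strongest
realized effects.

The shipped criterion therefore differs in three deliberate ways, each
exposed in `SelectionConfig`:

- `forest_max_features` adapts to the pool: `max(1, K // 20)` candidates
  examined per node. Small, uniformly informative pools (the strict-filter
  regime) get totally randomized split choice — importance then measures
  each candidate's *marginal* strength rather than its greedy win
  frequency, so equally informative features rank comparably. Large pools
  (loose filters, redundant features) get greedy concentration, so the
  same consistently strongest features are kept across resamples instead
  of a random thinning that the downstream intersections would annihilate;
- `mean_fraction = 0.5`: keep candidates with importance above half the
  pool mean — the whole informative cluster survives while features near
  the noise floor still fall out;
- `min_candidates = 4`: pools smaller than four candidates are rejected
  outright. An importance ranking over a couple of features carries no
  ensemble evidence, and tiny pools are precisely the signature of
  chance survivors: under label permutation the filter passes a Poisson(2)
  handful of columns per subset, and rejecting those pools lets the
  stacked intersections annihilate them.

Calibration of this default at study scale (96 patients, 26/70 split,
2000 surrogate columns, 20 planted at 2 SD): the OSF recovers 20/20
planted columns with zero noise columns, and under label permutation the
OSF is empty in every studied run. The strict reading remains available
(`mean_fraction=1.0, forest_max_features=None, min_candidates=1`), as does
a fixed-count rule (`importance_rule="top_k"`).

The forest itself is a purpose-built numba kernel (bootstrap, full-depth
CART, midpoint thresholds, per-tree normalized Gini importance): the
resampling loop refits the forest tens of thousands of times on small
matrices, where a general estimator's per-fit overhead exceeds the actual
tree-building work by two orders of magnitude. A unit test pins its
importance ranking to sklearn's `RandomForestClassifier` on planted data.

## Classification and evaluation

A linear-kernel SVM (C = 1, unweighted classes; C surfaced in config)
classifies patients from the selected CNN columns, optionally augmented
with the four clinical covariates. CNN columns and age are z-scored by
training-fold statistics (linear SVMs are scale-sensitive, and CNN
activations and ages live on very different scales); binary indicators
pass as 0/1; zero-variance training columns are dropped with a warning.
Standardization is refit inside every training fold — never on held-out
or test patients.

Evaluation modes:

- **LOO on the fine-tuning cohort**, with either the per-fold dynamic sets
  (DSF) or the fixed OSF; held-out decision values are pooled into one
  ROC/AUC and one confusion matrix at decision threshold 0 (per-fold
  standardization refit is the leakage-safe reading; pooling is the
  recorded convention for the single reported ROC).
- **Independent test**: one SVM fit on the full training cohort, scored on
  patients whose ids are checked against the OSF's provenance — any
  overlap raises a leakage error instead of producing a number.

Metrics: accuracy; sensitivity = recall of non-RFSi; specificity = recall
of RFSi; AUC by the rank-based (Mann-Whitney) estimator with midrank ties,
which equals the trapezoidal area under the pooled ROC (asserted to 1e-12
in tests). An empty feature set (possible when selection annihilates
everything and no clinical block is used) yields constant decision scores,
hence AUC 0.5 — the honest "no information" answer.

## Synthetic cohort generator

The generator emulates the statistical skeleton of the study data so every
stage is testable without any download. Per patient it produces T1/T2
slices, masks, an LD value, clinical covariates and the recurrence label.

Lesion model: a rotated anisotropic ellipse (axis ratio 0.65–1.0) with a
sigmoidal edge profile and band-limited Gaussian texture, plus i.i.d.
intensity noise (`noise_sd`, default 0.02 against a lesion amplitude of
~0.65). The class is encoded in exactly two latent properties:

- **T1 edge sharpness**: edge width 3·exp(∓`t1_effect`/2) px (non-RFSi
  sharper), with per-patient lognormal jitter. This puts the class signal
  in the local margin structure that early convolutional features detect.
- **T1→T2 response**: shrink factor 0.20·(1 ± `t2_response_effect`/2)
  (RFSi tumors respond more), with proportional contrast loss.

With both effects zero the class-conditional image distributions are
identical — the null condition used for calibration tests. With a large
`t1_effect` a hand-computed statistic (mean interior minus mean rim
intensity) separates the classes with AUC > 0.9 before any CNN is
involved, so the planted signal is real rather than an artifact of the
extractor.

Clinical covariates are drawn from class-conditional distributions whose
defaults are the observed rates of the emulated study population
(43 non-RFSi / 115 RFSi): ER+ 12/43 vs 66/115, PgR+ 14/43 vs 53/115,
HER2+ 17/43 vs 26/115; age normal 47.21 ± 8.67 vs 48.86 ± 8.96 years,
truncated to [18, 90]. The default cohort size and class fraction mirror
the fine-tuning composition (96 patients, 26/96 recurrence). The
class-conditional distribution of LD is not asserted (no reliable source
value); it emerges from the configured lesion diameter range, exposed in
config.

Labels are assigned deterministically (the first
`round(recurrence_fraction·n)` patients are non-RFSi) and each patient
draws from a stream keyed by (seed, patient index), so patient *i* is
identical across cohorts of different size and every cohort is bit-
reproducible from its seed.

A separate surrogate-feature generator produces the selection-stack test
bed: standard-normal columns with a planted block shifted by `effect` SD
in the non-RFSi class (default 2.0 — a strong but realistic marker; the
procedure's own design point, a p < 0.001 filter expected to pass a
feature in essentially every 90% resample at n ≈ 90, implies single-
feature separations of this order).

What the generator does **not** emulate: 3D volumes, contrast-kinetic
(pharmacokinetic) enhancement curves, scanner/site effects, segmentation
error, correlated feature structure of real CNN descriptors. Passing tests
therefore demonstrate that the machinery is correct and calibrated — that
planted signal of the stated form is recovered and absent signal is not
invented — not that any particular AUC is attainable on clinical data.

## Problem sizes and numerical choices

- Tests and the acceptance script run the selection stack at the study's
  own scale (96 patients, 2000 surrogate columns) where the procedure's
  statistical behavior is the claim being tested, and scale the *image*
  pipeline down (10–14 patients, 2 iterations, 5 subsets, looser filter
  cutoffs matched to the attainable exact p-values at those class sizes)
  where only the plumbing is under test — end-to-end determinism, schema,
  timepoint masking, null calibration of the full image path.
- All randomness flows from one root seed through named substreams
  (cohort, per-patient, selection, backend); subset draws are keyed by
  (fold, iteration) so lockstep scheduling cannot reorder them.
- Ties in rank statistics: midranks with tie-corrected variance and
  continuity correction (matches the standard asymptotic convention);
  exact path only for tie-free columns with both class sizes ≤ 12.
- Degenerate inputs are errors, not silent defaults: empty masks,
  single-class cohorts, subsets with fewer than two patients per class,
  test sets overlapping selection provenance.
- The monotone-intersection invariant (cumulative per-fold sets never
  grow) is asserted inside `dynamic_selection` on every run.

## Known limitations

- The pretrained-weights backend is a protocol, not a shipped artifact;
  all shipped results use the seeded random-filter backend. Random filters
  are good low-level edge/texture detectors but are not ImageNet features;
  absolute performance numbers on real MRI would differ.
- CNN descriptors are highly redundant (neighboring pooled cells of the
  same channel are near-duplicates). At desk-scale cohorts the OSF
  intersection therefore typically annihilates even when the per-fold
  dynamic sets are strong — near-equal features tie-break differently per
  fold. A stable OSF core is a large-cohort, many-iteration phenomenon;
  small-scale demonstrations should use the DSF (per-fold) mode, and the
  OSF machinery is validated at study scale on the surrogate feature
  space, where planted effects are distinct rather than duplicated.
- LOO + lockstep stopping makes selection O(folds × iterations × subsets)
  forest fits; at 10^2 patients this is minutes on one core, but the
  procedure as specified is inherently quadratic-ish in cohort size.
- The stopping rule's original phrasing ("for 95% of the patients") is
  ambiguous; both readings are implemented, neither asserted as the
  authors' intent.
- AUC confidence intervals and survival-time modeling are out of scope.
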