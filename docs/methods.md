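# Methods

glioseg segments gliomas from co-registered, skull-stripped multi-modal
MRI (T1, T1ce, T2, FLAIR; T2 optional) without any training data or
annotations. The pipeline has two stages: a FLAIR-only whole-tumor mask,
and an intensity-clustering refinement of that mask into necrosis, edema
and enhancing tumor. This note records the model, the parameter choices,
the numerical conventions, and the deliberate deviations from naive
formulations — the things a maintainer would otherwise have to rediscover.

## Stage 1: whole-tumor masking

Each modality is first rescaled to [0, 1] by robust percentile bounds
computed over strictly positive voxels only (the skull-stripped background
stays at zero): values at or below the 2nd percentile map to 0, at or
above the 98th to 1, linearly in between, clamped outside. Percentiles use
linear interpolation between order statistics; this estimator is pinned so
tests can be exact. A degenerate window (p98 − p2 below tolerance, e.g. a
constant foreground) maps all positive voxels to 0 with a logged warning
instead of raising, so flat inputs do not abort batch runs.

Every 2D slice of the normalized FLAIR volume — in the axial, coronal and
sagittal planes independently — is binarized against a Sauvola local
threshold

    T(x, y) = m(x, y) · (1 + k · (s(x, y) / R − 1)),

where m and s are the mean and population standard deviation over a
W × W window. Defaults: W = 15, k = 0.5, and R = 0.5 — half the dynamic
range of [0, 1] data, the same ratio as the classical R = 128 on 8-bit
images. Windows use reflective (symmetric) border padding; the population
(not sample) standard deviation is pinned for oracle-exact tests. A voxel
is foreground iff its intensity strictly exceeds T.

Each binary slice is then refined: connected components of size ≤ S_min
are removed (8-connectivity; strict retention of sizes > S_min), followed
by a morphological opening with a radius-2 disk and a closing with a
radius-3 disk. S_min defaults to 64 pixels per slice — large enough to
remove speckle and punctate texture at 1 mm resolution, small enough to
keep genuine small lesions; it is exposed in the configuration.
Erosions treat the image exterior as foreground and dilations as
background, the standard finite-grid convention, so closing is extensive
and border objects are not eaten.

The three per-plane mask stacks are fused voxelwise. The default is the
strict logical AND (a voxel survives only if detected in all three
orientations); majority vote, OR, and single-plane (axial) are available
for ablation. Because the thresholding and 2D cleanup are computed
independently per orientation, plane-specific false positives are largely
decorrelated and the AND intersection suppresses them, while a genuine 3D
lesion is detected in every plane. An optional 3D cleanup (26-connectivity
component removal, spherical closing) can run after fusion; it is off by
default since the per-slice path already regularizes the mask.

**What adaptive local thresholding can and cannot separate.** On [0, 1]
data with k = 0.5 and R = 0.5 the threshold reduces to T = m·(0.5 + s):
a voxel is rejected only if it is darker than roughly half its local
window mean. Two consequences are worth stating explicitly. First, a
homogeneous region of any positive intensity is never rejected — after
percentile normalization a flat background sits about two noise standard
deviations above zero and T lies about one standard deviation below its
mean, so ~84% of such voxels always pass, whatever the intensity level.
Second, separation therefore requires local contrast: windows over
healthy tissue must contain structure bright enough to pull T above the
matrix level, with the bright structure itself small enough for the
small-object removal and opening to delete. The method is, in effect, a
detector of large homogeneous hyperintense blobs against a textured,
predominantly darker background. The phantom (below) is designed in
exactly this regime, and results on it should be read accordingly.

## Stage 2: subregion clustering

Voxels inside the whole-tumor mask are described by feature vectors of
per-modality normalized intensities (modalities in the fixed order T1,
T1ce, T2, FLAIR, absent ones omitted), z-scored per modality over the
masked region so each sequence contributes comparably. The mask's
bounding box is tiled with 5×5×5 windows at 50% overlap (stride 2, with a
final window per axis so the box is fully covered); a patch is emitted iff
it contains a masked voxel.

Within each patch, voxels are clustered by affinity propagation on the
similarity

    s(x_i, x_k) = − Σ_b |A_i^b − A_k^b| / σ_b,

the negative scale-normalized Manhattan distance (zero for identical
points; σ_b = 1 after z-scoring, but the division is kept so the formula
is also correct on raw intensities). The preference (self-similarity
controlling how readily a point becomes an exemplar) defaults to the
median off-diagonal similarity, shared by all points; per-point row means
are selectable. Responsibility and availability messages are exchanged
until the exemplar set is unchanged for 15 consecutive iterations or 200
iterations elapse. There is no random initialization and all ties resolve
to the lowest index, so the stage is fully deterministic.

**Message stabilization.** The updates are stabilized by a moving average
with a four-iteration effective memory rather than a separate damping
factor: each smoothed message is an exponential moving average with
weight 3/4 on the running value and 1/4 on the fresh raw update,
zero-initialized. Responsibilities are computed from the smoothed
availabilities and availabilities from the freshly smoothed
responsibilities. Two design points were settled empirically and are
binding: (a) a finite-window (FIR) average of raw messages is *not* a
contraction — on well-separated test mixtures it either applies the full
availability shock at the first iteration (locking every point into
self-exemplarship) or converges to suboptimal fixed points on small
candidate sets, whereas the exponential form recovers the generating
structure reliably; (b) the availability support sum must exclude the
recipient's own responsibility (a(i,k) sums max(0, r(k′,k)) over
k′ ∉ {i, k}) — letting a point's own vote return to it as availability
allows tiny candidate sets to self-certify and over-merge. Exemplar
identification uses the combined smoothed evidence r̂ + â (the standard
affinity-propagation criterion); selection on smoothed responsibility
alone degenerates to a single cluster under these dynamics. Convergence
stability is counted only once the exemplar set is nonempty, because the
zero-initialized ramp-up would otherwise satisfy any stability window.

Points whose evidence argmax is themselves are exemplars; every other
point follows its argmax, is redirected once through the target's own
choice if the target is not an exemplar, and finally falls back to the
most similar exemplar. If no point selects itself, the point with the
largest self-evidence becomes the single exemplar.

**Hierarchy.** Level-1 exemplars from all patches are pooled and
re-clustered by the same algorithm, repeatedly, until the exemplar set
stabilizes or three levels are reached; each voxel inherits the top-level
cluster of its chain of exemplars. Pools larger than 1,000 points are
re-clustered in deterministic contiguous chunks (bounding the O(L²)
message matrices); a chunked pass consumes one hierarchy level. A voxel
covered by several overlapping patches follows its chained exemplar when
all covering patches agree and otherwise joins the candidate exemplar
most similar to its own features (ties to the lowest voxel index) — a
deterministic, patch-boundary-free rule.

**Level selection.** Each hierarchy level yields a global candidate
partition, scored by

    score = inter / (1 + intra),

with intra the mean distance of each voxel to its cluster's exemplar and
inter the mean pairwise distance between exemplars (zero for a single
cluster), both in the σ-normalized Manhattan metric. Redundant
near-duplicate exemplars depress inter (their near-zero pairs dominate),
and over-merging inflates intra, so the score peaks at the balanced
partition; the argmax level is selected, ties to the shallowest. The
exact form of the published partition-validity criterion this stands in
for lives in secondary literature we could not pin down; the
intra/inter ratio above is this package's declared surrogate.

**Label assignment.** Each cluster's mean intensity profile per modality
is ranked, never thresholded: the cluster with the highest mean T1ce is
enhancing tumor; among the rest the highest FLAIR (averaged with T2 when
T2 is present) is edema; the remainder — jointly darkest on T1ce and
FLAIR — is necrosis. With more than three clusters, three anchors are
chosen by the same extremal ranks and every other cluster joins the
anchor with the nearest profile (σ-normalized Manhattan distance on mean
vectors). With two clusters only enhancing tumor and edema are assigned;
a single cluster is labeled edema as a whole-lesion fallback. These
cardinality fallbacks make every partition labelable and stay
rank-consistent. The composites follow the standard evaluation regions:
TC = enhancing + necrosis, WT = all three.

## Evaluation metrics

Dice = 2|P∩G|/(|P|+|G|), with the two-empty-masks case defined as 1.
HD95 is the maximum of the two directed 95th-percentile surface
distances, in mm using the voxel spacing; boundary voxels are mask voxels
with at least one non-mask 6-neighbor, and the percentile uses linear
interpolation. HD95 is undefined (NaN) when either mask is empty; recall
is undefined for an empty reference and precision for an empty
prediction. These discretization and degenerate-case conventions are
pinned so the brute-force oracle tests are exact.

## The phantom generator

The generator is the package's test bed: a brain-shaped ellipsoid
(default 64³ voxels at 1 mm isotropic, half-axes 27/25/23) containing a
concentric lesion — necrotic core (45% of the rim's half-axes) inside an
enhancing rim (half-axes 9/8/7) inside an edema shell (4 voxels margin).
Per-compartment mean intensities follow the standard radiological
signatures: enhancing tumor brightest on T1ce (0.90 vs ≤ 0.35), edema
brightest on FLAIR/T2 (0.90/0.85), necrosis jointly darkest on T1ce and
FLAIR (0.15/0.55); the spec validates these orderings so the rank-based
labeling is well-posed. Gaussian noise (σ = 0.02 by default, on the
[0, 1] scale) is added inside the brain; outside is exactly zero.

The parenchyma is a dark matrix (FLAIR 0.10) carrying punctate bright
speckles (FLAIR 0.45; ~3% seed density dilated to ~2-voxel blobs, the
same geometry in every modality). This is the contrast regime stage 1
requires (see above): every window over healthy tissue contains bright
texture that lifts the local threshold above the matrix level, while the
speckles themselves are destroyed by the small-object removal and the
radius-2 opening, and the large homogeneous hyperintense lesion survives
everything. The necrotic core is set FLAIR-brighter than parenchyma —
consistent with the convention that the whole FLAIR-hyperintense envelope
includes necrosis — so stage 1 captures the full lesion.

What the phantom does *not* emulate: real FLAIR parenchyma is brighter
and far more homogeneous than this matrix-plus-speckle texture, real
lesions are not concentric ellipsoids with piecewise-constant
intensities, and there is no partial-volume effect, no multifocality and
no anatomy (ventricles, sulci). Passing phantom tests therefore
demonstrates internal correctness of the pipeline — each operator doing
what it claims, the stages composing, the clustering recovering planted
structure — not clinical-grade performance on acquired MRI.

Perturbation operators mirror common acquisition defects, all seeded:
additive Gaussian noise (σ on the normalized scale), a smooth
multiplicative bias field with bounded peak deviation (cubic upsampling
of a 4³ random grid, renormalized so max |field − 1| equals the
amplitude), 2× block-average downsampling with nearest re-upsampling,
and slice-wise motion (a stated fraction of axial slices replaced by
shifted, blurred copies).

## Problem sizes and runtime

A full two-stage run on a default 64³ phantom (≈7,200 lesion voxels,
≈1,550 patches) takes ≈20 s on one CPU core; the test suite's end-to-end
checks use 10 phantom seeds per condition and the reduced 36³ spec for
unit-level pipeline tests. The acceptance script uses 5 clean cases and
3 per noise severity. These sizes were chosen so the whole suite runs in
minutes while keeping the per-case voxel counts large enough that Dice
estimates are stable to well under a percentage point.

## Known limitations

* Stage 1 presumes lesion-to-background contrast above the T ≈ m/2
  rejection threshold and a textured background; homogeneous mid-gray
  backgrounds are unseparable by construction (see stage-1 notes).
* The clustering stage is O(L²) per patch and per re-clustering chunk in
  memory and time; very large lesions rely on the chunked hierarchy and
  would benefit from sparse similarities.
* With fewer than three clusters surviving selection, the necrosis class
  (and then the enhancing class) is empty by design; downstream
  consumers should treat absent classes as "not detected", not "absent
  in the patient".
* HD95 is reported as NaN when a region is empty in either prediction or
  reference; cohort aggregation should use nan-aware means.
* The phantom's noise response is not monotone: additive noise around
  σ ≈ 0.05 coherently enlarges the bright parenchymal texture past the
  scale the per-slice opening and small-object removal can delete, so a
  few small plane-consistent background remnants survive the AND fusion,
  while heavier noise (σ ≈ 0.10) fragments them again. Boundary recall
  does degrade monotonically with noise; the false-positive term does
  not (tumor-core and enhancing-tumor Dice do degrade monotonically).
  The robustness harness reports the measured values per severity rather
  than assuming an ordering; enabling the 3D post-fusion cleanup removes
  these remnants if monotone behavior matters for a use case.
* 2× downsampling hits the phantom much harder than it would real data:
  block-averaging smears the punctate parenchymal texture into exactly
  the homogeneous mid-gray background the stage-1 threshold cannot
  reject, so the mask floods. On acquired MRI the parenchyma retains
  multi-scale structure after moderate downsampling; on the phantom this
  perturbation probes the generator's texture model as much as the
  pipeline.
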