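# Methods

`pelvimark` localizes six anatomical landmarks — the bilateral posterior
superior iliac spines (PSIS_L, PSIS_R), the bilateral iliac crests (IC_L,
IC_R), and the L1 and L4 vertebral levels — on 3D surface scans of the
posterior pelvis and lower back. The pipeline is modular: a region-of-interest
(ROI) segmentation network restricts the scan to the posterior pelvic patch, a
rotation-regression network standardizes the pose, and a landmark-region
network labels marker neighbourhoods whose centroids become the landmark
coordinates. This note records the model, its assumptions, the tunable
parameters, the synthetic data the package trains and tests on, and the
numerical choices made where the design was open.

## Coordinate conventions and the canonical pose

All coordinates are millimetres, with x lateral (subject's right positive),
y vertical (up positive) and z depth (toward the scanner positive). Euler
angles are intrinsic x→y→z, so a rotation factors as
`R = Rx(θx) · Ry(θy) · Rz(θz)`; the convention is declared once and used by
both the Euler-angle loss and the serialized transform records.

The *canonical pose* is defined by three constraints: the PSIS midpoint sits
at the origin, the PSIS segment is horizontal (zero depth difference), and L4
has zero depth. It is constructed as a translation followed by a rotation
about y and then a rotation about x. When the PSIS segment has a vertical
component, the x-rotation re-introduces a small PSIS depth difference, so the
two angles are solved jointly by a short fixed-point iteration (alternating
closed-form angle updates, tolerance 1e-9·scale, at most 100 sweeps); the
returned rotation is still exactly of the form `Rx(β) · Ry(α)`, and the
construction reduces to the plain sequential two-step solution whenever the
PSIS markers are level. Landmark configurations too far from an upright
pelvis (e.g. upside-down poses) make the iteration fail; this raises a
degenerate-geometry error rather than returning a bad frame. Rotations act
about the global origin after translation, not about the cloud centroid;
the alignment stage explicitly centres its input first.

Rotation matrices predicted by a network are projected onto the rotation
group by SVD: `R = U·diag(1,1,det(UVᵀ))·Vᵀ`, the Frobenius-nearest rotation
with determinant +1. The orthonormality regularizer `‖I − RᵀR‖_F` is blind
to the sign of the determinant; the projection's determinant fix is what
excludes reflections. Inside the training graph the projection is computed by
a Newton iteration for the orthogonal polar factor, `X ← (X + X⁻ᵀ)/2`, after
Frobenius pre-scaling — a composition of differentiable primitives that
matches the SVD projection to machine precision whenever det(M) > 0. The
rotation head is initialized at the identity and regularized toward
orthonormality, which keeps its determinant positive throughout training;
inference always uses the exact SVD projection.

## Preprocessing

* **ROI labels.** The ROI is the axis-aligned bounding box of the six
  markers expanded by a fixed margin (default 100 mm) on every side; points
  inside (closed intervals — boundary points count as inside) are class 1.
* **Landmark labels.** Points within a fixed radius (default 10 mm, closed
  ball) of a marker inherit its class, 1–6 in the canonical order; a point
  inside several spheres takes the nearest marker. Labels are assigned on the
  full cloud and subset together with it.
* **Input features.** Six channels per point: raw (x, y, z) in mm, and the
  same coordinates min–max normalized over the cloud's own axis-aligned
  bounding box (a degenerate axis normalizes to 0.5). Set-abstraction layers
  additionally consume raw coordinates for distance computation, giving the
  first layer nine input channels.
* **Downsampling.** Uniform random sampling without replacement; an
  insufficient cloud raises rather than sampling with replacement.
* **Augmentation.** Offline: each sample is translated to its centroid and
  rotated by independent per-axis angles uniform in ±20° (composition order
  x, then y, then z, matching the Euler convention); the applied rotation is
  recorded because it is the alignment stage's regression target. Child
  seeds derive from a master seed by counter, so augmented datasets are
  reproducible regardless of generation order.
* **Manual-crop simulation.** For the ablation, the fixed 100 mm margin is
  replaced by six independent offsets uniform in [50, 150] mm (one per
  lower/upper bound per axis), emulating clinician-guided visual cropping.

## Network stages

All three stages share a set-abstraction / feature-propagation (SA/FP)
point-network backbone implemented on a small reverse-mode autodiff engine
over NumPy (`pelvimark.nn`). Geometric scaffolding — farthest-point
sampling, ball-query grouping, 3-NN interpolation — depends only on point
coordinates, is seeded, and is precomputed per cloud and cached across
epochs; the trainable part is dense tensor algebra with exact gradients
(verified against finite differences).

Normalization is per-point across channels (layer normalization) rather than
batch statistics: evaluation is then deterministic and independent of batch
composition, and the backward pass is exact. Grouping radii and MLP widths
are configuration, not contract; the `full` presets mirror the canonical
published segmentation architecture at stage sizes 1024/256/64/16
(multi-scale grouping, 512-d deepest features, 128-d per-point output,
dropout 0.5, log-softmax head) and 512/128 + global aggregation for the
alignment stage. The first-class `tiny` presets (stages 256/64/32/8 for
segmentation, 128/32 for alignment) train in minutes on one CPU and are the
presets every shipped experiment uses.

Two architecture details matter at desk scale:

* **Point-resolution geometric channels.** The per-point skip features at
  the finest level are augmented with a non-learned local-plane descriptor:
  for two neighbourhood scales (12 neighbours within 20 mm, 24 within
  40 mm), a PCA plane fit yields the point's signed height above the plane,
  the neighbourhood roughness and the normal tilt. The small scale resolves
  marker-scale dimples and prominences, the larger one ridge-scale
  curvature; without them the per-point class posterior is blurred to the
  first abstraction stage's ~25 mm spacing and marker centroids inherit that
  blur.
* **Moment- and frame-augmented global aggregation.** The alignment stage
  concatenates max- and mean-pooled learned features with three analytic
  descriptor blocks of its (centred, outlier-trimmed) input cloud: the
  first/second/third coordinate moments (raw and trace-normalized — second
  moments transform quadratically with rotation, third moments break sign
  ambiguities, trace normalization removes subject size); the same moments
  expressed in a per-cloud *sheet frame*; and the sheet frame itself. The
  sheet frame takes its depth axis from the smallest covariance eigenvector
  (the trunk patch is thin in depth; this axis is pose-equivariant and
  stable across subjects, unlike the in-plane eigenvectors, which swing
  tens of degrees with posture), its vertical axis from world +y projected
  into the sheet plane, and the +z-hemisphere sign convention from the
  acquisition protocol's bounded pose. Together these give the fully
  connected stack a nearly closed-form handle on orientation — at the small
  training sizes used here the difference between ~8° and <5° median
  recovery error.

## Training objectives

* ROI and landmark labeling train with weighted negative log-likelihood
  (mean over points of `w_y · log p_y`). ROI uses uniform class weights.
  Landmark classes are boosted by anchored square-root inverse-frequency
  weights `w_c = min(10, √(f₀/f_c))` with background fixed at 1; plain
  inverse-frequency weighting at these densities (a few labeled points per
  marker among thousands) collapses the background class entirely.
* The alignment objective is `L_pts + λ_rot·L_rot + λ_euler·L_euler`:
  index-paired mean Euclidean distance between the rotated input and the
  canonical reference cloud; the orthonormality residual of the raw matrix;
  and the l2 distance between Euler-angle vectors. Defaults λ_rot = 0.1,
  λ_euler = 1.0. The reference points are the same physical points in
  canonical pose (index-paired; no nearest-neighbour matching).
* The landmark objective is `L_NLL + λ_dist·L_dist` with λ_dist = 10.
  During training the marker centers of `L_dist` are *gated soft centers*:
  probability-weighted coordinates per class, restricted (by a constant
  gate) to points whose class probability is within 30% of the per-cloud
  maximum, so the term moves the predicted blob rather than smearing
  probability mass globally. The term engages after a warmup (first half of
  the epochs NLL-only): before the blobs localize, soft centers sit near the
  cloud centroid and the term's gradients are counter-productive. At
  evaluation, centers are hard-label centroids — the mean coordinate of the
  points argmax-assigned to each class — and a class with no assigned point
  is a missing marker, excluded from error means and counted in a coverage
  metric.

Optimization is Adam (default learning rate 1e-3; the shipped study uses
3e-3 with exponential decay). Model selection takes the epoch with the
lowest validation loss on a subject-level validation split carved from the
training data; validation always scores the full objective so selection is
consistent across the warmup boundary.

## Pipeline composition

Inference order: downsample the raw scan → ROI segmentation → keep the
points predicted pelvic (a mask, not a refitted box — the stricter reading)
→ centre and predict the rotation correction on a 1024-point subsample →
apply the correction to the ROI points → landmark labeling → hard-centroid
extraction → inverse-transform the centers into the original scan frame.
A predicted ROI below a minimum point count raises a failure carrying the
diagnostic mask. At inference there is no ground truth, so only the
predicted rotation is applied; the canonical reference exists only in the
training objective.

In the pipeline, center extraction first reduces each predicted region to
its dominant spatial cluster (single linkage at twice the labeling radius)
before averaging: a region is a contiguous patch, and an isolated stray
point tens of millimetres away would otherwise drag the centroid and
dominate run-to-run variability. The plain all-points centroid remains the
default of the extraction function itself. A marker whose class receives no
point is reported missing — never imputed — and downstream summaries count
missing markers separately from errors.

The alignment and landmark stages are trained on the *ROI network's
predicted crops* (with a ground-truth-box fallback when a mask is
degenerate), matching the inference-time input distribution; training them
on clean ground-truth box crops instead leaves the landmark stage exposed
to a bounding-box feature shift from ragged predicted masks and roughly
quintuples its in-pipeline error. Ground-truth crops remain available via
the `roinet=None` default of the preparation functions.

## Synthetic data

The generator produces back/pelvis surface sheets `z = f(x, y)`: an
elliptical trunk cross-section with height-dependent width (hips, waist,
shoulders), a spinal groove, a lumbar bulge, PSIS dimples ("dimples of
Venus", 5–9 mm deep, σ 12 mm), iliac-crest ridges peaking at the marked
points, and spinous prominences at the two marked vertebral levels
(4–8 mm). Landmarks are placed on the parametric surface from a per-subject
template (mutual separation ≥ 40 mm enforced) and the whole scan is
canonicalized by construction before a random scanner pose (±15° per axis,
±50 mm) is applied. The forward-bending posture (P2) adds a depth curvature
growing above the waist. Sensor noise is isotropic Gaussian along surface
normals, σ 1 mm (typical of structured-light scanners). Acquisition
artifacts: contiguous occlusion patches (exact point-count fraction) and
partially visible limb fragments beside the trunk. Repeats within a visit
share the subject shape and differ by pose, noise and a 2 mm landmark
placement jitter emulating palpation/digitization variability —
the structure the repeatability analysis assumes.

What the generator deliberately makes easy: every landmark has a local
curvature signature about five times the sensor noise, so markers are
locally detectable at the tiny preset's sampling density. Real scans are
harder — vertebral levels must be identified by counting rather than by a
single prominence, soft tissue shifts markers between postures, and
clothing occlusion is not a clean disk. Passing the recovery experiments
therefore demonstrates that the pipeline's stages compose and train
correctly under controlled conditions, not clinical-grade accuracy.

## Desk-scale study conditions

All shipped experiments (acceptance tests and `scripts/acceptance.py`) use
one fixed set of problem sizes, chosen so the whole study retrains from
scratch in one sitting on a single CPU: 13 synthetic subjects × 2 postures
× 2 repeats (52 scans; an 80/20 subject-level split leaves ~40 training
scans), tiny presets, raw scans downsampled to 2048 points for the ROI
stage (4096 when computing the in-pipeline crops), 2048-point ROI crops for
the landmark stage and 1024-point crops for the alignment stage. Schedules:
ROI 40 epochs; alignment 45 epochs with 10-fold augmentation; landmark 60
epochs with 3-fold augmentation (one unrotated canonical copy kept per scan
— the stage's inference inputs are rotation-corrected, i.e. near-canonical,
a pose per-axis ±20° draws almost never produce) and the distance-term
warmup; ablation baseline 30 epochs on raw scans. Batch size 8, learning
rate 3e-3 with exponential decay. Stage-wise landmark evaluation uses
predicted ROI crops at the corrected pose, mirroring the stage's intended
input; rotation robustness is measured by the full-pipeline ablation arm.

## Evaluation

Segmentation quality is class-specific IoU `TP/(TP+FP+FN)` and recall,
pooled over held-out scans; a class absent from prediction and truth is
reported missing, not zero. Localization error is the per-landmark
Euclidean distance; summaries give the overall and per-landmark medians, a
subject-level mean (unweighted over per-subject means) with a Student-t 95%
CI over subjects, and a CDF at 1 mm steps. Repeatability of the three
paired distances (PSIS_L–PSIS_R, IC_L–IC_R, L1–L4) uses the pooled
within-visit standard deviation, the CV (pooled STD as a percentage of the
grand mean, so a constant offset between subjects does not inflate it), and
the ICC in the two-way random-effects absolute-agreement single-measure
form, computed through pingouin with an F-based 95% CI (the consistency
form is available by flag). Zero total variance yields a missing ICC rather
than 0/0; unbalanced repeat counts are truncated to the common minimum to
keep the ICC design balanced. The hyperparameter grid trains the landmark
stage per setting (λ_dist ∈ {5, 10, 15} at the 10 mm radius, then radius ∈
{10, 15, 20} mm at λ_dist = 10, the shared center trained once) and
tabulates mean error.

## Known limitations

* The tiny-preset studies quantify recovery on the generator's synthetic
  world; none of the reported numbers transfer to clinical scans.
* The alignment stage assumes the scan pose is within roughly the
  augmentation range (±20° per axis) of canonical; it does not handle
  arbitrary orientations, mirroring the acquisition protocol's standardized
  positioning.
* Missing markers (no point assigned to a class) are reported as missing;
  the pipeline does not impute them.
* The NumPy networks are single-device and CPU-oriented; the `full` presets
  build and run but are not tuned for production-scale throughput.
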