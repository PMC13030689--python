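# pelvimark

Automatic anatomical-landmark localization on 3D surface scans of the
posterior pelvis and lower back, for researchers working on surface-based
musculoskeletal assessment (posture analysis, treatment follow-up,
repeatability studies) who need the six posterior landmarks — the bilateral
posterior superior iliac spines (**PSIS_L**, **PSIS_R**), the bilateral
iliac crests (**IC_L**, **IC_R**), and the **L1** and **L4** vertebral
levels — as 3D coordinates in millimetres, without manual palpation or
digitization.

## The method

The pipeline is modular, mirroring the clinical workflow (select the region,
standardize the posture, find the markers). Three point-cloud networks with a
shared set-abstraction / feature-propagation backbone are trained
independently and composed at inference:

1. **ROI segmentation.** The posterior-pelvic region of interest is the
   marker bounding box expanded by a 100 mm margin per axis; training labels
   are the in-box indicator, and the loss is the per-point negative
   log-likelihood
   `L_NLL = −(1/N) Σ_i w_{y_i} · log p_{i,y_i}`.
2. **Rotation canonicalization.** The canonical pose puts the PSIS midpoint
   at the origin, levels the PSIS segment in depth (rotation about y) and
   zeroes the depth of L4 (rotation about x). The network regresses a 3×3
   matrix from the centred ROI cloud; an SVD projection inside the forward
   pass returns the nearest rotation with det +1. Training minimizes
   `L_align = L_pts + λ_rot·‖I − R̂ᵀR̂‖_F + λ_euler·‖θ(R̂) − θ(R)‖₂`,
   where `L_pts` is the mean index-paired Euclidean distance to the
   canonical reference cloud and `θ(·)` is the intrinsic x→y→z Euler-angle
   vector.
3. **Landmark-region labeling.** Points within 10 mm of a marker carry its
   class (1–6); the network trains with
   `L_landmark = L_NLL + λ_dist·L_dist` (default `λ_dist = 10`), where
   `L_dist` is the mean distance between predicted and true marker centers.
   At inference each landmark is the centroid of its argmax-labeled points,
   reported in the original scan frame.

Evaluation covers per-class IoU/recall, localization-error distributions
(median, per-landmark, subject-level mean with 95% CI, CDF), a
five-configuration ablation (baseline / manual crop / crop+align / learned
ROI / full pipeline), within-visit repeatability (pooled STD, CV, ICC(2,1)
with F-based CI) and a λ_dist / labeling-radius sensitivity grid.

Because clinical scan corpora of this kind are not public, the package ships
a deterministic synthetic generator of pelvic-like surface scans (elliptical
trunk sheet with spinal groove, PSIS dimples, iliac-crest ridges, spinous
prominences, two postures, sensor noise, occlusion and limb-fragment
artifacts, repeated-scan structure) that every experiment trains and tests
on. See `docs/methods.md` for the model, parameters and what the synthetic
results do and do not show.

The networks run on a small reverse-mode autodiff engine over NumPy
(`pelvimark.nn`) — a single `pip install` gives you training and inference
on any CPU.

## Worked example

Generate a cohort, canonicalize a scan from its landmarks, and inspect the
training targets:

```bash
$ python examples/02_canonical_pose.py
scanner frame:
  PSIS midpoint: [ 26.2 -15.5 -36.6]
  L4 depth     : -18.0 mm
canonical frame:
  PSIS midpoint: [-0. -0.  0.]
  PSIS depth difference: -2e-08
  L4 depth     : 0.0 mm
transform record: {"rotation": [0.9803172279091854, 0.0, -0.19742880403945684, ...
```

The three canonical invariants (PSIS midpoint at the origin, level PSIS
depth, L4 at zero depth) hold to numerical precision; the rigid transform
serializes to a flat JSON record.

```bash
$ python examples/03_labels_and_features.py
ROI box bounds (mm):
[[-244.  182.]
 [ -82.  282.]
 [-228.   56.]]
pelvic fraction of the scan: 0.59
points per landmark class (10 mm radius at 16,384-point density): [25 27 13 12 20 17]
feature channels: 6 (raw xyz + bbox-normalized xyz)
```

About 59% of this scan falls in the pelvic ROI, and each marker's 10 mm
sphere captures a dozen-odd points at training density — the class
imbalance the weighted NLL and the center-distance loss are there to handle.

Repeatability of the paired landmark distances across repeated scans:

```bash
$ python examples/05_repeatability_statistics.py
per-region repeatability (manual annotations):
       region  std_mm  cv_percent   icc  icc_ci_lo  icc_ci_hi
    IC_L-IC_R   2.492       0.983 0.992       0.98       1.00
        L1-L4   2.636       2.540 0.933       0.84       0.97
PSIS_L-PSIS_R   2.602       3.395 0.948       0.89       0.98
```

STD is the pooled within-visit standard deviation (mm), CV expresses it as a
percentage of the mean distance, and the ICC is the two-way random-effects
absolute-agreement single-measure form.

`examples/04_train_roi_stage.py` trains the ROI stage on a miniature cohort
in a few minutes, and the `pelvimark` CLI (`synth`, `train`, `infer`,
`ablate`) exposes the same operations on scan files
(`pelvimark infer scan.ply --models models/ --out landmarks.csv`).

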