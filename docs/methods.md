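# Methods

`psnseg` implements patient-specific fine-tuning for daily clinical-target-
volume (CTV) segmentation in online adaptive radiotherapy, together with
everything needed to exercise it without clinical data: a longitudinal
phantom simulator, a trainable desk-scale backbone, and the geometric,
dosimetric and statistical evaluation protocol.

## The two-stage training strategy

A generalized segmentation model is first pre-trained on a multi-patient
cohort of daily scans.  It is then specialized to each new patient using the
sequence of that patient's own daily fractions, under one of two schedules
built from a common atom, the *train/test step* (train on a set of past
fractions, test on strictly later ones — a test fraction never appears in
its own training set):

* **Adaptive (cumulative)** — step *k* fine-tunes the *pre-trained*
  checkpoint on fractions 1..k and tests on k+1..n.  Training cost grows
  linearly in *k*; each step sees all accumulated patient data.
* **Sequence (chained)** — step *k* fine-tunes the *previous step's*
  checkpoint on fraction *k* alone and tests on fraction k+1.  Per-step cost
  is constant; knowledge propagates through the checkpoint chain
  (continual-learning style).

For n fractions both schedules emit n−1 steps, and their first steps are
identical by construction (same data, same initialization) — in
deterministic mode they produce bit-identical checkpoints, which the test
suite asserts.

Fine-tuning is *deliberate overfitting*: the goal is not generalization
across patients but adaptation to one patient's anatomy and, critically, to
the physician's contouring style for that patient, which a generalized model
cannot know.

Design choices where the protocol is underdetermined:

* An "epoch" of patch-based fine-tuning is defined as
  `patches_per_volume_per_epoch` seeded augmented patches per training
  volume; this makes a fixed epoch count meaningful at any scale.
* Adaptive steps re-start from the pre-trained checkpoint rather than from
  the previous adaptive step (a flagged alternative would chain them).
* Only model parameters cross sequence steps; optimizer state is reset each
  step.
* No early stopping; the epoch count is fixed (default 50).
* Per-step augmentation randomness derives from (master seed, patient,
  step ordinal), so any step can be replayed in isolation and the two
  schedules' first steps coincide exactly.

## Loss and optimization

The loss is an equal-weight (1:1) sum of soft-Dice on the target-class
probability and mean voxel cross-entropy,

    L = w_d · (1 − (2·Σ p·t + ε) / (Σ p + Σ t + ε)) + w_ce · CE,   w_d = w_ce = ½,

with smoothing ε = 1e-5, optimized by AdamW.  The clinical recipe
(lr 1e-4, weight decay 1e-5, 30 000 pre-training iterations, 96³ crops) is
configuration-reachable; the desk defaults below differ and are a package
choice.

## Backbone

The clinical architecture (Swin UNETR: 2×2×2-voxel patch embedding at width
48, four two-block Swin-Transformer stages with 48→96→192→384 channels and
3/6/12/24 attention heads in 7×7×7 windows, a 768-channel bottleneck,
drop-path 0.10, and a symmetric convolutional decoder) is shipped as a
*declarative descriptor* (`build_swin_descriptor()`), exportable to YAML and
consumable by an external Swin UNETR implementation.  Windowed
self-attention is deliberately not re-implemented here: the fine-tuning
strategy is backbone-agnostic, and the package's trainable model is a small
numpy encoder–decoder (`ReferenceNet`) satisfying the same contract —
two-channel score grid of the input's spatial shape, serializable
parameters, seeded initialization.  Its decoder mirrors the clinical design
in miniature: stride-2 downsampling, per-stage skip concatenation, 3×3×3
convolutions, 1×1×1 two-class head.  Forward, backward and AdamW updates
are hand-written in float32 numpy and bit-reproducible; gradients are
verified against finite differences in the test suite.

Model input is the clipped HU window mapped linearly to [0, 1] (the
normalization is a package decision).  Whole-volume inference is
sliding-window: overlapping patches, per-voxel softmax averaging, argmax.
Postprocessing keeps the largest 26-connected component — the CTV is a
single structure, so detached islands are false positives of patch-wise
inference.

## Preprocessing and augmentation

Order: clip HU to (−350, +350) → resample to the target grid (linear for
images, nearest-neighbour for masks) → augment (training only).
Augmentation applies per-axis flips (p = 0.1), per-axis rotations by random
90° multiples (p = 0.1; axis-aligned so masks stay exactly binary — an
arbitrary-angle option is off by default), a random crop, and an intensity
shift (p = 0.5) drawn uniformly in ± offset × window-width with offset 0.1
(the offset scale is interpreted as a *fraction of the clipped window
width*, i.e. ±70 HU for the default window; an absolute-HU reading would be
another defensible choice).  By default the crop is re-drawn until it
contains foreground (then centred on the mask); the training pipeline sets
`background_crop_prob = 0.25` so a quarter of crops are unconstrained —
without background exposure the model produces distant false positives at
whole-volume inference.

## Phantom cohort

The simulator emulates the statistical structure the method relies on, per
patient: a stable base anatomy (ellipsoidal CTV with uniformly drawn
semi-axes 10–16 mm, anterior bladder sphere, posterior rectum cylinder with
a variable gas pocket, lateral bone, soft-tissue background) and a fixed
anisotropic *contouring-style margin* per axis, drawn uniformly in ±3 mm.
Per fraction it applies a rigid shift (patient-systematic, SD 3 mm, plus
per-fraction random, SD 2 mm per axis — within the few-millimetre
systematic/random inter-fraction error ranges reported for prostate
radiotherapy), a smooth elastic deformation (peak 3 mm, Gaussian smoothing
scale 12 mm; shape changes of 2–4 mm are reported clinically), organ-filling
changes (bladder volume ±20%, rectal gas pocket 0–8 mm), and fresh Gaussian
intensity noise (SD 20 HU).  Intensities are CBCT-like only in scale
(soft tissue 30 HU, target 130 HU, bladder 0, gas −800, bone 700); no
scatter, rings or beam hardening are modelled.

Structures are evaluated analytically at the warped coordinates, so
reference masks are exact indicators of the deformed, style-adjusted
anatomy: there is no interpolation error, which keeps the simulator usable
as an oracle (e.g. centroid-shift statistics recover the configured motion
scales; a zero-variation configuration collapses all fractions exactly).
The reference contour is modelled as the deterministic deformation of the
style-adjusted target (no label noise by default; a `label_noise_mm` knob
exists but defaults to zero so oracles stay exact).  How daily reference
contours arise in clinic (physician edits of propagated proposals vs de
novo) is not modelled.

Two stand-ins close the evaluation loop without a treatment-planning
system:

* **Contour propagation baseline** (`propagate_planning_contour`) — the
  planning contour transported by the fraction's true displacement plus a
  seeded smooth residual field of controllable peak magnitude (default
  1.5 mm), emulating a deformable registration whose only defect is a
  residual alignment error.  Zero residual reproduces the daily reference
  exactly.
* **Synthetic dose** (`synth_dose`) — prescription dose (7.25 Gy per
  fraction, an SBRT-style 36.25 Gy in five) inside a 5 mm margin-expanded
  planning target, Gaussian falloff (σ = 5 mm) outside, fixed in room
  coordinates; day-to-day motion therefore changes what each contour
  receives, which is the effect the dose-error comparison probes.  No beam
  model, monitor units or plan re-optimization.

What passing tests on this phantom do and do not show: they validate the
*mechanism* — that per-patient fine-tuning recovers patient-specific
contouring style and anatomy that a generalized model cannot — under
idealized image formation and exactly consistent labels.  They do not
establish clinical-scale accuracy on real cone-beam CT, where contrast,
artifacts and label inconsistency are all less favourable.

## Geometric metrics

Surface = mask voxels with a 6-neighbour outside the mask or grid.
Distances are Euclidean between surface-voxel centres with anisotropic
spacing (no sub-voxel mesh — chosen for exact oracle testability).  HD95 is
the 95th percentile (linear interpolation between order statistics) of the
*pooled* symmetric distance multiset; MSD its mean.  Pooling rather than
the max-of-directed-percentiles convention is a documented choice isolated
in one function.  Signed deviation maps assign each reference-surface voxel
its distance to the predicted surface, positive where the prediction
extends outward past the reference.  Empty predictions are scored DSC 0
with the grid diagonal as a conservative finite distance.

## Dosimetry

DVH indices follow ICRU 83: D95/D98 near-minimum coverage, Dmean, D2
near-maximum.  The exact rank convention is Dx = value at rank
⌈x/100·N⌉ of the in-mask doses sorted descending (an interpolated-DVH
variant is available, `interpolate=True`).  Dose errors are absolute index
differences |Dx(method) − Dx(reference)| on the same dose grid; tables
report mean ± SD per (fraction, method).

## Statistics

With a handful of test patients, inference uses the exact two-sided
Wilcoxon signed-rank test: zeros dropped, midranks on ties, and the null
distribution of W⁺ enumerated over all 2ⁿ sign assignments of the realized
rank multiset (n ≤ 20; a tie-corrected normal approximation beyond that,
flagged in the result).  p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))).
Holm's step-down adjustment is applied within a declared family — here per
metric across evaluated fractions, a configurable choice since family
definitions are convention.  Effect sizes are matched-pairs rank-biserial
correlations r = (W⁺ − W⁻)/(W⁺ + W⁻) with seeded percentile-bootstrap
confidence intervals (default 10 000 resamples; degenerate all-zero
resamples are skipped and counted).  Comparisons with 0.05 < p_Holm ≤ 0.10
are labelled "marginal"; self-comparisons yield flagged degenerate rows.

## Desk-scale configuration

The default `ExperimentConfig` is sized for a single CPU core: 9 patients
(6 pre-training / 3 test) × 5 fractions on 64³ grids at 2 mm; a width-12,
depth-2 reference net; 16³ training crops; 3000 pre-training iterations at
lr 1e-3; 50 fine-tuning epochs of 8 patches per volume; sliding-window
overlap 0.25.  These sizes were chosen so the full pipeline
(phantom → pre-train → both schedules for every test patient → metrics,
dose errors, statistics) completes in minutes; the width/lr/iteration
combination was selected by a small convergence sweep (narrower nets
saturate well below usable accuracy, and the clinical lr of 1e-4 is matched
to a 30 000-iteration budget, not to this one).  Clinical-scale settings
(1×1×2 mm grids, 96³ crops, 30 000 iterations) remain reachable through
configuration.

Single-patch optimization of a small net from a random initialization
occasionally settles on the wrong structure (bone instead of the target),
and because that structure is rarely sampled by the crop distribution the
failure is invisible in the training loss — it only shows at whole-volume
scale.  Desk pre-training therefore trains two candidates from seed-derived
initializations and keeps the one with the best mean whole-volume DSC on a
small validation set drawn from the *pre-training split* (first fraction of
three pre-training patients; test-split patients are never consulted),
escalating to at most five candidates while the best validation DSC stays
below 0.6.  This mirrors ordinary practice of validating on held-out
training-cohort patients and is a convergence control, not test-set
selection.

## Numerical conventions

* Axis order (z, y, x); world = origin + index × spacing; volumes are used
  in stored voxel space (no reorientation on read; a warning is emitted if
  headers disagree within a patient).
* Masks are stored as uint8, images and dose as float32; NIfTI gzip streams
  carry zero mtime and checkpoint archives a fixed timestamp, so identical
  inputs give identical bytes (end-to-end determinism is asserted at the
  byte level).
* Checkpoints are `.npz` parameter archives plus a JSON sidecar recording
  stage, patient and the trained-fraction set; filenames are injective over
  that triple.
* All randomness flows from one master seed through named `SeedSequence`
  spawns.

## Known limitations

* The trainable backbone is a small CNN, not the clinical transformer; the
  schedules, loss, metrics and statistics are backbone-agnostic, but
  absolute accuracies at desk scale are not comparable to clinical values.
* The phantom's image formation is idealized; its reference contours are
  exactly self-consistent, which real physician contours are not.
* The propagation baseline's fidelity parameter (residual error) is an
  assumption, not a measurement of any registration algorithm.
* Dose grids are synthetic and static per patient; no adaptive re-planning
  is simulated.
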