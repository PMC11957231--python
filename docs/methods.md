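# Methods

This note documents the models, conventions, numerical choices and default
parameters behind `fluoropose`, and what the synthetic experiments do and do
not demonstrate.

## Coordinate conventions

**World frame.** Right-handed, millimeters, origin at the volume isocenter
(the geometric center of the voxel grid unless the file affine says
otherwise). Axes are patient-anatomical: `+x` left-right, `+y` anterior,
`+z` superior. Volumes read from NIfTI/DICOM keep their file affine;
`Volume3D.centered` builds isocentered grids for synthetic data.

**Camera frame.** The X-ray source sits at the camera origin; the principal
ray runs along camera `+z` and meets the detector plane at distance `sdd`
(source-to-detector distance). Camera `x`/`y` are the detector column/row
directions; pixel (0, 0) is the top-left pixel center and the principal
point is expressed as a millimeter offset `(x0, y0)` from the detector
center. A pose is the world→camera rigid map; `RigidTransform` stores the
3×3 rotation and translation (mm) and enforces orthogonality at
construction.

**Radiologic chart.** Clinicians position C-arms with two gantry angles and
a depth: α rotates about the patient superior–inferior axis (LAO positive,
RAO negative), β about the patient left–right axis (CRA positive, CAU
negative), and γ rolls the detector about the principal ray. The rotations
compose intrinsically in the order α, then β, then γ. `(bx, by, bz)`
translate the source rigidly in the rotated gantry frame, with `by` the
signed offset of the true source-to-isocenter distance from the nominal SID.
At the all-zero pose the source lies on the patient-anterior axis at the
nominal SID and the principal ray passes through the isocenter. The inverse
chart is an intrinsic Z–X–Y Euler factorization; it is degenerate at
|β| = 90°, where α and γ rotate about the same axis — requesting radiologic
parameters there raises `GimbalLockError` naming the ambiguous axes. Angles
are degrees at every interface and radians internally. This chart (rotation
order, gantry-frame translations) is a package convention chosen to match
clinical LAO/RAO-then-CRA/CAU usage; the pose JSON schema records both the
4×4 matrix and the radiologic tuple so files are self-describing.

## Rendering

A DRR pixel is the monoenergetic Beer–Lambert line integral of linear
attenuation μ (mm⁻¹) along the ray from the source through the pixel
center. Energy spectra, scatter and detector response are not modeled; the
geometric fidelity of the projection is what registration needs, and
normalized-correlation similarity absorbs affine intensity differences.
Hounsfield-calibrated CT converts first via `μ = μ_water (1 + HU/1000)`,
clamped at zero (`μ_water` default 0.02 mm⁻¹); MR/MRA-style volumes are
min–max normalized to [0, 1] pseudo-attenuation — their renderings are only
ever compared through intensity-invariant similarity, so the absolute scale
is irrelevant.

**Siddon's exact method.** Each ray's crossings with the three families of
voxel-boundary planes are generated analytically, merged, and sorted; each
inter-crossing segment contributes μ of the voxel containing its midpoint
times the segment length. Crossings within 1e-9 of each other collapse to
zero-length segments and are dropped; a midpoint landing exactly on a voxel
face is attributed to the voxel on the positive-normal side
(`floor(x + 0.5)`), making output deterministic and double-counting-free.
The implementation is vectorized over rays; the test suite pins it to an
algorithmically independent oracle (per-voxel axis-aligned-box clipping) at
1e-6 on random volumes and poses.

**Trilinear sampling.** `n_points` samples (default 2× the largest volume
dimension) are placed at segment midpoints between the ray's entry and exit
of the volume bounding box (slab method); each contributes the trilinearly
interpolated μ times the step length. Interpolation is zero-padded: the
volume is surrounded by one voxel of air, and out-of-volume samples
contribute nothing. Midpoint placement between entry and exit keeps the
quadrature resolution-adaptive and unbiased; for a piecewise-linear
integrand the midpoint rule is exact away from cell boundaries, which is
why the homogeneous-cube closed form reproduces to <0.1%.

**Differentiability.** The pose tangent chart is the camera-frame right
perturbation: with camera→world map `C`, the perturbed pose is
`C · exp(ξ)`, ξ ∈ se(3), so ξ₁..₃ rotate about the camera axes (radians,
about the source) and ξ₄..₆ translate along them (mm). `render_jacobian`
returns the exact forward-mode derivative of every pixel in all six
directions, propagating through the ray directions, the slab entry/exit
parameters, and the trilinear interpolant. The per-sample sums factorize
into four per-ray moments (Σ∇f, Σt∇f, Σ∇f·u, Σ frac·∇f·u), so the Jacobian
costs about one extra rendering rather than six. The derivative of the
*quadrature* is computed, so it matches central finite differences of the
renderer except on the measure-zero set of slab-switch/cell-boundary
configurations; the acceptance check observes ≲1e-4 relative agreement on a
smooth phantom. Siddon rendering is piecewise-constant in pose at
voxel-boundary crossings and deliberately has no gradient path; everything
gradient-based uses the trilinear renderer.

The sampling inner loops are fused numba kernels (`_kernels.py`); a
pure-NumPy reference path computes identical values (regression-tested) and
is used automatically if numba is unavailable.

**Structure-specific rendering.** `render_labels` renders each requested
label through a μ-masked copy of the volume. Because rendering is linear in
μ and sample/segment positions do not depend on μ, the per-structure images
of a full label partition (background included) sum to the unrestricted
rendering to machine precision — the conservation property the tests check
at 1e-5.

## Synthetic phantoms

`make_phantom` builds three families, all deterministic under their seed:

- `pelvis_like_solids`: a soft-tissue ellipsoid body containing bone solids —
  two *unequal* lateral spheres, a tilted central block, and a small
  off-axis dense marker.
- `skull_like_shell`: an ellipsoidal bone shell around soft tissue with a
  dense, off-center core (the nested-shell geometry used for the analytic
  chord-length check).
- `vessel_tree`: a recursive binary branching tree of tubes (radius and
  length decaying 0.75× per generation, default depth 4) on an air
  background, emulating single-hemisphere rotational angiography; the
  rasterized tube volume is pinned to the analytic cylinder-volume sum
  within ±20%.

Default grid 64³ at 2 mm (desk scale), attenuation air 0, soft tissue
0.02 mm⁻¹, bone 0.04 mm⁻¹ — CPU-minute rendering with realistic contrast
ordering. Structures are deliberately left-right asymmetric: a
mirror-symmetric phantom makes ±α (and ±β) projections nearly
indistinguishable, a degeneracy real anatomy does not have. Non-air tissue
additionally carries multiplicative smoothed speckle (±30%, ~2-voxel
grain) emulating trabecular/parenchymal texture; this high-frequency
content is what gives projections their pose-disambiguating parallax
detail. Fiducials (default 8) are sampled uniformly among bone/vessel
voxels, mirroring how target registration error is measured on real
benchmarks. `make_benchmark_case` adds views rendered at poses sampled from
the training ranges, with independent random streams for poses and
appearance noise so stored ground-truth poses are invariant to toggling
augmentation.

What the phantoms do *not* emulate: real anatomy's shape complexity,
soft-tissue overlap, pre/intraoperative content mismatch (devices,
contrast, surgical change), detector physics, or clinical image
resolutions. Passing tests therefore demonstrate the correctness of the
geometry, rendering, optimization and metrics, and the qualitative training
findings — not clinical-grade accuracy on real data.

## Pose regression

The regressor is a fully connected network (default hidden layers 256/128,
~0.5 M parameters at 32² input; ReLU, linear head) on per-sample min–max
normalized images, trained with manual backpropagation and Adam (lr 1e-3,
cosine-annealed to 10%). It regresses the six radiologic parameters
normalized to their sampling intervals; the training loss is the mean
squared error in that normalized chart. The chart is smooth over the whole
training domain because the sampling ranges exclude |β| = 90°, and the MSE
surrogate's zero set coincides with pose equality; held-out error is logged
with the weighted pose loss `w_r · geodesic(R̂, R) + w_t · ‖t̂ − t‖`
(defaults w_r = 1 rad⁻¹-scale, w_t = 0.01 mm⁻¹-scale, balancing ~0.25 rad
of rotation against ~20 mm of translation). A continuous 6-parameter
rotation representation was considered and set aside: on a gimbal-free
domain the radiologic chart is equally smooth and keeps the normalized
target scale uniform across all six outputs.

Training is fully on-the-fly: every batch samples poses uniformly from the
ranges (defaults α, β ∈ ±45°, γ ∈ ±15°, bx, bz ∈ ±50 mm, by ∈ ±100 mm,
overridable per procedure), renders, augments, and steps. No fixed dataset
exists and no annotation is consumed anywhere. The augmentation pipeline
(additive Gaussian noise 2% of dynamic range, gain ±10%, gamma 0.7–1.4,
intensity inversion p = 0.5, one rectangular occlusion ≤10% area, optional
blur/coarse dropout) models detector gain/contrast variation, film-vs-fluoro
polarity, and collimation or instrument occlusion. The synthetic
experiments in the tests use only the noise+gain components, since their
observed images come from the same renderer and exhibit no polarity or
occlusion shift.

Checkpoints store the weights plus a fingerprint of the training conditions
(intrinsics, ranges, normalization, nominal SID, seed, mode tag
de_novo / patient_agnostic / finetuned). Prediction refuses images whose
intrinsics do not match the fingerprint and directs the caller to
`resample_to_intrinsics` — silently predicting from misscaled pixels is the
failure mode this guards against. Patient-agnostic pretraining is the same
loop over a list of mutually preregistered volumes (one drawn per batch
item); transfer to a new patient uses `center_align` (pure translation
between volume centers) or a user-supplied rigid map, composed into the
predicted pose by `correct_pose_to_patient`.

Budgets are expressed in iterations (deterministic, used by all tests) or
wall-clock seconds; seeded runs are bit-reproducible on one device. A
zero-iteration budget with an initial model returns it unchanged; without
one it is a configuration error.

## Iterative refinement

`refine_pose` maximizes image similarity with Adam ascent in the se(3)
tangent chart re-anchored at the current pose every iteration (re-anchoring
avoids chart distortion far from the anchor). Similarity is patchwise NCC
over a non-overlapping grid (default 16-pixel patches, chosen to tile the
64² default detector exactly; zero-variance patches are skipped), falling
back to global NCC on request; both are invariant to positive affine
intensity maps, and their image gradients are analytic, chained with the
renderer's pose Jacobian — no finite differences anywhere in the loop.

The pyramid is ×4, ×2, ×1, ×1 with 60/60/100/100 iterations: the observed
image is block-mean pooled per level and the intrinsics rescaled, enlarging
the capture range coarse-to-fine. The repeated finest level is a warm
restart — Adam moments reset and the step size re-anneals — which escapes
the shallow valley along the near-degenerate rotate-about-source/translate
direction before the final polish. Step sizes are 7.5e-3 (radian scale) and
1.0 (mm scale) for the rotational and translational groups — the two groups
have incommensurate units — cosine-decayed to 2% within each level for
final precision. A level stops early when the best similarity improves less
than 1e-5 over 40 iterations. The best-similarity pose seen at the finest
level is returned whether or not the run converged; divergence (finishing
below the initial finest-level similarity) clears the `converged` flag.

With these defaults, 20 views of the 64³ pelvis phantom initialized within
5° / 15 mm of truth register with mTRE < 1 mm in ≥ 90% of trials (typically
19–20/20, median ≈ 0.2–0.3 mm) in about a minute of CPU.

## Evaluation metrics

mTRE is the mean 3D distance between fiducials mapped by the estimated and
true poses — sensitive to every pose error component, and invariant under a
global rigid change of world frame. SMSR counts mTRE *strictly* below the
threshold (default 1 mm); the strict inequality is fixed here to remove
boundary ambiguity. Survival curves report the fraction of views below each
threshold on a uniform grid over (0, 10 mm] (1000 points; 10 mm is the
conventional clinical success bound); the normalized AUC integrates by the
trapezoidal rule with the first grid value extended flat to zero, written
so a constant curve integrates exactly (all-zero errors give AUC exactly
1.0). Medians and IQRs are reported alongside means throughout.

## Known limitations

- **Network-initialized two-stage registration at desk scale.** At the 32–64
  pixel detectors the synthetic experiments use, an α/β error of several
  degrees compensated by an in-plane translation changes the projection by
  under one pixel of differential parallax. The regressor therefore retains
  ~7° median error in those two angles (γ and the translations learn to
  ~1° / ~1–2 mm, and the *mTRE* of its predictions is a few millimeters),
  and such compensated-rotation initializations sit outside the refiner's
  ~5° rotational capture range — it converges to a spurious similarity
  optimum along that valley. The submillimeter two-stage contract is
  therefore demonstrated from perturbation-level initializations (≤5° /
  ≤15 mm), which is where iterative refinement operates after an adequate
  initializer. Closing the gap needs clinical-resolution detectors (256²+)
  and a convolutional backbone, both out of desk-scale CPU budgets.
- The refiner's similarity is unimodal only near the truth; from far
  outside the capture range (tens of degrees) it returns its
  best-similarity pose with no correctness guarantee, flagged via
  `converged`.
- Monoenergetic line integrals without scatter or detector response; real
  fluoroscopy's appearance differences are only covered insofar as
  normalized correlation and the augmentation pipeline absorb them.
- Non-rigid anatomy (lungs, abdomen) is out of scope: the pose model is
  rigid.
- Problem sizes in tests (64³ volumes, 64² detectors, 10³-iteration
  training runs) are the package's chosen desk-scale study conditions;
  all algorithms are resolution-agnostic.
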