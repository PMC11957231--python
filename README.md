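# fluoropose

Rigid 2D/3D registration of intraoperative X-rays to preoperative volumes,
built around a differentiable X-ray renderer, self-supervised patient-specific
pose regression, and multiscale gradient-based pose refinement.

## The problem

Fluoroscopy-guided interventions (endovascular neurosurgery, orthopedics,
interventional radiology) navigate 3D anatomy using 2D projection images.
Recovering the C-arm pose that aligns a live X-ray with the patient's own
preoperative CT/MR volume restores the missing third dimension — but it must
be automatic, patient-specific, and accurate to about a millimeter to be
surgically useful. This package implements that workflow end to end and ships
a seeded synthetic phantom generator, so the entire pipeline is exercisable
and testable on a laptop with no external data.

## The model

**Rendering.** A digitally reconstructed radiograph (DRR) assigns each
detector pixel the Beer–Lambert line integral of the linear attenuation
coefficient μ (mm⁻¹) along the ray from the X-ray source through that pixel:

```
I(u, v) = ∫ μ(s(t; θ, K)) dt
```

where θ ∈ SE(3) is the rigid C-arm pose and K the pinhole intrinsics
(source-to-detector distance, pixel pitch, principal point). Two backends:
Siddon's exact method (sum of μᵢ × voxel intersection lengths) and trilinear
point sampling, whose analytic pose Jacobian `∂I/∂ξ` for the se(3) tangent
vector ξ drives gradient-based optimization. Poses use the radiologic chart
clinicians know: α (LAO/RAO), β (CRA/CAU), γ (detector roll), and
translations with the source-to-isocenter distance (SID) as depth.

**Stage 1 — patient-specific pose regression.** Poses are drawn uniformly
from per-parameter ranges, DRRs are rendered from the patient's own volume
on the fly, passed through an appearance-augmentation pipeline, and a small
regression network learns to predict the pose — entirely self-supervised.
The network can be trained de novo, pretrained patient-agnostically on a
corpus of preregistered volumes, or finetuned from the pretrained weights in
a fraction of the de novo iterations.

**Stage 2 — iterative refinement.** Starting from the regressed (or
DICOM-header, or user-supplied) pose, the registration maximizes patchwise
normalized cross-correlation between the observed X-ray and renderings,

```
θ* = argmax_θ  NCC_local( I_obs , DRR(V; θ, K) ) ,
```

by Adam ascent in the se(3) tangent chart re-anchored at the current pose,
coarse-to-fine over a detector pyramid. Accuracy is reported as mean target
registration error, `mTRE = mean_j ‖θ̂ pⱼ − θ pⱼ‖` over fiducials pⱼ, with
the submillimeter success rate (SMSR, fraction of views with mTRE < 1 mm)
and the normalized area under the mTRE survival curve.

## Worked example

```python
import numpy as np

from fluoropose import (
    Intrinsics, PhantomSpec, RadiologicParams, RefineConfig,
    make_phantom, mtre, pose_from_radiologic, pose_geodesic,
    refine_pose, render, se3_exp,
)

# a 64^3 pelvis-like phantom (2 mm voxels) with bone fiducials
vol, labels, fids = make_phantom(PhantomSpec(kind="pelvis_like_solids", seed=3))

# C-arm geometry: 64x64 detector, 3 mm pixels, SDD 1000 mm, SID 700 mm
K = Intrinsics(sdd=1000.0, height=64, width=64, delx=3.0, dely=3.0)
T_true = pose_from_radiologic(
    RadiologicParams(alpha=20.0, beta=-10.0, gamma=3.0), nominal_sid=700.0
)
xray = render(vol, T_true, K, method="trilinear")

# perturb the pose by 4 deg / 10 mm and register back
rng = np.random.default_rng(0)
axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
dt = rng.normal(size=3); dt *= 10.0 / np.linalg.norm(dt)
T_init = (T_true.inverse() @ se3_exp(np.r_[axis * np.deg2rad(4.0), dt])).inverse()
print(f"initial mTRE: {mtre(T_init, T_true, fids.points):.2f} mm")

result = refine_pose(xray, vol, init=T_init, cfg=RefineConfig())
rot, _ = pose_geodesic(result.final_pose, T_true)
print(f"final mTRE: {mtre(result.final_pose, T_true, fids.points):.3f} mm "
      f"(rotation {rot:.3f} deg), similarity {result.final_similarity:.4f}")
```

prints

```
initial mTRE: 21.15 mm
final mTRE: 0.582 mm (rotation 0.510 deg), similarity 1.0000
```

i.e. a pose 21 mm off (4° of rotation plus 10 mm of translation, measured at
bone fiducials) is registered back to 0.58 mm — submillimeter — in a few
hundred 64×64 renderings, a couple of seconds on one CPU core.

## Command line

```bash
fluoropose phantom  --kind pelvis_like_solids --n-views 10 --seed 1 --out case/
fluoropose train    --volume case/volume.nii.gz --seed 1 --out model/
fluoropose register --xray case/view_000.tif --volume case/volume.nii.gz \
                    --init-pose case/view_000_pose.json --out reg/
fluoropose evaluate --results reg/ --fiducials case/fiducials.json --out summary/
```

`register` also accepts `--checkpoint model/model.npz` (network
initialization, resampling the X-ray to the training intrinsics if needed)
or `--dicom-angles PRIMARY SECONDARY SID SDD` (positioner-tag
initialization). Volumes are NIfTI or DICOM CT series; X-rays are DICOM
(XA/RF, multi-frame with a selectable frame policy) or PNG/TIFF with a JSON
intrinsics sidecar.

## Documentation

`docs/methods.md` describes the geometric conventions, the rendering and
optimization mathematics, the synthetic phantom design, all default
parameters, and known limitations.
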