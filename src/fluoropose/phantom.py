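"""Seeded synthetic phantoms: volumes, label maps, fiducials and complete
benchmark registration cases.

Three phantom families cover the anatomies the registration pipeline
targets, at desk scale:

``pelvis_like_solids``
    A soft-tissue ellipsoid body containing high-attenuation "bone" solids
    (two lateral spheres and a central block), loosely mimicking iliac wings
    and sacrum — the contrast structure of a pelvic CT.

``skull_like_shell``
    A bone-attenuation ellipsoidal shell around a soft-tissue interior with
    a denser central core: the nested-shell geometry used for analytic
    chord-length checks of structure-specific rendering.

``vessel_tree``
    A random binary branching tree of tubes on an air background with no
    other anatomy, emulating the single-hemisphere vascular trees of
    rotational angiography.

Everything is deterministic under the ``PhantomSpec`` seed, and fiducials
are sampled
inside high-attenuation (bone/vessel) voxels, mirroring how fiducial-based
target registration error is evaluated on real benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Intrinsics, RigidTransform, pose_from_radiologic
from .rendering import LabelMap3D, Volume3D, XRay2D, render
from .regression import AugmentConfig, SamplingRanges, augment_xray, sample_pose

__all__ = ["PhantomSpec", "FiducialSet", "make_phantom", "make_benchmark_case"]

_KINDS = ("pelvis_like_solids", "skull_like_shell", "vessel_tree")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic phantom.

    ``attenuation`` maps tissue-class names to mu in mm^-1; defaults are
    bone 0.04, soft tissue 0.02, air 0 (realistic contrast ordering at CT
    energies).  ``jitter`` scales the seeded random variation of structure
    positions/sizes, so sibling phantoms (same kind, different seed) model
    different "patients".
    """

    kind: str = "pelvis_like_solids"
    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.0
    attenuation: Dict[str, float] = field(
        default_factory=lambda: {"air": 0.0, "soft": 0.02, "bone": 0.04}
    )
    n_fiducials: int = 8
    jitter: float = 1.0
    branch_depth: int = 4
    texture: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if min(self.shape) < 16:
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if any(v < 0 for v in self.attenuation.values()):
            raise ValueError("attenuation levels must be >= 0")
        if self.n_fiducials < 1:
            raise ValueError("need at least one fiducial")


@dataclass(frozen=True)
class FiducialSet:
    """Named set of world-space fiducial points (N, 3) mm."""

    points: np.ndarray
    name: str = "phantom"

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("fiducials must be an (N, 3) array")
        object.__setattr__(self, "points", pts)


def _grid_world(shape, spacing):
    """World coordinates of voxel centers for an isocentered grid."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _pelvis(spec: PhantomSpec, rng: np.random.Generator):
    X, Y, Z = _grid_world(spec.shape, spec.spacing)
    ext = min(spec.shape) * spec.spacing / 2.0
    j = spec.jitter
    labels = np.zeros(spec.shape, dtype=np.int32)
    # body: soft-tissue ellipsoid
    a, b, c = ext * 0.92, ext * 0.8, ext * 0.7
    body = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    labels[body] = 1
    # two lateral bone spheres ("iliac wings"); deliberately unequal sizes
    # and offsets so no projection direction is mirror-degenerate
    for lab, side, rf in ((2, -1.0, 0.32), (3, 1.0, 0.22)):
        r_w = ext * (rf + 0.03 * j * rng.uniform(-1, 1))
        cx = side * ext * (0.45 + 0.05 * j * rng.uniform(-1, 1))
        cy = ext * (0.1 * side + 0.05 * j * rng.uniform(-1, 1))
        cz = ext * (-0.08 * side + 0.05 * j * rng.uniform(-1, 1))
        sph = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r_w**2
        labels[sph & body] = lab
    # central bone block ("sacrum"), tilted off the midline
    hx = ext * 0.14
    hy = ext * (0.2 + 0.03 * j * rng.uniform(-1, 1))
    hz = ext * 0.3
    cy0 = -ext * (0.15 + 0.05 * j * rng.uniform(-1, 1))
    blk = (np.abs(X - 0.12 * ext) <= hx) & (np.abs(Y - cy0) <= hy) & (np.abs(Z) <= hz)
    labels[blk & body] = 4
    # small dense off-axis marker ("femoral head"), breaks residual symmetry
    cm = ext * np.array([0.2, 0.3, 0.45])
    mrk = (X - cm[0]) ** 2 + (Y - cm[1]) ** 2 + (Z - cm[2]) ** 2 <= (ext * 0.12) ** 2
    labels[mrk & body] = 5
    mu_of = {0: "air", 1: "soft", 2: "bone", 3: "bone", 4: "bone", 5: "bone"}
    bone_labels = (2, 3, 4, 5)
    return labels, mu_of, bone_labels


def _skull(spec: PhantomSpec, rng: np.random.Generator):
    X, Y, Z = _grid_world(spec.shape, spec.spacing)
    ext = min(spec.shape) * spec.spacing / 2.0
    j = spec.jitter
    labels = np.zeros(spec.shape, dtype=np.int32)
    a = ext * (0.85 + 0.04 * j * rng.uniform(-1, 1))
    b, c = a * 0.92, a * 0.88
    thick = ext * 0.1
    r = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    inner = 1.0 - thick / a
    labels[r <= 1.0] = 2             # bone shell ...
    labels[r <= inner] = 1           # ... around soft interior
    r_core = ext * (0.15 + 0.03 * j * rng.uniform(-1, 1))
    cc = ext * np.array([0.18, -0.12, 0.2])  # off-center: breaks mirror symmetry
    core = (X - cc[0]) ** 2 + (Y - cc[1]) ** 2 + (Z - cc[2]) ** 2 <= r_core**2
    labels[core] = 3                 # dense off-center core
    mu_of = {0: "air", 1: "soft", 2: "bone", 3: "bone"}
    return labels, mu_of, (2, 3)


def _vessels(spec: PhantomSpec, rng: np.random.Generator):
    shape = spec.shape
    sp = spec.spacing
    ext = min(shape) * sp / 2.0
    segments: List[Tuple[np.ndarray, np.ndarray, float]] = []

    def grow(p0, direction, length, radius, depth):
        p1 = p0 + direction * length
        lim = ext * 0.95
        p1 = np.clip(p1, -lim, lim)
        segments.append((p0, p1, radius))
        if depth == 0:
            return
        for _ in range(2):  # binary branching
            ang = rng.uniform(0.3, 0.9)
            axis = rng.normal(size=3)
            axis -= axis @ direction * direction
            nrm = np.linalg.norm(axis)
            axis = axis / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
            d_new = np.cos(ang) * direction + np.sin(ang) * axis
            d_new /= np.linalg.norm(d_new)
            grow(p1, d_new, length * 0.75, radius * 0.75, depth - 1)

    root = np.array([0.0, 0.0, -ext * 0.8])
    grow(root, np.array([0.0, 0.0, 1.0]), ext * 0.55, max(1.5 * sp, ext * 0.05),
         spec.branch_depth)

    X, Y, Z = _grid_world(shape, sp)
    pts = np.stack([X, Y, Z], axis=-1)
    labels = np.zeros(shape, dtype=np.int32)
    for p0, p1, r in segments:
        d = p1 - p0
        L2 = float(d @ d)
        if L2 < 1e-12:
            continue
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist2 = ((pts - closest) ** 2).sum(axis=-1)
        labels[dist2 <= r * r] = 1
    mu_of = {0: "air", 1: "bone"}  # vessels carry the high-contrast level
    return labels, mu_of, (1,), segments


def make_phantom(spec: PhantomSpec) -> Tuple[Volume3D, LabelMap3D, FiducialSet]:
    """Generate (volume, label map, fiducials); bit-identical under a seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "pelvis_like_solids":
        labels, mu_of, bone_labels = _pelvis(spec, rng)
    elif spec.kind == "skull_like_shell":
        labels, mu_of, bone_labels = _skull(spec, rng)
    else:
        labels, mu_of, bone_labels, _ = _vessels(spec, rng)

    mu = np.zeros(spec.shape, dtype=float)
    for lab, cls in mu_of.items():
        mu[labels == lab] = spec.attenuation[cls]
    if spec.texture > 0:
        # multiplicative speckle inside non-air tissue, smoothed to ~2-voxel
        # grain: emulates trabecular/parenchymal texture, which is what gives
        # projections their pose-disambiguating parallax detail
        from scipy.ndimage import gaussian_filter

        speckle = gaussian_filter(rng.standard_normal(spec.shape), 1.0)
        speckle /= max(np.abs(speckle).max(), 1e-12)
        mu = mu * (1.0 + spec.texture * speckle * (labels > 0))
        mu = np.clip(mu, 0.0, None)
    vol = Volume3D.centered(mu, spec.spacing)
    lm = LabelMap3D.like(vol, labels)

    bone_mask = np.isin(labels, list(bone_labels))
    idx = np.argwhere(bone_mask)
    if idx.shape[0] == 0:
        raise ValueError("infeasible phantom spec: no high-attenuation voxels generated")
    take = rng.choice(idx.shape[0], size=min(spec.n_fiducials, idx.shape[0]), replace=False)
    fids = vol.index_to_world(idx[take].astype(float))
    return vol, lm, FiducialSet(fids, name=f"{spec.kind}-seed{spec.seed}")


def make_benchmark_case(
    spec: PhantomSpec,
    ranges: Optional[SamplingRanges] = None,
    n_views: int = 10,
    noise: Optional[AugmentConfig] = None,
    seed: int = 0,
    intrinsics: Optional[Intrinsics] = None,
    nominal_sid: float = 700.0,
    method: str = "trilinear",
    n_points: Optional[int] = None,
) -> Tuple[Volume3D, LabelMap3D, FiducialSet, List[XRay2D]]:
    """Phantom + a set of rendered views with stored ground-truth poses.

    Poses are sampled uniformly from ``ranges``; with ``noise`` given, the
    views pass through the appearance augmentation pipeline (emulating the
    real-vs-synthetic domain gap) while their stored true poses stay exact.
    """
    if n_views < 1:
        raise ValueError("need at least one view")
    ranges = ranges or SamplingRanges()
    vol, lm, fids = make_phantom(spec)
    K = intrinsics or Intrinsics(sdd=1000.0, height=64, width=64, delx=3.0, dely=3.0)
    # independent streams: the pose draws under a given seed do not change
    # when augmentation is toggled on or off
    rng_pose, rng_noise = np.random.default_rng(seed).spawn(2)
    views: List[XRay2D] = []
    for _ in range(n_views):
        p = sample_pose(ranges, rng_pose)
        T = pose_from_radiologic(p, nominal_sid)
        x = render(vol, T, K, method=method, n_points=n_points)
        if noise is not None:
            x = augment_xray(x, noise, rng_noise)
        x.meta.update(
            {"radiologic": p, "nominal_sid": nominal_sid,
             "render_method": method, "n_points": n_points}
        )
        views.append(x)
    return vol, lm, fids, views
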