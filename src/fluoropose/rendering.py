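"""Differentiable X-ray rendering (digitally reconstructed radiographs).

A DRR pixel is the line integral of the linear attenuation coefficient mu
(mm^-1) along the ray from the X-ray source through that detector pixel
(monoenergetic Beer-Lambert; no spectrum, scatter, or detector response).
Two ray-tracing backends are provided:

``siddon``
    Siddon's exact method: the integral is the sum over traversed voxels of
    mu_i times the exact intersection length (mm).  Used for physically exact
    forward rendering and as the reference for label-partitioned rendering.

``trilinear``
    Fixed-count point sampling with trilinear interpolation times the step
    length.  This path is smooth in the C-arm pose almost everywhere, and
    :func:`render_jacobian` returns the analytic forward-mode derivative of
    every pixel with respect to a 6-vector se(3) tangent perturbation of the
    pose — the machinery that drives gradient-based pose refinement.

The tangent chart used for differentiation is the *camera-frame right
perturbation*: with camera-to-world map ``C``, the perturbed pose is
``C . exp(xi)`` where ``xi[:3]`` rotates about the camera axes (radians,
about the source) and ``xi[3:]`` translates along the camera axes (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .geometry import Intrinsics, RigidTransform, detector_grid_camera

__all__ = [
    "Volume3D",
    "LabelMap3D",
    "XRay2D",
    "hu_to_mu",
    "normalize_intensity",
    "render",
    "render_jacobian",
    "render_labels",
]

_EPS_PARALLEL = 1e-12
_SIDDON_MERGE_TOL = 1e-9


@dataclass
class Volume3D:
    """Attenuation voxel grid with world-space geometry.

    ``voxels[i, j, k]`` sits at world position
    ``origin + orientation @ (spacing * (i, j, k))`` — index axis ``i`` runs
    along the first column of ``orientation``, etc.  ``units`` records the
    intensity calibration: ``"mu"`` (linear attenuation, mm^-1), ``"hu"``
    (Hounsfield, must be converted before rendering), or ``"normalized"``
    (min-max pseudo-attenuation for MR-like volumes).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    units: str = "mu"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.abs(self.orientation.T @ self.orientation - np.eye(3)).max() > 1e-5:
            raise ValueError("orientation must be orthonormal")
        if self.units == "mu" and np.any(self.voxels < 0):
            raise ValueError("attenuation volume has negative voxels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @staticmethod
    def centered(voxels: np.ndarray, spacing, units: str = "mu") -> "Volume3D":
        """Volume whose world origin (the isocenter) is the grid center."""
        voxels = np.asarray(voxels, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
        center = (np.array(voxels.shape) - 1) / 2.0
        return Volume3D(voxels, spacing, origin=-center * spacing, units=units)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm points (..., 3) to continuous voxel-index coordinates."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.orientation) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return (idx * self.spacing) @ self.orientation.T + self.origin

    def isocenter(self) -> np.ndarray:
        """World position of the grid center."""
        center = (np.array(self.shape) - 1) / 2.0
        return self.index_to_world(center)


@dataclass
class LabelMap3D:
    """Integer label grid sharing a parent volume's geometry (0 = background)."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)

    @staticmethod
    def like(vol: Volume3D, labels: np.ndarray) -> "LabelMap3D":
        labels = np.asarray(labels)
        if labels.shape != vol.shape:
            raise ValueError("label map shape must match the parent volume")
        return LabelMap3D(labels, vol.spacing.copy(), vol.origin.copy(), vol.orientation.copy())

    def check_aligned(self, vol: Volume3D) -> None:
        if self.labels.shape != vol.shape or not (
            np.allclose(self.spacing, vol.spacing)
            and np.allclose(self.origin, vol.origin)
            and np.allclose(self.orientation, vol.orientation)
        ):
            raise ValueError("label map is not aligned with the volume")


@dataclass
class XRay2D:
    """2D line-integral image + detector intrinsics (+ optional true pose)."""

    pixels: np.ndarray
    intrinsics: Intrinsics
    true_pose: Optional[RigidTransform] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != self.intrinsics.shape:
            raise ValueError(
                f"pixel array {self.pixels.shape} does not match intrinsics "
                f"{self.intrinsics.shape}"
            )


def hu_to_mu(ct: Volume3D, mu_water: float = 0.02) -> Volume3D:
    """Convert a Hounsfield-calibrated CT to linear attenuation (mm^-1).

    mu = mu_water * (1 + HU/1000), clamped below at zero (air at -1000 HU
    maps exactly to 0).  Geometry is unchanged.
    """
    if ct.units != "hu":
        raise ValueError(
            f"hu_to_mu requires an HU-calibrated volume, got units={ct.units!r}"
        )
    mu = np.clip(mu_water * (1.0 + ct.voxels / 1000.0), 0.0, None)
    return Volume3D(mu, ct.spacing.copy(), ct.origin.copy(), ct.orientation.copy(), units="mu")


def normalize_intensity(vol: Volume3D) -> Volume3D:
    """Min-max normalize MR/MRA-style intensities to [0, 1] pseudo-attenuation."""
    v = vol.voxels
    lo, hi = float(v.min()), float(v.max())
    out = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    return Volume3D(out, vol.spacing.copy(), vol.origin.copy(), vol.orientation.copy(),
                    units="normalized")


# ---------------------------------------------------------------------------
# Ray setup
# ---------------------------------------------------------------------------

def _ray_geometry(vol: Volume3D, T: RigidTransform, K: Intrinsics,
                  pixel_rc: Optional[np.ndarray] = None):
    """Source and unit ray directions in world and index coordinates.

    Returns (s_w, q_w, u_w, L, s_idx, u_idx, A) where rays are flattened to
    (n_rays, 3).  ``A`` is the 3x3 world-direction -> index-direction map.
    ``t`` along a ray is measured in world mm from the source.
    """
    if not np.all(np.isfinite(vol.voxels)):
        raise ValueError("volume contains non-finite voxels")
    C = T.inverse()  # camera -> world
    s_w = C.translation  # source position = camera origin in world
    if pixel_rc is None:
        q_cam = detector_grid_camera(K).reshape(-1, 3)
    else:
        pixel_rc = np.atleast_2d(np.asarray(pixel_rc))
        grid = detector_grid_camera(K)
        q_cam = grid[pixel_rc[:, 0], pixel_rc[:, 1], :]
    q_w = C.apply(q_cam)
    d = q_w - s_w
    L = np.linalg.norm(d, axis=-1, keepdims=True)
    u_w = d / L
    A = (vol.orientation / vol.spacing[None, :]).T  # maps world dirs to index dirs
    s_idx = np.broadcast_to(vol.world_to_index(s_w), u_w.shape).copy()
    u_idx = u_w @ A.T
    return s_w, q_cam, u_w, L[:, 0], s_idx, u_idx, A


def _slab_intersect(shape, s_idx, u_idx):
    """Ray / voxel-grid bounding-box intersection (slab method).

    The box spans [-0.5, n_a - 0.5] in continuous index coordinates along
    each axis.  Returns (t_near, t_far, near_axis, far_axis, near_plane,
    far_plane); rays that miss have t_far <= t_near.
    """
    n = np.asarray(shape, dtype=float)
    lo, hi = -0.5, n - 0.5
    u = np.where(np.abs(u_idx) < _EPS_PARALLEL, _EPS_PARALLEL, u_idx)
    t_lo = (lo - s_idx) / u
    t_hi = (hi - s_idx) / u
    t_min = np.minimum(t_lo, t_hi)
    t_max = np.maximum(t_lo, t_hi)
    # parallel rays: inside the slab -> (-inf, +inf); outside -> miss
    parallel = np.abs(u_idx) < _EPS_PARALLEL
    inside = (s_idx >= lo) & (s_idx <= hi)
    t_min = np.where(parallel, np.where(inside, -np.inf, np.inf), t_min)
    t_max = np.where(parallel, np.where(inside, np.inf, -np.inf), t_max)
    near_axis = np.argmax(t_min, axis=-1)
    far_axis = np.argmin(t_max, axis=-1)
    rows = np.arange(t_min.shape[0])
    t_near = t_min[rows, near_axis]
    t_far = t_max[rows, far_axis]
    # which plane (lo or hi) is hit, for derivative bookkeeping
    near_plane = np.where(u_idx[rows, near_axis] > 0, lo, hi[near_axis])
    far_plane = np.where(u_idx[rows, far_axis] > 0, hi[far_axis], lo)
    return t_near, t_far, near_axis, far_axis, near_plane, far_plane


# ---------------------------------------------------------------------------
# Siddon's exact method
# ---------------------------------------------------------------------------

def _siddon_integrate(mu_flat, shape, s_idx, u_idx, t_near, t_far):
    """Exact per-voxel path-length integration, vectorized over rays."""
    n_rays = s_idx.shape[0]
    hit = t_far > t_near + _SIDDON_MERGE_TOL
    t0 = np.where(hit, t_near, 0.0)
    t1 = np.where(hit, t_far, 0.0)

    crossings = [t0[:, None], t1[:, None]]
    for a in range(3):
        planes = np.arange(shape[a] + 1) - 0.5
        u_a = np.where(np.abs(u_idx[:, a]) < _EPS_PARALLEL, _EPS_PARALLEL, u_idx[:, a])
        t = (planes[None, :] - s_idx[:, a, None]) / u_a[:, None]
        t = np.where(np.abs(u_idx[:, a, None]) < _EPS_PARALLEL, t0[:, None], t)
        t = np.clip(t, t0[:, None], t1[:, None])
        crossings.append(t)
    t_all = np.concatenate(crossings, axis=1)
    t_all.sort(axis=1)
    dt = np.diff(t_all, axis=1)  # mm
    t_mid = 0.5 * (t_all[:, :-1] + t_all[:, 1:])
    # voxel containing each segment midpoint; floor(x + 0.5) puts a midpoint
    # that lands exactly on a face into the voxel on the positive-normal side
    vox = np.floor(t_mid[:, :, None] * u_idx[:, None, :] + s_idx[:, None, :] + 0.5).astype(np.int64)
    for a in range(3):
        np.clip(vox[:, :, a], 0, shape[a] - 1, out=vox[:, :, a])
    flat = (vox[:, :, 0] * shape[1] + vox[:, :, 1]) * shape[2] + vox[:, :, 2]
    seg_mu = mu_flat[flat]
    seg_mu = np.where(dt > _SIDDON_MERGE_TOL, seg_mu, 0.0)
    out = np.einsum("rs,rs->r", seg_mu, np.where(dt > _SIDDON_MERGE_TOL, dt, 0.0))
    return np.where(hit, out, 0.0)


# ---------------------------------------------------------------------------
# Trilinear sampling (value + exact interpolation gradient)
# ---------------------------------------------------------------------------

def _trilinear(mu_pad, shape, pts, want_grad: bool):
    """Zero-padded trilinear interpolation at continuous index points.

    ``mu_pad`` is the volume padded by one zero voxel per side; ``pts`` has
    shape (..., 3) in unpadded index coordinates.  Returns (values, grad)
    where grad is the exact derivative w.r.t. the index coordinates (or None).
    """
    q = pts + 1.0  # padded coordinates
    i0 = np.floor(q).astype(np.int64)
    for a in range(3):
        np.clip(i0[..., a], 0, shape[a], out=i0[..., a])
    f = q - i0
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    sx, sy, sz = shape[0] + 2, shape[1] + 2, shape[2] + 2
    base = (i0[..., 0] * sy + i0[..., 1]) * sz + i0[..., 2]
    m = mu_pad.ravel()
    c000 = m[base]
    c001 = m[base + 1]
    c010 = m[base + sz]
    c011 = m[base + sz + 1]
    c100 = m[base + sy * sz]
    c101 = m[base + sy * sz + 1]
    c110 = m[base + sy * sz + sz]
    c111 = m[base + sy * sz + sz + 1]
    c00 = c000 + fz * (c001 - c000)
    c01 = c010 + fz * (c011 - c010)
    c10 = c100 + fz * (c101 - c100)
    c11 = c110 + fz * (c111 - c110)
    c0 = c00 + fy * (c01 - c00)
    c1 = c10 + fy * (c11 - c10)
    val = c0 + fx * (c1 - c0)
    if not want_grad:
        return val, None
    gx = c1 - c0
    d00 = c001 - c000
    d01 = c011 - c010
    d10 = c101 - c100
    d11 = c111 - c110
    gz = (d00 + fy * (d01 - d00)) * (1 - fx) + (d10 + fy * (d11 - d10)) * fx
    gy = (c01 - c00) * (1 - fx) + (c11 - c10) * fx
    return val, np.stack([gx, gy, gz], axis=-1)


def _default_n_points(vol: Volume3D) -> int:
    return 2 * max(vol.shape)


def _trilinear_forward(vol, s_idx, u_idx, t_near, t_far, n_points):
    """Midpoint-rule trilinear line integrals (numba kernel when available)."""
    hit = t_far > t_near
    t0 = np.where(hit, t_near, 0.0)
    dt_tot = np.where(hit, t_far - t_near, 0.0)
    mu_pad = np.pad(vol.voxels, 1)
    if _kernels.HAVE_NUMBA:
        return _kernels.trilinear_integrate(
            mu_pad, np.ascontiguousarray(s_idx), np.ascontiguousarray(u_idx),
            t0, dt_tot, n_points,
        )
    frac = (np.arange(n_points) + 0.5) / n_points
    t_i = t0[:, None] + frac[None, :] * dt_tot[:, None]
    pts = s_idx[:, None, :] + t_i[:, :, None] * u_idx[:, None, :]
    val, _ = _trilinear(mu_pad, vol.shape, pts, False)
    return val.sum(axis=1) * (dt_tot / n_points)


def _trilinear_moments(vol, s_idx, u_idx, t_near, t_far, n_points):
    """Line integrals + per-ray gradient moments for the pose Jacobian."""
    hit = t_far > t_near
    t0 = np.where(hit, t_near, 0.0)
    dt_tot = np.where(hit, t_far - t_near, 0.0)
    mu_pad = np.pad(vol.voxels, 1)
    if _kernels.HAVE_NUMBA:
        out = _kernels.trilinear_integrate_moments(
            mu_pad, np.ascontiguousarray(s_idx), np.ascontiguousarray(u_idx),
            t0, dt_tot, n_points,
        )
        return (*out, hit)
    frac = (np.arange(n_points) + 0.5) / n_points
    t_i = t0[:, None] + frac[None, :] * dt_tot[:, None]
    pts = s_idx[:, None, :] + t_i[:, :, None] * u_idx[:, None, :]
    val, grad = _trilinear(mu_pad, vol.shape, pts, True)
    integral = val.sum(axis=1) * (dt_tot / n_points)
    G0 = grad.sum(axis=1)
    G1 = np.einsum("rn,rnj->rj", t_i, grad)
    gu = np.einsum("rnj,rj->rn", grad, u_idx)
    return integral, val.sum(axis=1), G0, G1, gu.sum(axis=1), gu @ frac, hit


def render(
    vol: Volume3D,
    T: RigidTransform,
    K: Intrinsics,
    method: str = "trilinear",
    n_points: Optional[int] = None,
    ray_subset: Optional[np.ndarray] = None,
    true_pose_in_meta: bool = True,
) -> XRay2D:
    """Render a DRR of ``vol`` seen from world->camera pose ``T``.

    Parameters
    ----------
    method : "siddon" (exact voxel path lengths) or "trilinear" (point
        sampling, differentiable).
    n_points : samples per ray for trilinear; default 2 x max volume
        dimension, placed at segment midpoints between the entry and exit of
        the volume bounding box.
    ray_subset : optional (M, 2) integer array of (row, col) pixels; only
        those rays are computed (sparse rendering), other pixels are zero and
        the subset is recorded in ``meta["ray_subset"]``.
    """
    if vol.units == "hu":
        raise ValueError("volume is HU-calibrated; convert with hu_to_mu before rendering")
    if method not in ("siddon", "trilinear"):
        raise ValueError(f"unknown rendering method {method!r}")
    s_w, q_cam, u_w, L, s_idx, u_idx, A = _ray_geometry(vol, T, K, ray_subset)
    t_near, t_far, *_ = _slab_intersect(vol.shape, s_idx, u_idx)
    if method == "siddon":
        values = _siddon_integrate(vol.voxels.ravel(), vol.shape, s_idx, u_idx, t_near, t_far)
    else:
        n = n_points if n_points is not None else _default_n_points(vol)
        if n < 2:
            raise ValueError("trilinear rendering requires n_points >= 2")
        values = _trilinear_forward(vol, s_idx, u_idx, t_near, t_far, n)
    meta = {"method": method}
    if ray_subset is None:
        pixels = values.reshape(K.shape)
    else:
        pixels = np.zeros(K.shape)
        rc = np.atleast_2d(np.asarray(ray_subset))
        pixels[rc[:, 0], rc[:, 1]] = values
        meta["ray_subset"] = rc
    return XRay2D(pixels, K, true_pose=T if true_pose_in_meta else None, meta=meta)


def render_jacobian(
    vol: Volume3D,
    T: RigidTransform,
    K: Intrinsics,
    n_points: Optional[int] = None,
) -> Tuple[XRay2D, np.ndarray]:
    """Trilinear rendering plus the analytic pose Jacobian.

    Returns ``(image, J)`` with ``J`` of shape (6, H, W):
    ``J[k]`` is the derivative of every pixel with respect to the k-th
    camera-frame tangent coordinate of the pose (rotations about the camera
    axes in radians for k=0..2, translations along them in mm for k=3..5),
    evaluated at the rendered pose.  The derivative accounts for the motion
    of the ray directions *and* of the bounding-box entry/exit points, so it
    matches central finite differences of the renderer away from the
    (measure-zero) voxel-face and slab-switch configurations.
    """
    if vol.units == "hu":
        raise ValueError("volume is HU-calibrated; convert with hu_to_mu before rendering")
    n = n_points if n_points is not None else _default_n_points(vol)
    C = T.inverse()
    R_cw = C.rotation
    s_w, q_cam, u_w, L, s_idx, u_idx, A = _ray_geometry(vol, T, K)
    t_near, t_far, near_ax, far_ax, near_pl, far_pl = _slab_intersect(vol.shape, s_idx, u_idx)
    # Per-ray sample moments: the sum over samples of grad . dp factorizes as
    #   G0 . ds  +  G1 . du  +  (sum grad.u) dt_near  +  (sum frac*(grad.u)) dDt
    # because dp_i = ds + t_i du + (dt_near + frac_i dDt) u.
    integral, val_sum, G0, G1, gu_sum, guf_sum, hit = _trilinear_moments(
        vol, s_idx, u_idx, t_near, t_far, n
    )
    dt = np.where(hit, t_far - t_near, 0.0) / n
    n_rays = s_idx.shape[0]
    rows = np.arange(n_rays)

    J = np.zeros((6, n_rays))
    e = np.eye(3)
    u_na = u_idx[rows, near_ax]
    u_fa = u_idx[rows, far_ax]
    u_na = np.where(np.abs(u_na) < _EPS_PARALLEL, _EPS_PARALLEL, u_na)
    u_fa = np.where(np.abs(u_fa) < _EPS_PARALLEL, _EPS_PARALLEL, u_fa)
    for k in range(6):
        if k < 3:
            ds_w = np.zeros(3)  # rotation about the source leaves it fixed
            dq_w = np.cross(e[k][None, :], q_cam) @ R_cw.T
        else:
            ds_w = R_cw @ e[k - 3]
            dq_w = np.broadcast_to(R_cw @ e[k - 3], q_cam.shape)
        dd = dq_w - ds_w[None, :]
        dL = np.einsum("rj,rj->r", u_w, dd)
        du_w = (dd - u_w * dL[:, None]) / L[:, None]
        ds_idx = A @ ds_w
        du_idx = du_w @ A.T
        dt_near = np.where(hit, (-ds_idx[near_ax] - t_near * du_idx[rows, near_ax]) / u_na, 0.0)
        dt_far = np.where(hit, (-ds_idx[far_ax] - t_far * du_idx[rows, far_ax]) / u_fa, 0.0)
        d_dtot = dt_far - dt_near
        dirsum = (
            G0 @ ds_idx
            + np.einsum("rj,rj->r", G1, du_idx)
            + gu_sum * dt_near
            + guf_sum * d_dtot
        )
        J[k] = np.where(hit, dirsum * dt + val_sum * (d_dtot / n), 0.0)

    img = XRay2D(integral.reshape(K.shape), K, true_pose=T, meta={"method": "trilinear"})
    return img, J.reshape(6, *K.shape)


def render_labels(
    vol: Volume3D,
    lm: LabelMap3D,
    structures: Iterable[int],
    T: RigidTransform,
    K: Intrinsics,
    method: str = "siddon",
    n_points: Optional[int] = None,
) -> Dict[int, XRay2D]:
    """Structure-specific DRRs: one image per requested label.

    Each image integrates attenuation only where the label map matches, so
    the renderings over a full partition of the labels (including background
    0) sum to the unrestricted rendering — rendering is linear in mu.
    """
    lm.check_aligned(vol)
    present = set(np.unique(lm.labels).tolist())
    out: Dict[int, XRay2D] = {}
    for lab in structures:
        if int(lab) not in present:
            raise ValueError(f"structure label {lab} is absent from the label map")
        masked = Volume3D(
            vol.voxels * (lm.labels == int(lab)),
            vol.spacing.copy(), vol.origin.copy(), vol.orientation.copy(), units=vol.units,
        )
        img = render(masked, T, K, method=method, n_points=n_points)
        img.meta["structure"] = int(lab)
        out[int(lab)] = img
    return out
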