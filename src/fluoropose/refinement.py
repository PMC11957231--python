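"""Multiscale gradient-based iterative pose refinement.

Registration maximizes an intensity similarity (global or patchwise
normalized cross-correlation) between the observed X-ray and differentiable
renderings of the volume, with respect to the C-arm pose.  The pose is
parameterized in the se(3) tangent chart anchored at the *current* pose
(re-anchored every iteration, so the chart never distorts), and the analytic
pose Jacobian of the renderer is chained with the analytic image gradient of
the similarity — no finite differences anywhere.

Optimization runs coarse-to-fine over a detector pyramid: at factor ``f``
the observed image is block-mean pooled ``f x f`` and renderings use the
correspondingly rescaled intrinsics, enlarging the capture range before the
full-resolution polish.  The optimizer is Adam (first-order adaptive ascent)
with separate step sizes for the rotational (radian-scale) and translational
(mm-scale) parameter groups, decayed within each level for final precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Intrinsics, RigidTransform, se3_exp
from .rendering import Volume3D, XRay2D, render_jacobian

__all__ = [
    "RefineConfig",
    "RegistrationResult",
    "image_similarity",
    "similarity_and_image_grad",
    "similarity_pose_gradient",
    "refine_pose",
]

_VAR_TOL = 1e-24


def _ncc_and_grad(a: np.ndarray, b: np.ndarray, want_grad: bool):
    """Pearson NCC of two equal-size pixel sets and d(ncc)/d(b pixels)."""
    a0 = a - a.mean()
    b0 = b - b.mean()
    na = np.sqrt((a0 * a0).sum())
    nb = np.sqrt((b0 * b0).sum())
    if na * na < _VAR_TOL and nb * nb < _VAR_TOL:
        raise ValueError("undefined similarity: both images are constant")
    if na * na < _VAR_TOL or nb * nb < _VAR_TOL:
        raise ValueError("undefined similarity: an image has zero variance")
    s = float((a0 * b0).sum() / (na * nb))
    if not want_grad:
        return s, None
    g = a0 / (na * nb) - s * b0 / (nb * nb)
    return s, g  # already zero-mean, so the centering projector is implicit


def _patches(img: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping p x p patch stack (remainder rows/cols cropped)."""
    H, W = img.shape
    hh, ww = (H // p) * p, (W // p) * p
    if hh == 0 or ww == 0:
        raise ValueError(f"image {img.shape} smaller than the {p}-pixel patch")
    v = img[:hh, :ww].reshape(hh // p, p, ww // p, p)
    return v.transpose(0, 2, 1, 3).reshape(-1, p * p)


def _local_ncc_and_grad(a: np.ndarray, b: np.ndarray, p: int, want_grad: bool):
    pa = _patches(a, p)
    pb = _patches(b, p)
    a0 = pa - pa.mean(axis=1, keepdims=True)
    b0 = pb - pb.mean(axis=1, keepdims=True)
    va = (a0 * a0).sum(axis=1)
    vb = (b0 * b0).sum(axis=1)
    valid = (va > _VAR_TOL) & (vb > _VAR_TOL)
    if not np.any(valid):
        raise ValueError("undefined similarity: no patch has intensity variance")
    na = np.sqrt(np.where(valid, va, 1.0))
    nb = np.sqrt(np.where(valid, vb, 1.0))
    s_patch = (a0 * b0).sum(axis=1) / (na * nb)
    nv = int(valid.sum())
    s = float(s_patch[valid].mean())
    if not want_grad:
        return s, None
    g_patch = (a0 / (na * nb)[:, None] - s_patch[:, None] * b0 / (nb * nb)[:, None]) / nv
    g_patch[~valid] = 0.0
    H, W = a.shape
    hh, ww = (H // p) * p, (W // p) * p
    g = np.zeros_like(b)
    g[:hh, :ww] = (
        g_patch.reshape(hh // p, ww // p, p, p).transpose(0, 2, 1, 3).reshape(hh, ww)
    )
    return s, g


def similarity_and_image_grad(
    a: np.ndarray, b: np.ndarray, kind: str = "ncc", patch: int = 13,
    want_grad: bool = True,
):
    """Similarity in [-1, 1] and its gradient with respect to ``b``'s pixels.

    ``ncc`` is the Pearson correlation of the flattened images; ``local_ncc``
    averages patchwise NCC over a non-overlapping grid (zero-variance patches
    skipped).  Both are invariant to positive affine intensity maps of either
    image.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if kind == "ncc":
        return _ncc_and_grad(a, b, want_grad)
    if kind == "local_ncc":
        return _local_ncc_and_grad(a, b, patch, want_grad)
    raise ValueError(f"unknown similarity kind {kind!r}")


def image_similarity(a: XRay2D, b: XRay2D, kind: str = "ncc", patch: int = 13) -> float:
    """Similarity of two X-ray images (see :func:`similarity_and_image_grad`)."""
    s, _ = similarity_and_image_grad(a.pixels, b.pixels, kind, patch, want_grad=False)
    return s


def similarity_pose_gradient(
    target: np.ndarray,
    vol: Volume3D,
    K: Intrinsics,
    pose: RigidTransform,
    kind: str = "local_ncc",
    patch: int = 13,
    n_points: Optional[int] = None,
) -> Tuple[float, np.ndarray]:
    """Similarity of (target, rendering at pose) and its analytic gradient
    with respect to the camera-frame se(3) tangent coordinates of the pose."""
    img, J = render_jacobian(vol, pose, K, n_points=n_points)
    s, g_img = similarity_and_image_grad(target, img.pixels, kind, patch)
    grad = np.einsum("khw,hw->k", J, g_img)
    return s, grad


@dataclass
class RefineConfig:
    """Configuration of the multiscale refinement optimizer.

    pyramid : detector downsampling factors, descending, last usually 1.
        Repeating the finest factor (the default repeats level 1) runs a
        warm-restart pass: Adam moments reset and the step size re-anneals,
        which reliably escapes the shallow valley along the near-degenerate
        rotate-about-source/translate direction before the final polish.
    iterations : Adam iterations per pyramid level.
    lr_rot, lr_trans : step sizes for the rotation (radians) and translation
        (mm) groups.
    lr_decay : final fraction of the step size at the end of each level
        (cosine schedule); 1.0 disables decay.
    similarity : "ncc" or "local_ncc"; ``patch`` is the local_ncc patch size.
    tol : stop a level when the best similarity improves by less than this
        over ``patience`` iterations.
    """

    pyramid: Sequence[int] = (4, 2, 1, 1)
    iterations: Sequence[int] = (60, 60, 100, 100)
    lr_rot: float = 7.5e-3
    lr_trans: float = 1.0
    lr_decay: float = 0.02
    similarity: str = "local_ncc"
    patch: int = 16
    tol: float = 1e-5
    patience: int = 40
    max_total_iterations: int = 1000
    n_points: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        fac = list(self.pyramid)
        if any(f < 1 for f in fac) or any(
            fac[i] < fac[i + 1] for i in range(len(fac) - 1)
        ):
            raise ValueError("pyramid factors must be >= 1 and descending")
        if len(self.iterations) != len(fac):
            raise ValueError("need one iteration count per pyramid level")
        if any(i <= 0 for i in self.iterations):
            raise ValueError("iterations must be positive")
        if self.lr_rot <= 0 or self.lr_trans <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class RegistrationResult:
    """Outcome of an iterative registration."""

    init_pose: RigidTransform
    final_pose: RigidTransform
    trace: List[Tuple[int, float]]
    converged: bool
    n_renderings: int
    final_similarity: float = float("nan")

    def to_dict(self, nominal_sid: float = 0.0) -> dict:
        return {
            "init_matrix": [float(x) for x in self.init_pose.matrix().ravel()],
            "final_matrix": [float(x) for x in self.final_pose.matrix().ravel()],
            "converged": bool(self.converged),
            "n_renderings": int(self.n_renderings),
            "final_similarity": float(self.final_similarity),
            "trace": [[int(l), float(s)] for l, s in self.trace],
            "nominal_sid": float(nominal_sid),
        }


def _pool(img: np.ndarray, f: int, H: int, W: int) -> np.ndarray:
    """Block-mean pooling to (H, W) at factor f (cropping any remainder)."""
    if f == 1:
        return img
    return img[: H * f, : W * f].reshape(H, f, W, f).mean(axis=(1, 3))


def refine_pose(
    x: XRay2D,
    vol: Volume3D,
    K: Optional[Intrinsics] = None,
    init: Optional[RigidTransform] = None,
    cfg: Optional[RefineConfig] = None,
) -> RegistrationResult:
    """Refine ``init`` by multiscale gradient ascent on image similarity.

    The best-similarity pose seen at the finest level is returned whether or
    not the optimizer converged; ``converged`` is cleared when the final
    similarity fell below the initial one at the finest level (divergence)
    or the iteration budget ran out while still improving.
    """
    if K is None:
        K = x.intrinsics
    if x.pixels.shape != K.shape:
        raise ValueError("observed image does not match the intrinsics")
    if init is None:
        raise ValueError("refine_pose requires an initial pose")
    cfg = cfg or RefineConfig()

    C = init.inverse()  # optimize the camera->world map
    trace: List[Tuple[int, float]] = []
    n_render = 0
    total_iters = 0
    best_fine: Tuple[float, RigidTransform] = (-np.inf, init)
    init_fine_sim = None
    tol_stopped = False

    for level, (f, n_iter) in enumerate(zip(cfg.pyramid, cfg.iterations)):
        Kf = K.downsample(int(f))
        target = _pool(x.pixels, int(f), Kf.height, Kf.width)
        finest = int(f) == int(cfg.pyramid[-1])
        m = np.zeros(6)
        v = np.zeros(6)
        best_level = -np.inf
        since_improve = 0
        for it in range(int(n_iter)):
            if total_iters >= cfg.max_total_iterations:
                break
            pose = C.inverse()
            s, grad = similarity_pose_gradient(
                target, vol, Kf, pose, cfg.similarity, cfg.patch, cfg.n_points
            )
            n_render += 1
            total_iters += 1
            if not np.isfinite(s) or not np.all(np.isfinite(grad)):
                raise FloatingPointError(
                    f"non-finite similarity/gradient at level {f}, iteration {it}; "
                    f"trace so far: {trace[-5:]}"
                )
            trace.append((int(f), s))
            if finest:
                if init_fine_sim is None:
                    init_fine_sim = s
                if s > best_fine[0]:
                    best_fine = (s, pose)
            if s > best_level + cfg.tol:
                best_level = max(best_level, s)
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= cfg.patience:
                    tol_stopped = True
                    break
            # Adam ascent step in the tangent chart anchored at the current pose
            t = it + 1
            m = 0.9 * m + 0.1 * grad
            v = 0.999 * v + 0.001 * grad * grad
            mh = m / (1 - 0.9**t)
            vh = v / (1 - 0.999**t)
            step = mh / (np.sqrt(vh) + 1e-12)
            decay = cfg.lr_decay + (1 - cfg.lr_decay) * 0.5 * (
                1 + np.cos(np.pi * it / max(1, n_iter - 1))
            )
            step[:3] *= cfg.lr_rot * decay
            step[3:] *= cfg.lr_trans * decay
            C = C @ se3_exp(step)

    # score the last pose at the finest level too
    Kf = K.downsample(int(cfg.pyramid[-1]))
    target = _pool(x.pixels, int(cfg.pyramid[-1]), Kf.height, Kf.width)
    pose = C.inverse()
    from .rendering import render

    img = render(vol, pose, Kf, method="trilinear", n_points=cfg.n_points)
    n_render += 1
    s, _ = similarity_and_image_grad(
        target, img.pixels, cfg.similarity, cfg.patch, want_grad=False
    )
    trace.append((int(cfg.pyramid[-1]), s))
    if s > best_fine[0]:
        best_fine = (s, pose)

    diverged = init_fine_sim is not None and best_fine[0] < init_fine_sim - 1e-6
    converged = (not diverged) and (tol_stopped or total_iters < cfg.max_total_iterations)
    return RegistrationResult(
        init_pose=init,
        final_pose=best_fine[1],
        trace=trace,
        converged=bool(converged),
        n_renderings=n_render,
        final_similarity=float(best_fine[0]),
    )
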