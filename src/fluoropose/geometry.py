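"""SE(3) pose algebra, the radiologic C-arm parameterization, and perspective
projection onto the detector.

Conventions
-----------
World frame
    Right-handed, millimeters, origin at the volume isocenter (the geometric
    center of the voxel grid unless overridden).  Axes are patient-anatomical:
    ``+x`` = patient left-to-right ("R"-ward in an RAS sense), ``+y`` =
    anterior, ``+z`` = superior.

Camera frame
    The X-ray source sits at the camera origin and the principal ray runs
    along camera ``+z`` toward the detector plane at distance ``sdd``.
    Camera ``x``/``y`` are parallel to the detector column/row axes.

Canonical frontal pose
    With all radiologic parameters zero and nominal source-to-isocenter
    distance ``s0``, the source lies on the patient-anterior axis at
    ``(0, s0, 0)`` world mm, the principal ray passes through the isocenter,
    detector columns run along world ``+x`` and detector rows along world
    ``+z``.

Radiologic chart
    ``alpha`` rotates the gantry about the patient superior-inferior axis
    (LAO positive / RAO negative), ``beta`` about the patient left-right axis
    (CRA positive / CAU negative), and ``gamma`` rolls the detector about the
    principal ray.  The rotations compose intrinsically in that order.
    ``(bx, by, bz)`` translate the source rigidly in the rotated gantry
    frame; ``by`` is the signed offset of the actual source-to-isocenter
    distance from the nominal SID.  Angles are degrees at every interface
    (radians internally); all lengths are mm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "RadiologicParams",
    "Intrinsics",
    "GimbalLockError",
    "pose_from_radiologic",
    "radiologic_from_pose",
    "se3_exp",
    "se3_log",
    "project_points",
    "pose_geodesic",
    "detector_grid_camera",
    "pose_to_json",
    "pose_from_json",
]

_ORTHO_TOL = 1e-6

# Canonical camera orientation: rows of the world->camera rotation at the
# all-zero radiologic pose (camera axes expressed in world coordinates).
_R0_WC = np.array(
    [
        [1.0, 0.0, 0.0],   # camera x = world +x (patient left-right)
        [0.0, 0.0, 1.0],   # camera y = world +z (patient superior)
        [0.0, -1.0, 0.0],  # camera z = world -y (anterior -> posterior ray)
    ]
)


class GimbalLockError(ValueError):
    """Raised when the radiologic chart is degenerate (|beta| = 90 deg).

    At this configuration the alpha (LAO/RAO) and gamma (detector roll) axes
    align and only their sum/difference is observable.
    """


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > _ORTHO_TOL * 100:
        raise ValueError(f"rotation is not orthogonal (max |R'R - I| = {err:.2e})")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation has determinant -1 (reflection)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``x_cam = R @ x_world + t`` (rotation dimensionless, t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self @ other`` (apply ``other`` first)."""
        R = self.rotation @ other.rotation
        t = self.rotation @ other.translation + self.translation
        # Re-orthonormalize to keep long composition chains on SO(3).
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1
            R = U @ Vt
        return RigidTransform(R, t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map points (..., 3) through the transform."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(M[:3, :3], M[:3, 3])

    @property
    def camera_center(self) -> np.ndarray:
        """World position of the camera origin (the X-ray source), mm."""
        return -self.rotation.T @ self.translation

    def isclose(self, other: "RigidTransform", rtol: float = 1e-8, atol: float = 1e-8) -> bool:
        return np.allclose(self.rotation, other.rotation, rtol=rtol, atol=atol) and np.allclose(
            self.translation, other.translation, rtol=rtol, atol=atol
        )


@dataclass(frozen=True)
class RadiologicParams:
    """C-arm pose in radiologic coordinates.

    alpha, beta, gamma in degrees; bx, by, bz in mm.  ``by`` is the signed
    offset of the source-to-isocenter distance from the nominal SID.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    bx: float = 0.0
    by: float = 0.0
    bz: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.bx, self.by, self.bz])

    @staticmethod
    def from_array(v: Iterable[float]) -> "RadiologicParams":
        a = np.asarray(list(v), dtype=float)
        if a.shape != (6,):
            raise ValueError("expected 6 parameters (alpha, beta, gamma, bx, by, bz)")
        return RadiologicParams(*a)


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole detector model.

    sdd : source-to-detector distance, mm.
    delx, dely : pixel spacing, mm/pixel (columns, rows).
    x0, y0 : principal-point offset from the detector center, mm.
    height, width : detector size in pixels.  Pixel (0, 0) is the top-left
    pixel center; row index v increases along camera +y, column index u
    along camera +x.
    """

    sdd: float
    height: int
    width: int
    delx: float
    dely: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self):
        if not self.sdd > 0:
            raise ValueError("sdd must be positive")
        if not (self.delx > 0 and self.dely > 0):
            raise ValueError("pixel spacing must be positive")
        if self.height < 1 or self.width < 1:
            raise ValueError("detector must have at least one pixel per axis")

    @property
    def shape(self) -> Tuple[int, int]:
        return (int(self.height), int(self.width))

    def downsample(self, factor: int) -> "Intrinsics":
        """Coarser detector covering the same physical extent (pyramid level)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return Intrinsics(
            sdd=self.sdd,
            height=max(1, int(self.height) // factor),
            width=max(1, int(self.width) // factor),
            delx=self.delx * factor,
            dely=self.dely * factor,
            x0=self.x0,
            y0=self.y0,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "Intrinsics":
        return Intrinsics(
            sdd=float(d["sdd"]),
            height=int(d["height"]),
            width=int(d["width"]),
            delx=float(d["delx"]),
            dely=float(d["dely"]),
            x0=float(d.get("x0", 0.0)),
            y0=float(d.get("y0", 0.0)),
        )


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def pose_from_radiologic(p: RadiologicParams, nominal_sid: float) -> RigidTransform:
    """Build the world->camera rigid map from radiologic C-arm parameters.

    The gantry rotation is the intrinsic composition alpha (about patient
    superior-inferior), then beta (about patient left-right), then the
    detector roll gamma about the principal ray.  The source sits at
    ``R_gantry @ (bx, nominal_sid + by, bz)`` in world coordinates.
    """
    a, b, g = np.deg2rad([p.alpha, p.beta, p.gamma])
    R_g = _rot_z(a) @ _rot_x(b)
    # camera->world rotation: gantry * canonical camera axes * roll about camera z
    R_cw = R_g @ _R0_WC.T @ _rot_z(g)
    source_world = R_g @ np.array([p.bx, nominal_sid + p.by, p.bz])
    R_wc = R_cw.T
    return RigidTransform(R_wc, -R_wc @ source_world)


def radiologic_from_pose(T: RigidTransform, nominal_sid: float) -> RadiologicParams:
    """Invert :func:`pose_from_radiologic` on its principal domain.

    Raises
    ------
    GimbalLockError
        If |beta| is within ~1e-4 deg of 90, where alpha and gamma are not
        separately identifiable.
    """
    R_cw = T.rotation.T
    # R_cw = Rz(a) Rx(b) Ry(-g) R0_cw  =>  E = R_cw @ R0_wc is intrinsic Z-X-Y
    E = R_cw @ _R0_WC
    # sin(beta) lives in E[2,1] for intrinsic ZXY: Z(a)X(b)Y(c) has (2,1) = sin(b)
    sb = np.clip(E[2, 1], -1.0, 1.0)
    if abs(abs(sb) - 1.0) < 1e-9:
        raise GimbalLockError(
            "radiologic chart is degenerate at |beta| = 90 deg: the LAO/RAO "
            "(alpha) and detector-roll (gamma) axes coincide"
        )
    a, b, c = Rotation.from_matrix(E).as_euler("ZXY")
    alpha, beta, gamma = np.rad2deg([a, b, -c])
    R_g = _rot_z(a) @ _rot_x(b)
    offs = R_g.T @ T.camera_center
    return RadiologicParams(
        alpha=alpha, beta=beta, gamma=gamma,
        bx=offs[0], by=offs[1] - nominal_sid, bz=offs[2],
    )


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )


def se3_exp(v: np.ndarray) -> RigidTransform:
    """Exponential map se(3) -> SE(3).

    ``v[:3]`` is the rotational part (radians, axis-angle) and ``v[3:]`` the
    translational part (mm); the translation is coupled through the usual
    left-Jacobian ``V`` so that ``exp`` is the true matrix exponential of the
    twist.
    """
    v = np.asarray(v, dtype=float).reshape(6)
    w, rho = v[:3], v[3:]
    theta = np.linalg.norm(w)
    W = _hat(w)
    if theta < 1e-12:
        R = np.eye(3) + W + 0.5 * W @ W
        V = np.eye(3) + 0.5 * W
    else:
        A = np.sin(theta) / theta
        B = (1.0 - np.cos(theta)) / theta**2
        C = (1.0 - A) / theta**2
        R = np.eye(3) + A * W + B * W @ W
        V = np.eye(3) + B * W + C * W @ W
    return RigidTransform(R, V @ rho)


def se3_log(T: RigidTransform) -> np.ndarray:
    """Logarithm map SE(3) -> se(3); inverse of :func:`se3_exp` for rotation
    angle < pi.

    Raises
    ------
    ValueError
        At rotation angle pi, where the axis sign is ambiguous.
    """
    R = T.rotation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if np.pi - theta < 1e-6:
        raise ValueError(
            "se3_log branch point: rotation angle is pi, axis-angle sign is ambiguous"
        )
    if theta < 1e-12:
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2.0
        V_inv = np.eye(3) - 0.5 * _hat(w)
    else:
        w = (
            theta
            / (2.0 * np.sin(theta))
            * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        )
        W = _hat(w)
        V_inv = (
            np.eye(3)
            - 0.5 * W
            + (1.0 / theta**2 - (1.0 + np.cos(theta)) / (2.0 * theta * np.sin(theta)))
            * W
            @ W
        )
    return np.concatenate([w, V_inv @ T.translation])


def detector_grid_camera(K: Intrinsics, rows=None, cols=None) -> np.ndarray:
    """Camera-frame 3D positions (mm) of detector pixel centers.

    Returns an array of shape (len(rows), len(cols), 3) on the plane
    ``z = sdd``.  ``rows``/``cols`` default to the full pixel grid.
    """
    if rows is None:
        rows = np.arange(K.height)
    if cols is None:
        cols = np.arange(K.width)
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    cx = (K.width - 1) / 2.0
    cy = (K.height - 1) / 2.0
    x = (cols - cx) * K.delx - K.x0
    y = (rows - cy) * K.dely - K.y0
    X, Y = np.meshgrid(x, y)
    return np.stack([X, Y, np.full_like(X, K.sdd)], axis=-1)


def project_points(T: RigidTransform, K: Intrinsics, pts: np.ndarray) -> np.ndarray:
    """Pinhole projection of world points (N, 3) mm to detector pixels (N, 2).

    Returned columns are (u, v) = (column, row) pixel coordinates; pixels may
    fall outside the physical detector.  A point at the source (camera depth
    ~0) has no projection and raises ``ValueError``.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    cam = T.apply(pts)
    z = cam[:, 2]
    if np.any(np.abs(z) < 1e-9):
        raise ValueError("singular projection: point coincides with the X-ray source")
    x_mm = cam[:, 0] * K.sdd / z + K.x0
    y_mm = cam[:, 1] * K.sdd / z + K.y0
    u = x_mm / K.delx + (K.width - 1) / 2.0
    v = y_mm / K.dely + (K.height - 1) / 2.0
    return np.stack([u, v], axis=-1)


def pose_geodesic(T1: RigidTransform, T2: RigidTransform) -> Tuple[float, float]:
    """Geodesic rotation distance (degrees) and translation distance (mm)."""
    R = T1.rotation.T @ T2.rotation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    rot_deg = float(np.rad2deg(np.arccos(cos_theta)))
    trans_mm = float(np.linalg.norm(T1.translation - T2.translation))
    return rot_deg, trans_mm


# ---------------------------------------------------------------------------
# Pose JSON schema: {"matrix": 16 row-major floats (world->camera, mm),
#                    "radiologic": {...}, "nominal_sid": float}
# The writer emits both representations; the reader accepts either.
# ---------------------------------------------------------------------------

def pose_to_json(T: RigidTransform, nominal_sid: float) -> str:
    doc = {
        "matrix": [float(x) for x in T.matrix().ravel()],
        "nominal_sid": float(nominal_sid),
    }
    try:
        p = radiologic_from_pose(T, nominal_sid)
        doc["radiologic"] = {
            "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma,
            "bx": p.bx, "by": p.by, "bz": p.bz,
        }
    except GimbalLockError:
        doc["radiologic"] = None
    return json.dumps(doc, indent=2)


def pose_from_json(text: str) -> Tuple[RigidTransform, float]:
    doc = json.loads(text)
    sid = float(doc.get("nominal_sid", 0.0))
    if doc.get("matrix") is not None:
        M = np.array(doc["matrix"], dtype=float).reshape(4, 4)
        return RigidTransform.from_matrix(M), sid
    r = doc["radiologic"]
    p = RadiologicParams(
        alpha=r["alpha"], beta=r["beta"], gamma=r["gamma"],
        bx=r["bx"], by=r["by"], bz=r["bz"],
    )
    return pose_from_radiologic(p, sid), sid
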