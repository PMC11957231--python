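"""I/O for standard medical-imaging formats, the intrinsics-resampling
transform, and DICOM-header pose initialization.

Volumes move through NIfTI (nibabel) or DICOM CT series (pydicom); 2D
X-rays through DICOM (XA/RF, single- or multi-frame) or PNG/TIFF with a
JSON sidecar holding the detector intrinsics.  Volume world coordinates
follow the file affine (RAS-like, mm); every pose/fiducial JSON the package
writes records the conventions so outputs are auditable.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    Intrinsics,
    RadiologicParams,
    RigidTransform,
    pose_from_json,
    pose_from_radiologic,
    pose_to_json,
)
from .rendering import Volume3D, XRay2D, hu_to_mu, normalize_intensity

__all__ = [
    "read_volume",
    "write_volume",
    "read_xray",
    "write_xray",
    "resample_to_intrinsics",
    "pose_from_dicom_angles",
    "read_pose",
    "write_pose",
    "read_fiducials",
    "write_fiducials",
]


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _affine_to_geometry(affine: np.ndarray):
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine: zero-length direction column")
    orientation = M / spacing
    return spacing, affine[:3, 3].copy(), orientation


def _geometry_to_affine(vol: Volume3D) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = vol.orientation * vol.spacing[None, :]
    A[:3, 3] = vol.origin
    return A


def read_volume(path: str, modality: Optional[str] = None, convert: bool = True,
                mu_water: float = 0.02) -> Volume3D:
    """Read a NIfTI file or a DICOM CT series directory into a Volume3D.

    ``modality`` hints the intensity calibration: "ct" (Hounsfield; converted
    to attenuation when ``convert``), "mr" (min-max normalized
    pseudo-attenuation), or None to take the units as already being mm^-1
    attenuation (NIfTI) / Hounsfield (DICOM CT).
    """
    p = Path(path)
    if p.is_dir():
        vol = _read_dicom_series(p)
        modality = modality or "ct"
    else:
        import nibabel as nib

        img = nib.load(str(p))
        spacing, origin, orientation = _affine_to_geometry(img.affine)
        data = np.asarray(img.dataobj, dtype=float)
        units = "hu" if modality == "ct" else ("normalized" if modality == "mr" else "mu")
        vol = Volume3D(data, spacing, origin, orientation,
                       units=units if modality else "mu")
    if modality == "ct" and vol.units != "hu":
        vol = Volume3D(vol.voxels, vol.spacing, vol.origin, vol.orientation, units="hu")
    if convert:
        if modality == "ct":
            vol = hu_to_mu(vol, mu_water=mu_water)
        elif modality == "mr":
            vol = normalize_intensity(vol)
    return vol


def _read_dicom_series(dirpath: Path) -> Volume3D:
    import pydicom

    files = sorted(q for q in dirpath.iterdir() if q.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient"):
            slices.append((f.name, ds))
    if not slices:
        raise ValueError(f"no DICOM slices with geometry found in {dirpath}")
    iops = {tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 6))
            for _, ds in slices}
    if len(iops) != 1:
        raise ValueError(f"inconsistent DICOM series: mixed orientations in {dirpath}")
    row = np.asarray(slices[0][1].ImageOrientationPatient[:3], float)
    col = np.asarray(slices[0][1].ImageOrientationPatient[3:], float)
    normal = np.cross(row, col)
    slices.sort(key=lambda it: float(np.asarray(it[1].ImagePositionPatient, float) @ normal))
    pos = np.array([np.asarray(ds.ImagePositionPatient, float) @ normal for _, ds in slices])
    gaps = np.diff(pos)
    if len(gaps) and (gaps.max() - gaps.min() > 1e-3 * max(1.0, gaps.mean())):
        bad = [slices[i + 1][0] for i in np.nonzero(np.abs(gaps - gaps.mean()) > 1e-3)[0]]
        raise ValueError(f"inconsistent DICOM series: non-uniform slice spacing at {bad}")
    ps = {tuple(np.round(np.asarray(ds.PixelSpacing, float), 6)) for _, ds in slices}
    if len(ps) != 1:
        raise ValueError("inconsistent DICOM series: mixed pixel spacings")
    dr, dc = np.asarray(slices[0][1].PixelSpacing, float)
    dz = float(gaps.mean()) if len(gaps) else float(
        getattr(slices[0][1], "SliceThickness", 1.0)
    )
    frames = []
    for _, ds in slices:
        arr = ds.pixel_array.astype(float)
        arr = arr * float(getattr(ds, "RescaleSlope", 1.0)) + float(
            getattr(ds, "RescaleIntercept", 0.0)
        )
        frames.append(arr)
    # voxels[i, j, k]: i along image rows (col direction), j along columns
    # (row direction), k across slices -> reorder to (k? ) keep (row, col,
    # slice) with orientation columns (col_dir? ...)
    stack = np.stack(frames, axis=-1)  # (rows, cols, slices)
    orientation = np.stack([col, row, normal], axis=1)  # rows move along col vector
    spacing = np.array([dr, dc, dz])
    origin = np.asarray(slices[0][1].ImagePositionPatient, float)
    return Volume3D(stack, spacing, origin, orientation, units="hu")


def write_volume(vol: Volume3D, path: str) -> None:
    """Write a Volume3D to NIfTI, preserving geometry in the affine."""
    import nibabel as nib

    img = nib.Nifti1Image(vol.voxels.astype(np.float64), _geometry_to_affine(vol))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# 2D X-rays
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_xray(path: str, frame: str | int = "first") -> XRay2D:
    """Read an X-ray from DICOM or PNG/TIFF (+ JSON intrinsics sidecar).

    ``frame`` selects among multi-frame acquisitions: "first" (e.g. the
    pre-subtraction frame of a DSA run, which retains bony anatomy), an
    integer index, or "min-intensity" (the frame with the lowest mean —
    typically maximal contrast filling).
    """
    p = Path(path)
    if p.suffix.lower() == ".dcm":
        return _read_dicom_xray(p, frame)
    if p.suffix.lower() in (".png", ".tif", ".tiff"):
        side = _sidecar_path(p)
        if not side.exists():
            raise ValueError(
                f"no intrinsics available for {p}: expected sidecar {side.name}"
            )
        doc = json.loads(side.read_text())
        if doc.get("units", "mm") != "mm":
            raise ValueError("sidecar intrinsics must declare mm/pixel units")
        K = Intrinsics.from_dict(doc["intrinsics"])
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(p)), dtype=float)
        if arr.ndim == 3:
            arr = _select_frame(arr, frame) if arr.shape[-1] > 4 else arr[..., 0]
        w = doc.get("window")
        if w is not None:  # undo affine min-max windowing recorded at write time
            arr = arr / doc.get("window_max_code", 65535.0) * (w[1] - w[0]) + w[0]
        meta = {"path": str(p)}
        tp = None
        if doc.get("pose") is not None:
            tp, _ = pose_from_json(json.dumps(doc["pose"]))
        return XRay2D(arr, K, true_pose=tp, meta=meta)
    raise ValueError(f"unsupported X-ray format: {p.suffix}")


def _select_frame(stack: np.ndarray, frame: str | int) -> np.ndarray:
    if isinstance(frame, int):
        return stack[frame] if stack.shape[0] < stack.shape[-1] else stack[..., frame]
    if frame == "first":
        return stack[0] if stack.shape[0] < stack.shape[-1] else stack[..., 0]
    if frame == "min-intensity":
        axis = 0 if stack.shape[0] < stack.shape[-1] else -1
        means = stack.mean(axis=tuple(i for i in range(stack.ndim) if i != (axis % stack.ndim)))
        k = int(np.argmin(means))
        return stack[k] if axis == 0 else stack[..., k]
    raise ValueError(f"unknown frame policy {frame!r}")


def _read_dicom_xray(p: Path, frame: str | int) -> XRay2D:
    import pydicom

    ds = pydicom.dcmread(str(p))
    arr = ds.pixel_array.astype(float)
    if arr.ndim == 3:
        arr = _select_frame(arr, frame)
    try:
        dr, dc = np.asarray(ds.ImagerPixelSpacing, float)
        sdd = float(ds.DistanceSourceToDetector)
    except AttributeError as exc:
        raise ValueError(
            f"missing detector intrinsics in DICOM tags of {p}: {exc}"
        ) from None
    K = Intrinsics(sdd=sdd, height=arr.shape[0], width=arr.shape[1], delx=dc, dely=dr)
    meta = {"path": str(p)}
    for tag in ("DistanceSourceToPatient", "PositionerPrimaryAngle",
                "PositionerSecondaryAngle"):
        if hasattr(ds, tag):
            meta[tag] = float(getattr(ds, tag))
    return XRay2D(arr, K, meta=meta)


def write_xray(x: XRay2D, path: str, fmt: Optional[str] = None) -> None:
    """Write an X-ray as 32-bit float TIFF or windowed 16-bit PNG, with a
    JSON sidecar carrying intrinsics (and the true pose when known)."""
    p = Path(path)
    fmt = fmt or p.suffix.lstrip(".").lower()
    doc = {"units": "mm", "intrinsics": x.intrinsics.to_dict()}
    if x.true_pose is not None:
        sid = float(x.meta.get("nominal_sid", 0.0))
        doc["pose"] = json.loads(pose_to_json(x.true_pose, sid))
    if fmt in ("tif", "tiff"):
        import tifffile

        tifffile.imwrite(str(p), x.pixels.astype(np.float32))
    elif fmt == "png":
        import imageio.v3 as iio

        lo, hi = float(x.pixels.min()), float(x.pixels.max())
        scale = (x.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(x.pixels)
        iio.imwrite(str(p), (scale * 65535).astype(np.uint16))
        doc["window"] = [lo, hi]
        doc["window_max_code"] = 65535.0
    else:
        raise ValueError(f"unsupported X-ray output format {fmt!r}")
    _sidecar_path(p).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# Intrinsics resampling
# ---------------------------------------------------------------------------

def resample_to_intrinsics(x: XRay2D, target: Intrinsics) -> XRay2D:
    """Resample an X-ray onto the detector grid of ``target``.

    Each target pixel's physical detector coordinate is mapped into the
    source image and bilinearly interpolated; regions outside the source
    detector are zero-filled and flagged in ``meta["resample_mask"]``.  The
    source and target SDD must agree — changing the source-to-detector
    distance changes projective geometry, which requires re-rendering, not
    resampling.
    """
    K = x.intrinsics
    if abs(K.sdd - target.sdd) > 1e-6:
        raise ValueError(
            "cannot resample between different source-to-detector distances "
            f"({K.sdd} vs {target.sdd}); re-render at the target geometry instead"
        )
    tu = np.arange(target.width)
    tv = np.arange(target.height)
    x_mm = (tu - (target.width - 1) / 2.0) * target.delx - target.x0
    y_mm = (tv - (target.height - 1) / 2.0) * target.dely - target.y0
    su = (x_mm + K.x0) / K.delx + (K.width - 1) / 2.0
    sv = (y_mm + K.y0) / K.dely + (K.height - 1) / 2.0
    U, V = np.meshgrid(su, sv)
    pix = map_coordinates(x.pixels, [V, U], order=1, mode="constant", cval=0.0)
    inside = (U >= 0) & (U <= K.width - 1) & (V >= 0) & (V <= K.height - 1)
    meta = dict(x.meta)
    meta["resample_mask"] = inside
    return XRay2D(pix, target, true_pose=x.true_pose, meta=meta)


# ---------------------------------------------------------------------------
# DICOM-header pose initialization
# ---------------------------------------------------------------------------

def pose_from_dicom_angles(
    primary_deg: float,
    secondary_deg: float,
    sid_mm: float,
    sdd_mm: float,
    like: Optional[Intrinsics] = None,
) -> Tuple[RigidTransform, Intrinsics]:
    """C-arm pose and intrinsics from DICOM positioner tags.

    Positioner primary angle maps to alpha (LAO/RAO) and secondary to beta
    (CRA/CAU); ``sid_mm`` is the source-to-isocenter distance and ``sdd_mm``
    the source-to-detector distance.  Detector sampling fields are copied
    from ``like`` when given (defaults: 256 x 256 at 1 mm).  Note this
    initialization ignores how the patient lies relative to the C-arm — it
    locates the gantry, not the anatomy — so it is only a coarse starting
    point for refinement.
    """
    pose = pose_from_radiologic(
        RadiologicParams(alpha=primary_deg, beta=secondary_deg), nominal_sid=sid_mm
    )
    if like is not None:
        K = Intrinsics(sdd=sdd_mm, height=like.height, width=like.width,
                       delx=like.delx, dely=like.dely, x0=like.x0, y0=like.y0)
    else:
        K = Intrinsics(sdd=sdd_mm, height=256, width=256, delx=1.0, dely=1.0)
    return pose, K


# ---------------------------------------------------------------------------
# Pose / fiducial JSON files
# ---------------------------------------------------------------------------

def write_pose(T: RigidTransform, nominal_sid: float, path: str) -> None:
    Path(path).write_text(pose_to_json(T, nominal_sid))


def read_pose(path: str) -> Tuple[RigidTransform, float]:
    return pose_from_json(Path(path).read_text())


def write_fiducials(points: np.ndarray, path: str, name: str = "fiducials") -> None:
    doc = {
        "name": name,
        "units": "mm",
        "frame": "volume world (RAS-like, isocenter origin)",
        "points": np.asarray(points, dtype=float).tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_fiducials(path: str) -> np.ndarray:
    doc = json.loads(Path(path).read_text())
    return np.asarray(doc["points"], dtype=float)
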