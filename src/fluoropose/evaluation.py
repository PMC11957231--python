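"""Registration error metrics: mTRE, pose errors, submillimeter success rate
(SMSR), survival curves and normalized AUC.

mTRE (mean Target Registration Error) is the mean 3D distance between
fiducial points mapped by the estimated vs the true pose — the most
stringent of the standard 2D/3D registration error metrics, since it is
sensitive to every component of the pose error.  SMSR is the percentage of
views registered with mTRE strictly below 1 mm; survival curves generalize
it to a sweep of thresholds, with the normalized area under the curve (AUC)
summarizing cumulative success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .geometry import RigidTransform, pose_geodesic

__all__ = ["mtre", "smsr", "survival_auc", "pose_error", "ErrorSummary", "summarize_errors"]


def mtre(est: RigidTransform, true: RigidTransform, fids: np.ndarray) -> float:
    """Mean Target Registration Error (mm) over fiducial points (N, 3) world mm."""
    pts = np.atleast_2d(np.asarray(fids, dtype=float))
    if pts.size == 0:
        raise ValueError("mTRE requires at least one fiducial point")
    d = est.apply(pts) - true.apply(pts)
    return float(np.linalg.norm(d, axis=-1).mean())


def smsr(errors: Sequence[float], threshold: float = 1.0) -> float:
    """Submillimeter success rate: percent of errors strictly below threshold.

    The inequality is strict ("less than 1 mm"); an error exactly at the
    threshold does not count as a success.
    """
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValueError("smsr requires a non-empty error list")
    return float(100.0 * np.count_nonzero(e < threshold) / e.size)


def survival_auc(
    errors: Sequence[float], max_threshold: float = 10.0, n_grid: int = 1000
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Survival curve and its normalized area under the curve.

    ``curve[k]`` is the fraction of errors strictly below ``thresholds[k]``
    on a uniform grid over (0, max_threshold].  The AUC integrates the curve
    by the trapezoidal rule (extending the first grid value flat down to
    threshold 0) and divides by ``max_threshold``, so it lies in [0, 1]:
    all-zero errors give exactly 1.0, errors all above the maximum give 0.0.

    Returns (thresholds, curve, auc).
    """
    if max_threshold <= 0:
        raise ValueError("max_threshold must be positive")
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValueError("survival_auc requires a non-empty error list")
    t = np.linspace(max_threshold / n_grid, max_threshold, n_grid)
    curve = (e[None, :] < t[:, None]).mean(axis=1)
    # uniform grid: trapezoid over (t1..tmax) + flat extension over (0, t1];
    # written so that a constant curve integrates exactly (all-zero errors
    # give auc exactly 1.0)
    area_over_h = 1.5 * curve[0] + curve[1:-1].sum() + 0.5 * curve[-1]
    return t, curve, float(area_over_h / n_grid)


def pose_error(est: RigidTransform, true: RigidTransform) -> Tuple[float, float]:
    """(rotation degrees, translation mm) geodesic pose error."""
    return pose_geodesic(est, true)


@dataclass(frozen=True)
class ErrorSummary:
    """Per-view mTRE values with the derived summary statistics."""

    errors: np.ndarray
    median: float
    iqr: Tuple[float, float]
    mean: float
    smsr: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "n": int(self.errors.size),
            "median_mm": self.median,
            "iqr_mm": list(self.iqr),
            "mean_mm": self.mean,
            "smsr_percent": self.smsr,
            "survival_auc": self.auc,
        }


def summarize_errors(
    errors: Sequence[float],
    smsr_threshold: float = 1.0,
    max_threshold: float = 10.0,
    n_grid: int = 1000,
) -> ErrorSummary:
    """Median/IQR/mean, SMSR and survival AUC of a set of per-view mTREs."""
    e = np.asarray(list(errors), dtype=float)
    q1, med, q3 = np.percentile(e, [25, 50, 75])
    _, _, auc = survival_auc(e, max_threshold=max_threshold, n_grid=n_grid)
    return ErrorSummary(
        errors=e,
        median=float(med),
        iqr=(float(q1), float(q3)),
        mean=float(e.mean()),
        smsr=smsr(e, smsr_threshold),
        auc=auc,
    )
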