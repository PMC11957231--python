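"""Patient-specific pose-regression training simulation.

A convolutional-free (fully connected) regression network is trained
entirely on synthetic X-rays rendered on the fly from the patient's own
volume: sample a C-arm pose uniformly from clinician-specified radiologic
parameter ranges, render the DRR, push it through an appearance-augmentation
pipeline emulating the synthetic-to-real domain gap, and regress the pose.
No manual annotation enters anywhere — the ground-truth pose of every
training image is known by construction (self-supervision).

Three training modes share one code path: ``de_novo`` (random init, one
volume), ``patient_agnostic`` (random init, a corpus of mutually
preregistered volumes), and ``finetuned`` (initialized from a pretrained
patient-agnostic model, one volume).  The network regresses the six
radiologic parameters normalized to their sampling intervals; because the
sampling ranges exclude the |beta| = 90 deg chart singularity, this chart is
smooth over the entire training domain.  Training minimizes the mean squared
error in this normalized chart (a smooth surrogate whose zero set is exactly
pose equality); held-out error is reported with the weighted
geodesic-plus-translation pose loss.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    Intrinsics,
    RadiologicParams,
    RigidTransform,
    pose_from_radiologic,
    pose_geodesic,
)
from .rendering import Volume3D, XRay2D, render

__all__ = [
    "SamplingRanges",
    "AugmentConfig",
    "TrainConfig",
    "PoseRegressor",
    "IntrinsicsMismatchError",
    "sample_pose",
    "augment_xray",
    "pose_loss",
    "train_regressor",
    "predict_pose",
    "correct_pose_to_patient",
    "center_align",
]

_PARAM_NAMES = ("alpha", "beta", "gamma", "bx", "by", "bz")


class IntrinsicsMismatchError(ValueError):
    """Input X-ray intrinsics differ from the model's training intrinsics."""


@dataclass(frozen=True)
class SamplingRanges:
    """Closed per-parameter intervals for uniform C-arm pose sampling.

    Angles in degrees, translations in mm.  Defaults cover +/-45 deg oblique
    and craniocaudal angulation, a modest +/-15 deg detector roll, +/-50 mm
    in-plane translations and +/-100 mm of source-to-isocenter (depth)
    variation — a generic surgical working envelope, overridable per
    procedure.
    """

    alpha: Tuple[float, float] = (-45.0, 45.0)
    beta: Tuple[float, float] = (-45.0, 45.0)
    gamma: Tuple[float, float] = (-15.0, 15.0)
    bx: Tuple[float, float] = (-50.0, 50.0)
    by: Tuple[float, float] = (-100.0, 100.0)
    bz: Tuple[float, float] = (-50.0, 50.0)

    def __post_init__(self):
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range for {name} has min > max")

    def bounds(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES], dtype=float)

    def center(self) -> np.ndarray:
        b = self.bounds()
        return (b[:, 0] + b[:, 1]) / 2.0

    def halfwidth(self, floor: float = 1e-6) -> np.ndarray:
        b = self.bounds()
        return np.maximum((b[:, 1] - b[:, 0]) / 2.0, floor)

    def normalize(self, params: np.ndarray) -> np.ndarray:
        return (params - self.center()) / self.halfwidth()

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return z * self.halfwidth() + self.center()

    def to_dict(self) -> dict:
        return {n: list(getattr(self, n)) for n in _PARAM_NAMES}

    @staticmethod
    def from_dict(d: dict) -> "SamplingRanges":
        return SamplingRanges(**{n: tuple(d[n]) for n in _PARAM_NAMES})


def sample_pose(ranges: SamplingRanges, rng: np.random.Generator) -> RadiologicParams:
    """Draw each radiologic parameter independently and uniformly."""
    b = ranges.bounds()
    draw = rng.uniform(b[:, 0], b[:, 1])
    return RadiologicParams.from_array(draw)


# ---------------------------------------------------------------------------
# Appearance augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Appearance augmentation emulating the synthetic-to-real domain gap.

    All magnitudes >= 0; the all-zero config is an exact no-op.  Noise sigma
    and dropout/occlusion areas are fractions (of the dynamic range and of
    the image area respectively); gamma jitter raises min-max normalized
    intensities to a random power.  Defaults follow the package's standard
    training recipe: mild noise, gamma and gain jitter, random intensity
    inversion (film vs fluoro polarity), and one rectangular occlusion
    emulating collimation or instruments.
    """

    blur_sigma: float = 0.0
    noise_sigma: float = 0.02
    gain: float = 0.1
    gamma_range: Tuple[float, float] = (0.7, 1.4)
    invert_p: float = 0.5
    occlusion_frac: float = 0.1
    dropout_frac: float = 0.0
    dropout_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.blur_sigma, self.noise_sigma, self.gain, self.invert_p,
               self.occlusion_frac, self.dropout_frac) < 0:
            raise ValueError("augmentation magnitudes must be >= 0")
        if self.gamma_range[0] <= 0:
            raise ValueError("gamma exponents must be positive")

    @staticmethod
    def identity() -> "AugmentConfig":
        return AugmentConfig(noise_sigma=0.0, gain=0.0, gamma_range=(1.0, 1.0),
                             invert_p=0.0, occlusion_frac=0.0)


def _occlusion_shape(n_pix: int, H: int, W: int, rng: np.random.Generator):
    """Pick (h, w) with h*w == n_pix when a divisor pair fits the image."""
    divs = [d for d in range(1, int(np.sqrt(n_pix)) + 1) if n_pix % d == 0]
    pairs = []
    for d in divs:
        for h, w in ((d, n_pix // d), (n_pix // d, d)):
            if h <= H and w <= W:
                pairs.append((h, w))
    if pairs:
        return pairs[rng.integers(len(pairs))]
    h = min(H, max(1, int(round(np.sqrt(n_pix)))))
    return h, min(W, max(1, n_pix // h))


def augment_xray(
    img: XRay2D, cfg: AugmentConfig, rng: Optional[np.random.Generator] = None
) -> XRay2D:
    """Randomly perturb image appearance; intrinsics and pose are untouched."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = img.pixels.copy()
    lo, hi = float(p.min()), float(p.max())
    dyn = hi - lo

    if cfg.blur_sigma > 0:
        p = gaussian_filter(p, cfg.blur_sigma)
    if cfg.gamma_range != (1.0, 1.0) and dyn > 0:
        g = rng.uniform(*cfg.gamma_range)
        p = ((p - lo) / dyn) ** g * dyn + lo
    if cfg.gain > 0:
        p = p * rng.uniform(1.0 - cfg.gain, 1.0 + cfg.gain)
    if cfg.noise_sigma > 0 and dyn > 0:
        p = p + rng.normal(0.0, cfg.noise_sigma * dyn, size=p.shape)
    if cfg.invert_p > 0 and rng.uniform() < cfg.invert_p:
        p = p.max() + p.min() - p
    if cfg.occlusion_frac > 0:
        H, W = p.shape
        n_pix = max(1, int(round(cfg.occlusion_frac * H * W)))
        h, w = _occlusion_shape(n_pix, H, W, rng)
        r0 = rng.integers(0, H - h + 1)
        c0 = rng.integers(0, W - w + 1)
        p[r0 : r0 + h, c0 : c0 + w] = float(p.min())
    if cfg.dropout_frac > 0:
        H, W = p.shape
        s = max(1, int(cfg.dropout_size))
        n_cells = max(1, int(round(cfg.dropout_frac * H * W / (s * s))))
        for _ in range(n_cells):
            r0 = rng.integers(0, max(1, H - s + 1))
            c0 = rng.integers(0, max(1, W - s + 1))
            p[r0 : r0 + s, c0 : c0 + s] = float(p.min())
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("augmentation produced non-finite pixels")
    return XRay2D(p, img.intrinsics, true_pose=img.true_pose, meta=dict(img.meta))


def pose_loss(
    pred: RigidTransform,
    true: RigidTransform,
    w_rot: float = 1.0,
    w_trans: float = 1.0,
) -> float:
    """Weighted pose discrepancy: w_rot * geodesic rotation angle (radians)
    + w_trans * translation distance (mm).  Zero iff the poses are equal."""
    rot_deg, trans_mm = pose_geodesic(pred, true)
    return float(w_rot * np.deg2rad(rot_deg) + w_trans * trans_mm)


# ---------------------------------------------------------------------------
# The network: a small fully connected regressor with manual backprop + Adam
# ---------------------------------------------------------------------------

class _MLP:
    """Plain NumPy MLP (ReLU hidden layers, linear output), Adam optimizer."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W = []
        self.b = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / n_in)
            self.W.append(rng.normal(0.0, scale, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    def forward(self, x: np.ndarray, cache: Optional[list] = None) -> np.ndarray:
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            if cache is not None:
                cache.append(h)
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
        return h

    def backward_and_step(self, cache: list, x: np.ndarray, dout: np.ndarray, lr: float):
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        d = dout
        for i in reversed(range(len(self.W))):
            a_in = cache[i]
            if i < len(self.W) - 1:
                # recompute the ReLU mask from the forward pre-activation
                pre = a_in @ self.W[i] + self.b[i]
                d = d * (pre > 0)
            else:
                pre = None
            grads_W[i] = a_in.T @ d
            grads_b[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = grads_W + grads_b
        for j, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[j] = 0.9 * self._adam_m[j] + 0.1 * g
            self._adam_v[j] = 0.999 * self._adam_v[j] + 0.001 * g * g
            mh = self._adam_m[j] / (1 - 0.9**t)
            vh = self._adam_v[j] / (1 - 0.999**t)
            p -= lr * mh / (np.sqrt(vh) + 1e-8)

    def state(self) -> dict:
        return {f"W{i}": w for i, w in enumerate(self.W)} | {
            f"b{i}": b for i, b in enumerate(self.b)
        }

    @staticmethod
    def from_state(state: dict) -> "_MLP":
        n = len([k for k in state if k.startswith("W")])
        mlp = _MLP.__new__(_MLP)
        mlp.W = [np.array(state[f"W{i}"], dtype=float) for i in range(n)]
        mlp.b = [np.array(state[f"b{i}"], dtype=float) for i in range(n)]
        mlp._adam_m = [np.zeros_like(w) for w in mlp.W + mlp.b]
        mlp._adam_v = [np.zeros_like(w) for w in mlp.W + mlp.b]
        mlp._adam_t = 0
        return mlp

    def copy(self) -> "_MLP":
        return _MLP.from_state({k: v.copy() for k, v in self.state().items()})


def _prep_images(imgs: np.ndarray) -> np.ndarray:
    """Per-sample min-max normalization to [0, 1], flattened (detector gain
    invariance; constant images map to zero)."""
    flat = imgs.reshape(imgs.shape[0], -1)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    rng_ = np.where(hi - lo > 0, hi - lo, 1.0)
    return (flat - lo) / rng_


@dataclass
class TrainConfig:
    """Training budget and optimization hyperparameters.

    The budget is ``iterations`` (deterministic) or ``time_budget_s``
    (wall-clock), whichever is hit first; set ``time_budget_s=None`` for
    fully deterministic runs.
    """

    iterations: int = 2000
    time_budget_s: Optional[float] = None
    batch_size: int = 16
    lr: float = 1e-3
    lr_final: float = 0.1
    w_rot: float = 1.0
    w_trans: float = 0.01
    hidden: Tuple[int, ...] = (256, 128)
    n_points: Optional[int] = None
    eval_every: int = 50
    n_eval: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iteration budget must be >= 0")
        if self.time_budget_s is not None and self.time_budget_s <= 0:
            raise ValueError("time budget must be positive")
        if self.batch_size < 1 or self.lr <= 0:
            raise ValueError("batch size must be >= 1 and lr > 0")
        if self.w_rot <= 0 or self.w_trans <= 0:
            raise ValueError("loss weights must be positive")


@dataclass
class PoseRegressor:
    """Trained pose-regression network + the fingerprint of its training
    conditions (intrinsics, sampling ranges, normalization, nominal SID).

    The fingerprint is checked at prediction time: an X-ray must be resampled
    to the training intrinsics before the network sees it.
    """

    net: _MLP
    intrinsics: Intrinsics
    ranges: SamplingRanges
    nominal_sid: float
    mode: str = "de_novo"
    normalization: str = "minmax01"
    seed: int = 0
    log: List[dict] = field(default_factory=list)

    def fingerprint(self) -> dict:
        return {
            "intrinsics": self.intrinsics.to_dict(),
            "ranges": self.ranges.to_dict(),
            "nominal_sid": float(self.nominal_sid),
            "normalization": self.normalization,
            "mode": self.mode,
            "seed": int(self.seed),
        }

    def save(self, path: str) -> None:
        """Checkpoint = weights (.npz) + JSON fingerprint in one file."""
        np.savez(
            path,
            fingerprint=np.frombuffer(
                json.dumps(self.fingerprint()).encode(), dtype=np.uint8
            ),
            log=np.frombuffer(json.dumps(self.log).encode(), dtype=np.uint8),
            **self.net.state(),
        )

    @staticmethod
    def load(path: str) -> "PoseRegressor":
        with np.load(path) as z:
            fp = json.loads(bytes(z["fingerprint"].tobytes()).decode())
            log = json.loads(bytes(z["log"].tobytes()).decode())
            net = _MLP.from_state({k: z[k] for k in z.files if k[0] in "Wb"})
        return PoseRegressor(
            net=net,
            intrinsics=Intrinsics.from_dict(fp["intrinsics"]),
            ranges=SamplingRanges.from_dict(fp["ranges"]),
            nominal_sid=fp["nominal_sid"],
            mode=fp["mode"],
            normalization=fp["normalization"],
            seed=fp["seed"],
            log=log,
        )


def _check_intrinsics_match(model_k: Intrinsics, k: Intrinsics) -> None:
    a, b = model_k.to_dict(), k.to_dict()
    for key in a:
        if abs(float(a[key]) - float(b[key])) > 1e-6:
            raise IntrinsicsMismatchError(
                f"X-ray intrinsics ({key}={b[key]}) differ from the model's "
                f"training intrinsics ({key}={a[key]}); resample the image with "
                "interface.resample_to_intrinsics before prediction"
            )


def _render_batch(vols, K, poses_params, nominal_sid, n_points, rng, aug_cfg, vol_idx):
    imgs = np.empty((len(poses_params), K.height, K.width))
    for i, p in enumerate(poses_params):
        T = pose_from_radiologic(p, nominal_sid)
        x = render(vols[vol_idx[i]], T, K, method="trilinear", n_points=n_points)
        if aug_cfg is not None:
            x = augment_xray(x, aug_cfg, rng)
        imgs[i] = x.pixels
    return imgs


def train_regressor(
    vol: Union[Volume3D, Sequence[Volume3D]],
    K: Intrinsics,
    ranges: SamplingRanges,
    train_cfg: Optional[TrainConfig] = None,
    aug_cfg: Optional[AugmentConfig] = None,
    init: Optional[PoseRegressor] = None,
    nominal_sid: float = 700.0,
) -> PoseRegressor:
    """Train (or finetune) a pose regressor on freshly rendered synthetic
    X-rays — there is no fixed dataset; every batch is sampled, rendered and
    augmented on the fly.

    ``vol`` may be a single patient volume (de novo / finetuning) or a
    sequence of mutually preregistered volumes (patient-agnostic
    pretraining).  With ``init`` given, its weights are the starting point
    and its training intrinsics must match ``K``.  A zero-iteration budget
    with ``init`` returns ``init`` unchanged.
    """
    cfg = train_cfg or TrainConfig()
    vols = [vol] if isinstance(vol, Volume3D) else list(vol)
    if len(vols) == 0:
        raise ValueError("need at least one volume")
    for v in vols:
        if v.units == "hu":
            raise ValueError("convert HU volumes with hu_to_mu before training")

    if init is not None:
        _check_intrinsics_match(init.intrinsics, K)
        if cfg.iterations == 0:
            return init
        net = init.net.copy()
        mode = "finetuned"
    else:
        if cfg.iterations == 0:
            raise ValueError("zero-iteration budget without an initial model")
        rng_init = np.random.default_rng(cfg.seed)
        net = _MLP([K.height * K.width, *cfg.hidden, 6], rng_init)
        mode = "patient_agnostic" if len(vols) > 1 else "de_novo"

    rng = np.random.default_rng(cfg.seed + 1)
    model = PoseRegressor(net, K, ranges, nominal_sid, mode=mode, seed=cfg.seed)

    # fixed held-out evaluation set (never augmented)
    rng_eval = np.random.default_rng(cfg.seed + 2)
    eval_params = [sample_pose(ranges, rng_eval) for _ in range(cfg.n_eval)]
    eval_vidx = rng_eval.integers(len(vols), size=cfg.n_eval)
    eval_imgs = _render_batch(
        vols, K, eval_params, nominal_sid, cfg.n_points, rng_eval, None, eval_vidx
    )
    eval_x = _prep_images(eval_imgs)
    eval_poses = [pose_from_radiologic(p, nominal_sid) for p in eval_params]

    def heldout_error() -> float:
        z = net.forward(eval_x)
        losses = [
            pose_loss(
                pose_from_radiologic(
                    RadiologicParams.from_array(ranges.denormalize(zi)), nominal_sid
                ),
                Tp, cfg.w_rot, cfg.w_trans,
            )
            for zi, Tp in zip(z, eval_poses)
        ]
        return float(np.median(losses))

    model.log.append({"iteration": 0, "train_mse": None,
                      "heldout_pose_loss": heldout_error()})

    t_start = time.time()
    it = 0
    while it < cfg.iterations:
        if cfg.time_budget_s is not None and time.time() - t_start > cfg.time_budget_s:
            if it == 0:
                raise ValueError(
                    "training budget exhausted before a single batch completed"
                )
            break
        params = [sample_pose(ranges, rng) for _ in range(cfg.batch_size)]
        vidx = rng.integers(len(vols), size=cfg.batch_size)
        imgs = _render_batch(vols, K, params, nominal_sid, cfg.n_points, rng, aug_cfg, vidx)
        x = _prep_images(imgs)
        target = np.stack([ranges.normalize(p.as_array()) for p in params])
        cache: list = []
        z = net.forward(x, cache)
        resid = z - target
        loss = float((resid**2).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}; last lr={cfg.lr}, "
                f"batch residual range=({np.nanmin(resid)}, {np.nanmax(resid)})"
            )
        # cosine-annealed learning rate for end-of-training precision
        lr = cfg.lr * (
            cfg.lr_final
            + (1 - cfg.lr_final) * 0.5 * (1 + np.cos(np.pi * it / max(1, cfg.iterations)))
        )
        net.backward_and_step(cache, x, 2.0 * resid / resid.size, lr)
        it += 1
        if it % cfg.eval_every == 0 or it == cfg.iterations:
            model.log.append(
                {"iteration": it, "train_mse": loss, "heldout_pose_loss": heldout_error()}
            )
    return model


def predict_pose(model: PoseRegressor, x: XRay2D) -> RigidTransform:
    """Regress the world->camera pose of an X-ray (deterministic).

    The image must already be sampled on the model's training intrinsics;
    a mismatch raises :class:`IntrinsicsMismatchError` rather than silently
    predicting from misscaled pixels.
    """
    _check_intrinsics_match(model.intrinsics, x.intrinsics)
    z = model.net.forward(_prep_images(x.pixels[None]))[0]
    params = RadiologicParams.from_array(model.ranges.denormalize(z))
    return pose_from_radiologic(params, model.nominal_sid)


def center_align(template: Volume3D, patient: Volume3D) -> RigidTransform:
    """Pure translation mapping template world coords to patient world
    coords by aligning the two volume centers (anatomy-agnostic)."""
    d = patient.isocenter() - template.isocenter()
    return RigidTransform(np.eye(3), d)


def correct_pose_to_patient(
    pred: RigidTransform, template_to_patient: RigidTransform
) -> RigidTransform:
    """Re-express a pose predicted in the pretraining template frame in the
    patient's volume frame.

    With ``A`` mapping template coords to patient coords, the corrected
    world->camera map is ``pred o A^-1``, so rendering the patient volume at
    the corrected pose reproduces the template rendering.  The identity
    transform leaves the pose unchanged.
    """
    return pred @ template_to_patient.inverse()
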