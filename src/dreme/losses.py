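"""Training objectives and the motion/angle augmentation sampler.

Every loss has a differentiable core operating on autodiff tensors (used by
the trainer) and a thin numpy-facing wrapper returning a float (used for
evaluation and testing).  The wrappers run the same code path in float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .geometry import VolumeGrid
from .motion import (DVF, MotionBasisSet, evaluate_basis_t, invert_dvf,
                     warp_volume)

AUGMENTATION_MODES = ("off", "angle_only", "motion_and_angle")


@dataclass
class LossWeights:
    """Per-term weighting factors of the total training objective."""

    image_sim: float = 1.0
    projection_sim: float = 1.0
    tv: float = 2e-4
    mbc: float = 1.0
    zero_mean: float = 1e-3
    self_consistency: float = 1e3
    augmentation: float = 1e-4

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be non-negative")

    def ablate(self, *names: str) -> "LossWeights":
        """Zero selected weights (ablation variants of the framework)."""
        kw = {k: (0.0 if k in names else v) for k, v in vars(self).items()}
        unknown = set(names) - set(vars(self))
        if unknown:
            raise ValueError(f"unknown loss terms: {sorted(unknown)}")
        return LossWeights(**kw)


@dataclass
class AugmentationConfig:
    """Score resampling ranges for deformable augmentation.

    r1 is drawn once per projection instance (overall scale), r2 once per
    (level, direction) channel, both uniform.
    """

    r1_range: tuple[float, float] = (0.6, 2.0)
    r2_range: tuple[float, float] = (0.8, 1.2)
    mode: str = "motion_and_angle"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in AUGMENTATION_MODES:
            raise ValueError(f"mode must be one of {AUGMENTATION_MODES}")


# ---------------------------------------------------------------------------
# differentiable cores
# ---------------------------------------------------------------------------

def image_similarity_t(rendered: Tensor, label: Tensor) -> Tensor:
    """Voxelwise mean squared error."""
    if rendered.shape != label.shape:
        raise ValueError("volume shapes do not match")
    return ((rendered - label) ** 2).mean()


def projection_similarity_t(drrs: Tensor, measured: Tensor) -> Tensor:
    """Pixelwise MSE over a batch of DRR/measured frame pairs."""
    if drrs.shape != measured.shape:
        raise ValueError("projection batch shapes do not match")
    return ((drrs - measured) ** 2).mean()


def tv_t(volume: Tensor) -> Tensor:
    """Isotropic total variation: mean gradient magnitude, forward diffs."""
    v = volume.data
    if v.ndim != 3:
        raise ValueError("TV loss expects a 3D volume")
    dx = np.diff(v, axis=0, append=v[-1:, :, :])
    dy = np.diff(v, axis=1, append=v[:, -1:, :])
    dz = np.diff(v, axis=2, append=v[:, :, -1:])
    mag = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    out = mag.mean()

    def back(g):
        inv = np.zeros_like(mag)
        nz = mag > 0
        inv[nz] = 1.0 / mag[nz]
        scale = g / v.size
        gx = scale * dx * inv
        gy = scale * dy * inv
        gz = scale * dz * inv
        gv = np.zeros_like(v)
        gv[:-1] -= gx[:-1]
        gv[1:] += gx[:-1]
        gv[:, :-1] -= gy[:, :-1]
        gv[:, 1:] += gy[:, :-1]
        gv[:, :, :-1] -= gz[:, :, :-1]
        gv[:, :, 1:] += gz[:, :, :-1]
        return (gv,)

    return ad.custom(np.asarray(out), [volume], back)


def mbc_orthonormality_t(fields: Tensor) -> Tensor:
    """Ortho-normality penalty on the dense MBC fields (3 levels, 3 dirs, ...).

    Inner products are voxel means, which keeps the penalty independent of
    the evaluation grid size and the scores on the mm scale.
    """
    n_vox = int(np.prod(fields.shape[2:]))
    total = None
    for k in range(3):
        ek = fields[:, k].reshape(3, n_vox)
        G = (ek @ ek.transpose()) * (1.0 / n_vox)
        term = (G[0, 0] - 1.0) ** 2 + (G[1, 1] - 1.0) ** 2 + (G[2, 2] - 1.0) ** 2 \
            + G[0, 1] ** 2 + G[0, 2] ** 2 + G[1, 2] ** 2
        total = term if total is None else total + term
    return total * (1.0 / 9.0)


def zero_mean_t(scores: Tensor) -> Tensor:
    """Squared per-channel batch mean of the scores, averaged over channels."""
    if scores.ndim == 2:
        scores = scores.reshape(scores.shape[0], 3, 3)
    return (scores.mean(axis=0) ** 2).mean()


def augmentation_loss_t(predicted: Tensor, target: Tensor) -> Tensor:
    """MSE between re-inferred and augmented target scores."""
    if predicted.shape != target.shape:
        raise ValueError("score shapes do not match")
    return ((predicted - target) ** 2).mean()


# ---------------------------------------------------------------------------
# public numpy-facing losses
# ---------------------------------------------------------------------------

def _vol_data(v) -> np.ndarray:
    return v.data if isinstance(v, VolumeGrid) else np.asarray(v)


def loss_image_similarity(rendered, label) -> float:
    a = _vol_data(rendered).astype(np.float64)
    b = _vol_data(label).astype(np.float64)
    with ad.no_grad():
        return float(image_similarity_t(Tensor(a), Tensor(b)).item())


def loss_projection_similarity(drrs: np.ndarray, measured: np.ndarray) -> float:
    a = np.asarray(drrs, dtype=np.float64)
    b = np.asarray(measured, dtype=np.float64)
    with ad.no_grad():
        return float(projection_similarity_t(Tensor(a), Tensor(b)).item())


def loss_tv(volume) -> float:
    with ad.no_grad():
        return float(tv_t(Tensor(_vol_data(volume).astype(np.float64))).item())


def loss_mbc_orthonormality(basis: MotionBasisSet, grid: VolumeGrid) -> float:
    with ad.no_grad():
        fields = evaluate_basis_t(basis, grid)
        return float(mbc_orthonormality_t(
            Tensor(fields.numpy().astype(np.float64))).item())


def loss_mbc_orthonormality_fields(fields: np.ndarray) -> float:
    """Same penalty, on already-evaluated dense fields (3,3,nx,ny,nz)."""
    with ad.no_grad():
        return float(mbc_orthonormality_t(
            Tensor(np.asarray(fields, dtype=np.float64))).item())


def loss_zero_mean(scores: np.ndarray) -> float:
    """`scores`: (Nbatch, 9) or (Nbatch, 3, 3) MBC scores of a batch."""
    with ad.no_grad():
        return float(zero_mean_t(
            Tensor(np.asarray(scores, dtype=np.float64))).item())


def loss_self_consistency(ref: VolumeGrid, dvf: DVF,
                          iterations: int = 3) -> float:
    """Round-trip error: warp by d, warp back by the iterative inverse.

    Voxels whose round-trip sampling left the field of view are excluded
    (border clamping there is not a motion error).
    """
    warped = warp_volume(ref, dvf)
    dinv = invert_dvf(dvf, iterations)
    back = warp_volume(warped, dinv)
    mask = self_consistency_mask(dvf, dinv)
    a = back.data.astype(np.float64)[mask]
    b = ref.data.astype(np.float64)[mask]
    return float(np.mean((a - b) ** 2))


def self_consistency_mask(dvf: DVF, dinv: DVF) -> np.ndarray:
    """True where both sampling steps of the round trip stay inside the FOV."""
    shape = dvf.shape
    grid = VolumeGrid(np.empty(shape, dtype=np.uint8), dvf.spacing, dvf.origin)
    base = grid.voxel_centers().reshape(shape + (3,))
    lo = np.asarray(dvf.origin)
    hi = lo + (np.asarray(shape) - 1) * np.asarray(dvf.spacing)
    y = base + dinv.displacement
    ok1 = np.all((y >= lo) & (y <= hi), axis=-1)
    from .motion import _sample_dvf
    d_at_y = _sample_dvf(dvf.displacement.astype(np.float64),
                         ((y - lo) / np.asarray(dvf.spacing)).reshape(-1, 3))
    z = y + d_at_y.reshape(shape + (3,))
    ok2 = np.all((z >= lo) & (z <= hi), axis=-1)
    return ok1 & ok2


# ---------------------------------------------------------------------------
# augmentation sampler
# ---------------------------------------------------------------------------

def augment_scores(scores: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Randomly rescale solved scores: w' = r1(instance) * r2(i,k) * w.

    `scores`: (N, 3, 3) or (3, 3); returns the same shape.
    """
    w = np.asarray(scores, dtype=np.float64)
    single = w.ndim == 2
    if single:
        w = w[None]
    n = w.shape[0]
    r1 = rng.uniform(*cfg.r1_range, size=(n, 1, 1))
    r2 = rng.uniform(*cfg.r2_range, size=(n, 3, 3))
    out = r1 * r2 * w
    return out[0] if single else out


def loss_augmentation(predicted: np.ndarray, target: np.ndarray) -> float:
    with ad.no_grad():
        return float(augmentation_loss_t(
            Tensor(np.asarray(predicted, dtype=np.float64)),
            Tensor(np.asarray(target, dtype=np.float64))).item())
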