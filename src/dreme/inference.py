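"""Real-time single-projection inference and contour propagation."""

from __future__ import annotations

import time

import numpy as np

from .geometry import VolumeGrid
from .model import DremeModel
from .motion import DVF, MBCScores, compose_dvf, warp_volume


def infer_realtime(model: DremeModel, frame: np.ndarray,
                   render: bool = True):
    """Scores, DVF and (optionally) the volumetric image from one projection.

    `frame` is a raw post-log projection at any gantry angle; preprocessing
    (resize + intensity scaling) uses the constants frozen at training time.
    Returns (MBCScores, DVF, VolumeGrid or None).  Pure function of
    (model, frame); wall time is recorded on `model.last_inference_s`.
    """
    if not getattr(model, "finalized", False):
        raise RuntimeError("model is not trained/finalized")
    t0 = time.perf_counter()
    pre = model.preprocess(np.asarray(frame))
    scores = MBCScores(model.cnn.encode(pre[None])[0].reshape(3, 3))
    fields = model.basis_fields()
    dvf = compose_dvf(scores, model.basis, model.grid_hi, fields=fields)
    volume = None
    if render:
        volume = warp_volume(model.reference_volume(), dvf)
    model.last_inference_s = time.perf_counter() - t0
    return scores, dvf, volume


def infer_scores(model: DremeModel, frames: np.ndarray) -> np.ndarray:
    """Batch scores for a stack of frames, order-preserving: (N, 3, 3)."""
    if not getattr(model, "finalized", False):
        raise RuntimeError("model is not trained/finalized")
    pre = np.stack([model.preprocess(f) for f in np.asarray(frames)])
    return model.cnn.encode(pre).reshape(-1, 3, 3)


def propagate_contour(mask: VolumeGrid, dvf: DVF) -> VolumeGrid:
    """Pull-back nearest-neighbour warp of a binary mask (stays binary)."""
    if mask.shape != dvf.shape or \
            not np.allclose(mask.spacing, dvf.spacing) or \
            not np.allclose(mask.origin, dvf.origin):
        raise ValueError("mask and DVF grids do not match")
    sp = np.asarray(mask.spacing)
    shape = np.asarray(mask.shape)
    grid = VolumeGrid(np.empty(mask.shape, dtype=np.uint8),
                      mask.spacing, mask.origin)
    base = grid.voxel_centers().reshape(mask.shape + (3,))
    coords = (base + dvf.displacement - np.asarray(mask.origin)) / sp
    idx = np.rint(coords).astype(np.int64)
    np.clip(idx, 0, shape - 1, out=idx)
    out = (mask.data > 0)[idx[..., 0], idx[..., 1], idx[..., 2]]
    return mask.like(out.astype(np.uint8))
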