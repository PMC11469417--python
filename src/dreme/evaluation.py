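"""Quantitative evaluation: image metrics, tumor-tracking metrics, the
Amsterdam-Shroud breathing trace, and the cross-scenario study harness."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity

from .geometry import ProjectionSet, VolumeGrid
from .phantom import (TRAJECTORY_KINDS, PhantomSpec, build_phantom,
                      make_trajectory, simulate_scan)

log = logging.getLogger(__name__)


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, VolumeGrid) else np.asarray(x)


def _frames(x) -> np.ndarray:
    """Coerce a volume / list of volumes / 4D stack to (Nf, ...) float64."""
    if isinstance(x, VolumeGrid):
        return _data(x).astype(np.float64)[None]
    if isinstance(x, (list, tuple)):
        return np.stack([_data(v) for v in x]).astype(np.float64)
    x = np.asarray(x, dtype=np.float64)
    return x[None] if x.ndim == 3 else x


def relative_error(est, truth) -> float:
    """Mean over frames of ||est - truth||_2 / ||truth||_2 (voxelwise)."""
    a, b = _frames(est), _frames(truth)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    num = np.sqrt(((a - b) ** 2).reshape(a.shape[0], -1).sum(axis=1))
    den = np.sqrt((b ** 2).reshape(b.shape[0], -1).sum(axis=1))
    return float(np.mean(num / den))


def ssim_volume(est, truth) -> float:
    """Volumetric SSIM, Gaussian window, data range = truth max - min."""
    a, b = _data(est).astype(np.float64), _data(truth).astype(np.float64)
    dr = b.max() - b.min()
    if dr <= 0:
        raise ValueError("truth volume has zero dynamic range")
    return float(structural_similarity(b, a, data_range=dr,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False))


def come(est_mask, truth_mask, spacing) -> float:
    """Tumor center-of-mass error in mm; NaN sentinel for an empty estimate."""
    a, b = _data(est_mask) > 0, _data(truth_mask) > 0
    sp = np.asarray(spacing, dtype=np.float64)
    if not a.any():
        log.warning("COME: empty estimated mask, returning NaN sentinel")
        return float("nan")
    if not b.any():
        raise ValueError("truth mask is empty")
    ca = np.argwhere(a).mean(axis=0) * sp
    cb = np.argwhere(b).mean(axis=0) * sp
    return float(np.linalg.norm(ca - cb))


def dsc(est_mask, truth_mask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    a, b = _data(est_mask) > 0, _data(truth_mask) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def pearson(trace_a, trace_b) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("trace length mismatch")
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if den == 0:
        raise ValueError("constant trace has undefined correlation")
    return float((a * b).sum() / den)


# ---------------------------------------------------------------------------
# Amsterdam-Shroud breathing trace
# ---------------------------------------------------------------------------

def amsterdam_shroud(projections: ProjectionSet, roi=None):
    """Extract a per-frame SI breathing trace from a projection set.

    Per frame, the intensity gradient along the detector v axis (the SI
    direction) is integrated along u over the ROI to form one column of the
    AS image.  Columns are z-normalized for contrast and the dominant edge
    position is located with a parabolic sub-pixel peak fit.

    roi: (u_lo, u_hi, v_lo, v_hi) pixel bounds; defaults to the full frame.

    Returns (trace_mm, as_image) with trace in detector millimetres.
    """
    frames = projections.frames
    np_, nv, nu = frames.shape
    if roi is None:
        roi = (0, nu, 0, nv)
    u0, u1, v0, v1 = roi
    grad = np.gradient(frames[:, v0:v1, u0:u1].astype(np.float64), axis=1)
    as_image = grad.sum(axis=2).T                      # (nv_roi, Np)
    std = as_image.std(axis=0, keepdims=True)
    std[std == 0] = 1.0
    enhanced = (as_image - as_image.mean(axis=0, keepdims=True)) / std

    mean_prof = np.abs(enhanced).mean(axis=1)
    jref = int(np.argmax(mean_prof))                   # dominant edge row
    half = max(3, (v1 - v0) // 6)
    lo = max(1, jref - half)
    hi = min(enhanced.shape[0] - 1, jref + half)

    dv = projections.geometry.dv
    trace = np.empty(np_)
    for i in range(np_):
        col = np.abs(enhanced[:, i])
        j = lo + int(np.argmax(col[lo:hi]))
        y0, y1, y2 = col[j - 1], col[j], col[j + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        trace[i] = (v0 + j + delta) * dv
    return trace, as_image


def trace_localization_error(trace_a, trace_b) -> float:
    """Mean absolute difference between two traces (detector mm)."""
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# tumor segmentation from a solved reference volume
# ---------------------------------------------------------------------------

def segment_tumor(volume: VolumeGrid, spec: PhantomSpec) -> VolumeGrid:
    """Threshold-and-label segmentation of the tumor in a solved reference.

    The tumor is the only soft-tissue-attenuation island inside a lung, so
    after thresholding midway between lung and tumor attenuation it appears
    as a connected component detached from the body shell.  The component
    whose voxel count is closest to the analytic sphere volume is selected.
    """
    sm = ndimage.gaussian_filter(volume.data.astype(np.float64), sigma=1.0)
    thr = 0.5 * (spec.mu_lung + spec.mu_tumor)
    labels, n = ndimage.label(sm > thr)
    if n == 0:
        log.warning("tumor segmentation found no candidate components")
        return volume.like(np.zeros(volume.shape, dtype=np.uint8))
    counts = ndimage.sum_labels(np.ones_like(labels), labels,
                                index=np.arange(1, n + 1))
    expected = (4.0 / 3.0) * np.pi * (spec.tumor_diameter / 2.0) ** 3 \
        / np.prod(volume.spacing)
    order = np.argsort(counts)[::-1]
    candidates = [i for i in order[1:]  # skip the body, always the largest
                  if 0.2 * expected <= counts[i] <= 3.0 * expected]
    if not candidates:
        log.warning("tumor segmentation found no plausible component")
        return volume.like(np.zeros(volume.shape, dtype=np.uint8))
    best = min(candidates, key=lambda i: abs(counts[i] - expected))
    return volume.like((labels == best + 1).astype(np.uint8))


# ---------------------------------------------------------------------------
# cross-scenario study harness
# ---------------------------------------------------------------------------

def evaluate_scenarios(model, spec: PhantomSpec, kinds=TRAJECTORY_KINDS,
                       angle_offset_deg: float = 90.27, eval_stride: int = 1,
                       seed: int = 0, reference_contour: str = "solved",
                       trajectory_kwargs: dict | None = None) -> pd.DataFrame:
    """Train-on-one / test-on-all evaluation grid.

    For each trajectory kind a fresh test scan is simulated with gantry
    angles offset by `angle_offset_deg` from the training scan, every
    `eval_stride`-th frame is pushed through single-projection inference,
    and RE / SSIM / COME / DSC are accumulated against the exact ground
    truth.  Returns one row per scenario plus an 'overall' row of
    frame-weighted means.

    reference_contour: 'solved' segments the tumor from the model's solved
    reference volume (the deployable protocol); 'truth' uses the phantom
    mask directly (isolates motion error from segmentation error).
    """
    from .inference import infer_realtime, propagate_contour

    phantom, tumor_mask = build_phantom(spec)
    geom = model.geometry
    if reference_contour == "solved":
        ref_contour = segment_tumor(model.reference_volume(), spec)
    elif reference_contour == "truth":
        ref_contour = tumor_mask
    else:
        raise ValueError("reference_contour must be 'solved' or 'truth'")
    if not ref_contour.data.any():
        log.warning("empty reference contour; COME/DSC will be NaN")

    tkw = dict(duration_s=geom.n_projections / geom.frame_rate,
               fps=geom.frame_rate)
    tkw.update(trajectory_kwargs or {})
    rows = []
    pooled = {m: [] for m in ("re", "ssim", "come", "dsc")}
    rng = np.random.SeedSequence(seed)
    for kind, child in zip(kinds, rng.spawn(len(kinds))):
        traj = make_trajectory(kind, seed=int(child.generate_state(1)[0] % 2**31),
                               **tkw)
        # only every eval_stride-th frame of the test scan is scored, so
        # only those frames are simulated (results are unchanged)
        sel = np.arange(0, traj.n_frames, eval_stride)
        traj = type(traj)(traj.amplitudes[sel], traj.times[sel], traj.peaks,
                          traj.kind)
        test_geom = type(geom)(sad=geom.sad, sdd=geom.sdd, n_u=geom.n_u,
                               n_v=geom.n_v, du=geom.du, dv=geom.dv,
                               angles=geom.angles[sel] + angle_offset_deg,
                               detector_offset_u=geom.detector_offset_u,
                               frame_rate=geom.frame_rate)
        scan, truth = simulate_scan(phantom, tumor_mask, traj, test_geom, spec)
        metrics = {m: [] for m in pooled}
        for i in range(scan.n_projections):
            _, dvf, est_vol = infer_realtime(model, scan.frames[i])
            gt_vol = truth.volume(i)
            gt_mask = truth.mask(i)
            est_mask = propagate_contour(ref_contour, dvf)
            metrics["re"].append(relative_error(est_vol, gt_vol))
            metrics["ssim"].append(ssim_volume(est_vol, gt_vol))
            metrics["come"].append(come(est_mask, gt_mask, phantom.spacing))
            metrics["dsc"].append(dsc(est_mask, gt_mask))
        row = {"scenario": kind, "n_frames": len(metrics["re"])}
        for m, vals in metrics.items():
            vals = np.asarray(vals)
            row[f"{m}_mean"] = float(np.nanmean(vals))
            row[f"{m}_sd"] = float(np.nanstd(vals))
            pooled[m].extend(vals.tolist())
        rows.append(row)
    overall = {"scenario": "overall", "n_frames": len(pooled["re"])}
    for m, vals in pooled.items():
        overall[f"{m}_mean"] = float(np.nanmean(vals))
        overall[f"{m}_sd"] = float(np.nanstd(vals))
    rows.append(overall)
    return pd.DataFrame(rows)
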