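"""Progressive multiresolution training orchestrator.

Seven stages (I-a .. II-d) progressively raise the learning complexity under
two grid resolutions: the reference network is warm-started against an FDK
volume, then jointly refined with the motion basis and the CNN encoder
against the measured projections, and finally the encoder alone is hardened
with motion/angle augmentation while the anatomy and motion model stay
frozen.  One "epoch" is one optimizer step over one mini-batch of randomly
drawn projections (the stage counts are iteration counts, not passes over
the scan).
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .geometry import ProjectionSet, VolumeGrid, default_step, fdk_reconstruct, project_tensor
from .losses import (AugmentationConfig, LossWeights, augment_scores,
                     augmentation_loss_t, image_similarity_t,
                     mbc_orthonormality_t, projection_similarity_t, tv_t,
                     zero_mean_t)
from .model import DremeModel, ModelConfig
from .motion import evaluate_basis_t, sample_volume_t, warp_tensor
from .networks import preprocess_frame

LOSS_NAMES = ("image", "projection", "tv", "mbc", "zero_mean",
              "self_consistency", "augmentation")


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class Stage:
    name: str
    epochs: int
    resolution: str                      # "lo" (4 mm) or "hi" (2 mm)
    lr_inr: float
    lr_encoder: float
    lr_bspline: float
    losses: tuple[str, ...]
    augmentation: str = "off"            # off / angle_only / motion_and_angle
    image_label: str = "fdk"             # fdk / upsample

    def __post_init__(self):
        unknown = set(self.losses) - set(LOSS_NAMES)
        if unknown:
            raise ValueError(f"unknown losses {sorted(unknown)}")
        if self.resolution not in ("lo", "hi"):
            raise ValueError("resolution must be 'lo' or 'hi'")


@dataclass
class TrainingSchedule:
    """Ordered stage ledger with loss weights; defaults follow the standard
    progressive strategy (zero learning rate = component frozen)."""

    stages: list[Stage]
    weights: LossWeights = field(default_factory=LossWeights)

    @classmethod
    def standard(cls, epochs: dict[str, int] | None = None,
                 epoch_scale: float = 1.0,
                 weights: LossWeights | None = None) -> "TrainingSchedule":
        base = [
            Stage("I-a", 400, "lo", 4e-4, 0.0, 0.0, ("image",)),
            Stage("I-b", 700, "lo", 4e-5, 0.0, 0.0, ("projection", "tv")),
            Stage("I-c", 1700, "lo", 1e-5, 1e-3, 1e-3,
                  ("projection", "tv", "mbc", "zero_mean", "self_consistency")),
            Stage("II-a", 1000, "hi", 1e-3, 0.0, 0.0, ("image",),
                  image_label="upsample"),
            Stage("II-b", 1000, "hi", 4e-4, 0.0, 0.0,
                  ("projection", "tv", "augmentation"), "angle_only"),
            Stage("II-c", 1000, "hi", 1e-4, 1e-4, 1e-4,
                  ("projection", "tv", "mbc", "zero_mean", "self_consistency",
                   "augmentation"), "angle_only"),
            Stage("II-d", 1000, "hi", 0.0, 1e-4, 0.0, ("augmentation",),
                  "motion_and_angle"),
        ]
        out = []
        for st in base:
            n = epochs.get(st.name, st.epochs) if epochs else st.epochs
            out.append(replace(st, epochs=max(int(round(n * epoch_scale)), 0)))
        return cls(out, weights or LossWeights())

    @classmethod
    def desk(cls, weights: LossWeights | None = None,
             epochs: dict[str, int] | None = None) -> "TrainingSchedule":
        """Scaled-down profile: fewer iterations with learning rates
        recalibrated so each stage still converges within its budget."""
        base = [
            Stage("I-a", 150, "lo", 1e-2, 0.0, 0.0, ("image",)),
            Stage("I-b", 100, "lo", 1e-3, 0.0, 0.0, ("projection", "tv")),
            Stage("I-c", 350, "lo", 2.5e-4, 3e-3, 1e-2,
                  ("projection", "tv", "mbc", "zero_mean", "self_consistency")),
            Stage("II-a", 100, "hi", 1e-2, 0.0, 0.0, ("image",),
                  image_label="upsample"),
            Stage("II-b", 70, "hi", 1e-3, 0.0, 0.0,
                  ("projection", "tv", "augmentation"), "angle_only"),
            Stage("II-c", 80, "hi", 2.5e-4, 3e-4, 1e-3,
                  ("projection", "tv", "mbc", "zero_mean", "self_consistency",
                   "augmentation"), "angle_only"),
            Stage("II-d", 300, "hi", 0.0, 1e-3, 0.0, ("augmentation",),
                  "motion_and_angle"),
        ]
        if epochs:
            base = [replace(st, epochs=epochs.get(st.name, st.epochs))
                    for st in base]
        return cls(base, weights or LossWeights())


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with parameter groups; groups with lr == 0 are skipped entirely."""

    def __init__(self, groups: list[tuple[list[Tensor], float]],
                 betas=(0.9, 0.999), eps=1e-8, grad_clip: float | None = None):
        self.groups = [(params, lr) for params, lr in groups if lr > 0]
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {}
        self.v = {}
        for params, _ in self.groups:
            for p in params:
                self.m[id(p)] = np.zeros_like(p.data)
                self.v[id(p)] = np.zeros_like(p.data)

    def parameters(self):
        return [p for params, _ in self.groups for p in params]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def step(self):
        self.t += 1
        if self.grad_clip is not None:
            sq = 0.0
            for p in self.parameters():
                if p.grad is not None:
                    sq += float((p.grad.astype(np.float64) ** 2).sum())
            norm = np.sqrt(sq)
            scale = self.grad_clip / norm if norm > self.grad_clip else 1.0
        else:
            scale = 1.0
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for params, lr in self.groups:
            for p in params:
                if p.grad is None:
                    continue
                g = p.grad * scale
                m = self.m[id(p)]
                v = self.v[id(p)]
                m *= self.b1; m += (1 - self.b1) * g
                v *= self.b2; v += (1 - self.b2) * g * g
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def resample_volume(vol: VolumeGrid, target: VolumeGrid) -> np.ndarray:
    """Trilinear resample of `vol` onto the voxel centers of `target`."""
    pts = target.voxel_centers()
    coords = vol.world_to_voxel(pts).astype(vol.data.dtype)
    with ad.no_grad():
        out = sample_volume_t(Tensor(np.ascontiguousarray(vol.data)),
                              Tensor(np.ascontiguousarray(coords)))
    return out.numpy().reshape(target.shape)


def _state_hash(state: dict) -> str:
    h = hashlib.md5()
    for k in sorted(state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state[k]).tobytes())
    return h.hexdigest()


class _BatchSampler:
    """Uniform sampling without replacement within each shuffled cycle."""

    def __init__(self, n: int, batch: int, rng: np.random.Generator):
        self.n = n
        self.batch = min(batch, n)
        self.rng = rng
        self._queue = np.empty(0, dtype=np.int64)

    def next(self) -> np.ndarray:
        if self._queue.size < self.batch:
            self._queue = np.concatenate([self._queue,
                                          self.rng.permutation(self.n)])
        out, self._queue = self._queue[:self.batch], self._queue[self.batch:]
        return out


def _augmented_drrs(volume: np.ndarray, fields: np.ndarray,
                    targets: np.ndarray, grid: VolumeGrid, geometry,
                    step: float, rng: np.random.Generator):
    """Render DRRs of re-deformed volumes at uniformly random gantry angles."""
    n = targets.shape[0]
    drrs = np.empty((n, geometry.n_v, geometry.n_u), dtype=np.float32)
    angles = rng.uniform(0.0, 360.0, size=n)
    vol_t = Tensor(volume)
    with ad.no_grad():
        for j in range(n):
            disp = np.einsum("ik,ik...->...k", targets[j].astype(np.float32),
                             fields)
            w = warp_tensor(vol_t, Tensor(disp), grid)
            drrs[j] = project_tensor(w, grid, geometry, angles[j], step).numpy()
    return drrs, angles


def make_augmented_batch(model: DremeModel, measured: np.ndarray,
                         cfg: AugmentationConfig, rng: np.random.Generator):
    """Build one augmentation batch from measured frames.

    angle_only: targets are the currently solved scores of the frames and
    the solved dynamic volumes are re-rendered at random angles.
    motion_and_angle: targets are randomly rescaled scores and the volumes
    are re-deformed accordingly before rendering.

    Returns (drr_batch, target_scores, angles).
    """
    if cfg.mode == "off":
        raise ValueError("augmentation mode is off")
    measured = np.atleast_3d(np.asarray(measured))
    if measured.ndim == 2:
        measured = measured[None]
    pre = np.stack([model.preprocess(f) for f in measured])
    scores = model.cnn.encode(pre).reshape(-1, 3, 3)
    if cfg.mode == "motion_and_angle":
        scores = augment_scores(scores, cfg, rng)
    vol = model.reference_volume()
    fields = model.basis_fields()
    step = default_step(model.grid_hi, model.config.step_scale)
    drrs, angles = _augmented_drrs(vol.data, fields, scores, model.grid_hi,
                                   model.geometry, step, rng)
    return drrs, scores, angles


def _base_vox(grid: VolumeGrid) -> np.ndarray:
    from .motion import base_voxel_coords
    return base_voxel_coords(grid, np.float32)


def _warp_frame_t(V: Tensor, fields: Tensor, scores: Tensor, j: int,
                  grid: VolumeGrid, base_vox: np.ndarray) -> Tensor:
    """Fused per-frame warp: scores[j] x fields -> DVF -> pull-back sample.

    One graph node instead of a dozen; avoids materializing intermediate
    (Nvox,3) tensors and their gradients for every batch frame.
    """
    from . import _kernels as K

    n_vox = grid.n_voxels
    inv_sp = (1.0 / np.asarray(grid.spacing)).astype(np.float32)
    w = scores.data[j].astype(np.float32)                    # (3,3)
    f = fields.data.reshape(3, 3, n_vox)
    disp = np.einsum("ik,ikn->nk", w, f)                     # mm
    coords = np.ascontiguousarray(base_vox + disp * inv_sp)
    out = np.empty(n_vox, dtype=np.float32)
    K.tri_gather(V.data, coords, out)

    need_coord_grad = fields.requires_grad or scores.requires_grad

    def back(g):
        g = np.ascontiguousarray(g.reshape(n_vox), dtype=np.float32)
        gV = gf = gw = None
        if V.requires_grad:
            gV = np.zeros_like(V.data)
            K.tri_scatter(gV, coords, g)
        if need_coord_grad:
            gcoords = np.empty_like(coords)
            K.tri_coord_grad(V.data, coords, g, gcoords)
            gdisp = gcoords * inv_sp                         # (Nvox, 3)
            if scores.requires_grad:
                gw = np.zeros_like(scores.data)
                gw[j] = np.einsum("nk,ikn->ik", gdisp, f)
            if fields.requires_grad:
                gf = np.einsum("ik,nk->ikn", w, gdisp).reshape(fields.shape)
        return gV, gf, gw

    return ad.custom(out.reshape(grid.shape), [V, fields, scores], back)


def _subgrid_indices(grid: VolumeGrid, stride: int) -> np.ndarray:
    ix, iy, iz = [np.arange(0, n, stride) for n in grid.shape]
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    return np.ravel_multi_index((gx.ravel(), gy.ravel(), gz.ravel()),
                                grid.shape)


def _self_consistency_t(ref: Tensor, disp: Tensor, warped: Tensor,
                        grid: VolumeGrid, sub_idx: np.ndarray,
                        iterations: int = 3) -> Tensor:
    """Differentiable round-trip loss on a strided voxel subgrid.

    The inverse DVF is evaluated only at the subgrid points by the same
    fixed-point iteration as the standalone inverter; voxels whose round
    trip leaves the FOV are masked out (border clamping is not motion).
    """
    dtype = ref.data.dtype
    shape = grid.shape
    inv_sp = (1.0 / np.asarray(grid.spacing)).astype(dtype)
    sub = np.stack(np.unravel_index(sub_idx, shape), axis=1).astype(dtype)
    base = Tensor(sub)                                   # voxel units
    comps = [disp[:, k].reshape(shape) for k in range(3)]

    dinv = [Tensor(np.zeros(sub.shape[0], dtype=dtype)) for _ in range(3)]
    for _ in range(iterations):
        coords = ad.stack([base[:, k] + dinv[k] * inv_sp[k] for k in range(3)],
                          axis=-1)
        dinv = [-sample_volume_t(comps[k], coords) for k in range(3)]
    coords = ad.stack([base[:, k] + dinv[k] * inv_sp[k] for k in range(3)],
                      axis=-1)
    iprime = sample_volume_t(warped, coords)
    ref_sub = ref.reshape(int(np.prod(shape)))[sub_idx]

    with ad.no_grad():
        c = coords.data
        ok1 = np.all((c >= 0) & (c <= np.asarray(shape) - 1), axis=1)
        d_at = np.stack([comps[k].data[tuple(np.clip(np.round(c).astype(int), 0,
                         np.asarray(shape) - 1).T)] for k in range(3)], axis=1)
        c2 = c + d_at * inv_sp
        ok2 = np.all((c2 >= 0) & (c2 <= np.asarray(shape) - 1), axis=1)
        mask = (ok1 & ok2).astype(dtype)
    denom = float(max(mask.sum(), 1.0))
    diff = (iprime - ref_sub) * Tensor(mask)
    return (diff ** 2).sum() * (1.0 / denom)


# ---------------------------------------------------------------------------
# main training loop
# ---------------------------------------------------------------------------

def train_dreme(projections: ProjectionSet,
                schedule: TrainingSchedule | None = None,
                config: ModelConfig | None = None, seed: int = 17,
                verbose: bool = False,
                keep_stage_states: bool = False):
    """Run the full staged optimization on one pre-treatment scan.

    Returns (model, report) where report carries the per-epoch loss history,
    per-stage parameter hashes (freezing audit) and optional stage states.
    """
    schedule = schedule or TrainingSchedule.standard()
    config = config or ModelConfig()
    model = DremeModel(projections.geometry, config, seed=seed)
    geometry = projections.geometry
    frames = projections.frames.astype(np.float32)
    n_frames = frames.shape[0]
    frame_norm = float(frames.max()) if frames.max() > 0 else 1.0
    preproc = np.stack([preprocess_frame(f, config.cnn_input, frame_norm)
                        for f in frames])

    ss = np.random.SeedSequence([int(seed), 7])
    rng_batch, rng_sub, rng_aug = [np.random.default_rng(s) for s in ss.spawn(3)]
    weights = schedule.weights
    aug_cfg = AugmentationConfig(mode="motion_and_angle",
                                 seed=int(seed))

    history: list[dict] = []
    stage_hashes: dict[str, dict] = {}
    stage_states: dict[str, dict] = {}
    fdk_label: np.ndarray | None = None

    for stage in schedule.stages:
        grid = model.grid_lo if stage.resolution == "lo" else model.grid_hi
        n_vox = grid.n_voxels
        step = default_step(grid, config.step_scale)
        sampler = _BatchSampler(n_frames, config.n_batch, rng_batch)
        sub_idx_sc = _subgrid_indices(grid, config.sc_stride)
        base_vox = _base_vox(grid)

        inr_on = stage.lr_inr > 0
        enc_on = stage.lr_encoder > 0
        bsp_on = stage.lr_bspline > 0
        opt = Adam([(model.inr.parameters(), stage.lr_inr),
                    (model.cnn.parameters(), stage.lr_encoder),
                    (model.basis.parameters(), stage.lr_bspline)],
                   grad_clip=config.grad_clip)

        before = {k: _state_hash(v) for k, v in model.state().items()}

        # image-domain label for warm-start stages
        label_flat = None
        if "image" in stage.losses:
            if stage.image_label == "fdk":
                if fdk_label is None or fdk_label.shape != grid.shape:
                    fdk_label = fdk_reconstruct(projections, grid.shape,
                                                grid.spacing, grid.origin).data
                label_flat = fdk_label.reshape(-1).astype(np.float32)
            else:  # tri-linear upsampling of the solved low-res reference
                lo_ref = model.reference_volume(model.grid_lo)
                label_flat = resample_volume(lo_ref, grid).reshape(-1)

        # frozen-component caches
        V_const = fields_const = None
        need_v = any(l in stage.losses for l in
                     ("projection", "tv", "self_consistency"))
        need_fields = any(l in stage.losses for l in
                          ("projection", "mbc", "self_consistency"))
        if (need_v or stage.augmentation != "off") and not inr_on:
            V_const = model.reference_volume(grid).data
        if (need_fields or stage.augmentation != "off") and not bsp_on:
            with ad.no_grad():
                fields_const = evaluate_basis_t(model.basis, grid).numpy()
        solved_stage = None
        if stage.augmentation == "motion_and_angle":
            # targets come from the scores solved by the reconstruction,
            # frozen at stage entry (not from the updating encoder)
            solved_stage = model.cnn.encode(preproc).reshape(n_frames, 3, 3)

        t_stage = time.perf_counter()
        for epoch in range(stage.epochs):
            batch = sampler.next()
            nb = batch.size
            terms: dict[str, Tensor] = {}

            if "image" in stage.losses:
                if config.image_subsample and config.image_subsample < n_vox:
                    subset = rng_sub.integers(0, n_vox,
                                              size=config.image_subsample)
                else:
                    subset = None
                pred = model.inr.render_t(grid, subset=subset)
                lab = label_flat if subset is None else label_flat[subset]
                terms["image"] = image_similarity_t(
                    pred.reshape(lab.size), Tensor(lab))

            V = None
            if need_v:
                V = model.inr.render_t(grid) if inr_on else Tensor(V_const)
            fields = None
            if need_fields:
                fields = (evaluate_basis_t(model.basis, grid) if bsp_on
                          else Tensor(fields_const))

            scores33 = None
            warped: dict[int, tuple] = {}
            if "projection" in stage.losses:
                x = Tensor(preproc[batch][:, None])
                if enc_on:
                    scores33 = model.cnn.forward_t(x, training=True)
                    scores33 = scores33.reshape(nb, 3, 3)
                else:
                    # frozen encoder: keep the scores out of the graph so the
                    # warp backward skips CNN and coordinate gradients
                    with ad.no_grad():
                        scores33 = model.cnn.forward_t(x, training=False)
                        scores33 = scores33.reshape(nb, 3, 3)
                sc_set = (set(range(min(config.sc_frames, nb)))
                          if "self_consistency" in stage.losses else set())
                ek = None
                drrs = []
                for j, fi in enumerate(batch):
                    if j in sc_set:
                        # explicit DVF tensor: the self-consistency loss needs
                        # to sample the displacement field itself
                        if ek is None:
                            ek = [fields[:, k].reshape(3, n_vox)
                                  for k in range(3)]
                        comps = [(scores33[j:j + 1, :, k] @ ek[k]).reshape(n_vox)
                                 for k in range(3)]
                        disp = ad.stack(comps, axis=-1)
                        w = warp_tensor(V, disp, grid)
                        warped[j] = (w, disp)
                    else:
                        w = _warp_frame_t(V, fields, scores33, j, grid,
                                          base_vox)
                    drrs.append(project_tensor(w, grid, geometry,
                                               geometry.angles[fi], step))
                drr_stack = ad.stack(drrs, axis=0)
                measured = frames[batch]
                if config.normalize_projections:
                    drr_stack = drr_stack * (1.0 / frame_norm)
                    measured = measured / frame_norm
                terms["projection"] = projection_similarity_t(
                    drr_stack, Tensor(measured))

            if "tv" in stage.losses:
                terms["tv"] = tv_t(V)
            if "mbc" in stage.losses:
                terms["mbc"] = mbc_orthonormality_t(fields)
            if "zero_mean" in stage.losses and scores33 is not None:
                terms["zero_mean"] = zero_mean_t(scores33)
            if "self_consistency" in stage.losses and warped:
                sc_js = list(range(min(config.sc_frames, nb)))
                sc_total = None
                for j in sc_js:
                    w, disp = warped[j]
                    t = _self_consistency_t(V, disp, w, grid, sub_idx_sc)
                    sc_total = t if sc_total is None else sc_total + t
                terms["self_consistency"] = sc_total * (1.0 / len(sc_js))

            # with a frozen encoder the augmentation term carries no gradient;
            # rendering its DRR batch would only burn time
            if "augmentation" in stage.losses and enc_on:
                with ad.no_grad():
                    vol_np = V.data if V is not None else (
                        V_const if V_const is not None
                        else model.inr.render_t(grid).numpy())
                    f_np = fields.data if fields is not None else (
                        fields_const if fields_const is not None
                        else evaluate_basis_t(model.basis, grid).numpy())
                    if stage.augmentation == "motion_and_angle":
                        tgt = augment_scores(solved_stage[batch], aug_cfg,
                                             rng_aug)
                    elif scores33 is not None:
                        tgt = scores33.data.copy().astype(np.float64)
                    else:
                        tgt = model.cnn.encode(preproc[batch]).reshape(nb, 3, 3)
                    drr_aug, _ = _augmented_drrs(vol_np, f_np, tgt, grid,
                                                 geometry, step, rng_aug)
                pre_aug = np.stack([preprocess_frame(f, config.cnn_input,
                                                     frame_norm)
                                    for f in drr_aug])
                pred = model.cnn.forward_t(Tensor(pre_aug[:, None]),
                                           training=enc_on)
                terms["augmentation"] = augmentation_loss_t(
                    pred, Tensor(tgt.reshape(nb, 9).astype(np.float32)))

            lam = {"image": weights.image_sim, "projection": weights.projection_sim,
                   "tv": weights.tv, "mbc": weights.mbc,
                   "zero_mean": weights.zero_mean,
                   "self_consistency": weights.self_consistency,
                   "augmentation": weights.augmentation}
            total = None
            for name, t in terms.items():
                wt = t * lam[name]
                total = wt if total is None else total + wt
            if total is None:
                continue
            tval = total.item()
            if not np.isfinite(tval):
                raise RuntimeError(
                    f"non-finite loss at stage {stage.name} epoch {epoch}: "
                    + ", ".join(f"{k}={v.item():.3e}" for k, v in terms.items()))
            opt.zero_grad()
            total.backward()
            opt.step()
            rec = {"stage": stage.name, "epoch": epoch, "total": tval,
                   "seconds": time.perf_counter() - t_stage}
            rec.update({k: v.item() for k, v in terms.items()})
            history.append(rec)
            if verbose and (epoch % 50 == 0 or epoch == stage.epochs - 1):
                print(f"[{stage.name}] epoch {epoch:5d} total {tval:.5e}")

        model.invalidate_caches()
        after = {k: _state_hash(v) for k, v in model.state().items()}
        stage_hashes[stage.name] = {k: (before[k], after[k]) for k in before}
        if keep_stage_states:
            stage_states[stage.name] = model.state()

    solved = model.cnn.encode(preproc).reshape(n_frames, 3, 3)
    model.finalize(solved, frame_norm)
    report = {"history": history, "stage_hashes": stage_hashes,
              "stage_states": stage_states}
    return model, report
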