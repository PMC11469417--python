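"""Synthetic dynamic thorax phantom and cone-beam scan simulator.

An analytic attenuation phantom (body/lung ellipsoids, a spine cylinder and
a spherical lung tumor) is deformed by a smooth, diaphragm-anchored,
SI-dominant displacement field scaled by a breathing amplitude a(t) in [0,1].
Seven trajectory kinds emulate progressively harder breathing scenarios,
including one whose SI range extends beyond all others.  Ground truth (the
displacement field, per-frame amplitudes, tumor masks and centroids) is
recorded exactly as generated, so the evaluation chain can be validated
independently of any training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (ProjectionSet, ScanGeometry, VolumeGrid,
                       forward_project)
from .motion import DVF, warp_volume

TRAJECTORY_KINDS = ("regular", "amplitude-varying", "frequency-varying",
                    "pattern-shift", "slow", "irregular", "extended-range")


@dataclass
class PhantomSpec:
    """Analytic thorax phantom definition (all lengths mm, attenuation mm^-1).

    Structure geometry defaults scale with the grid extent so the same
    anatomy proportions hold at full scale (400x400x200 mm) and desk scale.
    """

    shape: tuple[int, int, int] = (200, 200, 100)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mu_tissue: float = 0.020
    mu_lung: float = 0.004
    mu_bone: float = 0.040
    mu_tumor: float = 0.020
    tumor_diameter: float = 30.0
    # fractions of the half-extent per axis
    body_frac: tuple[float, float] = (0.84, 0.70)
    lung_center_frac: tuple[float, float, float] = (0.40, 0.0, 0.30)
    lung_semi_frac: tuple[float, float, float] = (0.30, 0.62, 1.15)
    tumor_center_frac: tuple[float, float, float] = (0.40, 0.06, -0.20)
    spine_center_frac: float = 0.52
    spine_radius_frac: float = 0.12

    def __post_init__(self):
        if min(self.shape) < 8:
            raise ValueError("grid too small")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.tumor_diameter < 0:
            raise ValueError("tumor diameter must be non-negative")
        for mu in (self.mu_tissue, self.mu_lung, self.mu_bone, self.mu_tumor):
            if mu < 0:
                raise ValueError("attenuation must be non-negative")

    @property
    def half_extent(self) -> np.ndarray:
        return np.array([(n - 1) * s / 2.0
                         for n, s in zip(self.shape, self.spacing)])

    @property
    def tumor_center(self) -> np.ndarray:
        return np.asarray(self.tumor_center_frac) * self.half_extent


def build_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid]:
    """Piecewise-constant attenuation volume and binary tumor mask."""
    grid = VolumeGrid(np.zeros(spec.shape, dtype=np.float32), spec.spacing)
    he = spec.half_extent
    ax = [np.asarray(grid.origin)[i] + np.arange(spec.shape[i]) * spec.spacing[i]
          for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")

    vol = grid.data
    bx, by = spec.body_frac[0] * he[0], spec.body_frac[1] * he[1]
    body = (X / bx) ** 2 + (Y / by) ** 2 <= 1.0
    vol[body] = spec.mu_tissue

    sc = spec.spine_center_frac * he[1]
    sr = spec.spine_radius_frac * he[0]
    spine = (X ** 2 + (Y - sc) ** 2) <= sr ** 2
    vol[body & spine] = spec.mu_bone

    lc = np.asarray(spec.lung_center_frac) * he
    ls = np.asarray(spec.lung_semi_frac) * he
    for sgn in (+1, -1):
        lung = ((X - sgn * lc[0]) / ls[0]) ** 2 + ((Y - lc[1]) / ls[1]) ** 2 \
            + ((Z - lc[2]) / ls[2]) ** 2 <= 1.0
        vol[body & lung] = spec.mu_lung

    tc = spec.tumor_center
    r = spec.tumor_diameter / 2.0
    tumor = (X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2 <= r ** 2
    if spec.tumor_diameter > 0:
        vol[tumor] = spec.mu_tumor
    mask = grid.like(tumor.astype(np.uint8))
    return grid, mask


def motion_weight_field(spec: PhantomSpec, grid: VolumeGrid | None = None,
                        peaks: tuple[float, float, float] = (2.0, 3.0, 10.0),
                        z_anchor_frac: float = 0.2,
                        z_scale_frac: float = 0.25) -> np.ndarray:
    """Ground-truth displacement field D(x), shape (nx, ny, nz, 3), in mm.

    SI-dominant and diaphragm-anchored: a sigmoid in z concentrates motion
    inferiorly, a quadratic in-plane taper makes it vanish at the chest wall.
    `peaks` are the (LR, AP, SI) displacement maxima.  Positive SI means the
    anatomy shifts inferiorly under the pull-back warp.
    """
    if grid is None:
        grid = VolumeGrid(np.zeros(spec.shape, dtype=np.float32), spec.spacing)
    he = spec.half_extent
    ax = [np.asarray(grid.origin)[i] + np.arange(grid.shape[i]) * grid.spacing[i]
          for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    bx, by = spec.body_frac[0] * he[0], spec.body_frac[1] * he[1]
    wxy = np.maximum(1.0 - (X / bx) ** 2 - (Y / by) ** 2, 0.0)
    z0 = z_anchor_frac * he[2]
    tau = z_scale_frac * he[2]
    wz = 1.0 / (1.0 + np.exp((Z - z0) / tau))
    w = (wxy * wz).astype(np.float32)
    D = np.empty(grid.shape + (3,), dtype=np.float32)
    for k in range(3):
        D[..., k] = w * peaks[k]
    return D


@dataclass
class MotionTrajectory:
    """Scalar breathing amplitude a(t) plus per-direction peak displacements."""

    amplitudes: np.ndarray           # (Nt,), values in [0, ~1.4]
    times: np.ndarray                # (Nt,) seconds
    peaks: tuple[float, float, float]  # (LR, AP, SI) mm
    kind: str = "regular"

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.amplitudes.shape != self.times.shape:
            raise ValueError("amplitudes/times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.amplitudes.size


def _raised_cosine(phase: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Breathing waveform in [0,1]: long exhale dwell, sharp inhale peak."""
    return ((1.0 - np.cos(2.0 * np.pi * phase)) / 2.0) ** power


def make_trajectory(kind: str, duration_s: float = 60.0, fps: float = 11.0,
                    seed: int = 0, period_s: float = 4.0,
                    peaks: tuple[float, float, float] = (2.0, 3.0, 10.0),
                    extend_factor: float = 1.35) -> MotionTrajectory:
    """Breathing trajectory analog of one study scenario.

    Kinds: regular / amplitude-varying / frequency-varying / pattern-shift /
    slow / irregular / extended-range.  All but the last share the same SI
    range; 'extended-range' exceeds it by `extend_factor`.
    """
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"kind must be one of {TRAJECTORY_KINDS}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps

    if kind == "slow":
        a = _raised_cosine(t / (1.5 * period_s))
    elif kind == "frequency-varying":
        inst_period = period_s * (1.0 + 0.2 * np.sin(2 * np.pi * t / 15.0
                                                     + rng.uniform(0, 2 * np.pi)))
        phase = np.cumsum(1.0 / (inst_period * fps))
        a = _raised_cosine(phase)
    elif kind == "amplitude-varying":
        env = 0.75 + 0.25 * np.sin(2 * np.pi * t / 22.0 + rng.uniform(0, 2 * np.pi))
        a = env * _raised_cosine(t / period_s)
    elif kind == "pattern-shift":
        half = t >= duration_s / 2.0
        a = np.where(half,
                     0.15 + 0.85 * _raised_cosine(t / period_s, power=1.0),
                     _raised_cosine(t / period_s, power=2.0))
    elif kind == "irregular":
        # per-cycle random amplitude and period, linearly blended
        phase = np.zeros(n)
        period = period_s * rng.uniform(0.8, 1.3)
        amp = rng.uniform(0.6, 1.1)
        amps = np.empty(n)
        ph = 0.0
        for i in range(n):
            ph += 1.0 / (period * fps)
            if ph >= 1.0:
                ph -= 1.0
                period = period_s * rng.uniform(0.8, 1.3)
                amp = rng.uniform(0.6, 1.1)
            phase[i] = ph
            amps[i] = amp
        a = amps * _raised_cosine(phase)
    elif kind == "extended-range":
        a = extend_factor * _raised_cosine(t / period_s)
    else:  # regular
        a = _raised_cosine(t / period_s)

    return MotionTrajectory(a, t, tuple(peaks), kind)


@dataclass
class GroundTruth:
    """Exact per-frame motion truth of a simulated scan."""

    phantom: VolumeGrid
    tumor_mask: VolumeGrid
    weight_field: np.ndarray         # D(x): (nx, ny, nz, 3) mm at unit amplitude
    amplitudes: np.ndarray           # (Np,)
    tumor_centers: np.ndarray        # (Np, 3) world mm
    trajectory: MotionTrajectory = None

    def dvf(self, i: int) -> DVF:
        return DVF(self.amplitudes[i] * self.weight_field,
                   self.phantom.spacing, self.phantom.origin)

    def volume(self, i: int) -> VolumeGrid:
        return warp_volume(self.phantom, self.dvf(i))

    def mask(self, i: int) -> VolumeGrid:
        from .inference import propagate_contour
        return propagate_contour(self.tumor_mask, self.dvf(i))


def _mask_centroid(mask: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    idx = np.argwhere(mask > 0)
    if idx.size == 0:
        return np.full(3, np.nan)
    return np.asarray(grid.origin) + idx.mean(axis=0) * np.asarray(grid.spacing)


def simulate_scan(phantom: VolumeGrid, tumor_mask: VolumeGrid,
                  trajectory: MotionTrajectory, geometry: ScanGeometry,
                  spec: PhantomSpec, noise_i0: float | None = None,
                  seed: int = 0) -> tuple[ProjectionSet, GroundTruth]:
    """Render a dynamic cone-beam scan frame by frame.

    Each frame warps the phantom by a(t)*D(x) (pull-back convention) and
    projects it at that frame's gantry angle.  Optional Poisson noise is
    applied on pre-log intensities with incident fluence `noise_i0`.
    """
    if trajectory.n_frames != geometry.n_projections:
        raise ValueError("trajectory length must equal the number of angles")
    from .inference import propagate_contour

    D = motion_weight_field(spec, phantom, peaks=trajectory.peaks)
    frames = np.empty((geometry.n_projections, geometry.n_v, geometry.n_u),
                      dtype=np.float32)
    centers = np.empty((geometry.n_projections, 3))
    rng = np.random.default_rng(seed)
    for i, (a, ang) in enumerate(zip(trajectory.amplitudes, geometry.angles)):
        dvf = DVF(np.float32(a) * D, phantom.spacing, phantom.origin)
        vol_i = warp_volume(phantom, dvf)
        frames[i] = forward_project(vol_i, geometry, ang)
        centers[i] = _mask_centroid(propagate_contour(tumor_mask, dvf).data,
                                    phantom)
    if noise_i0 is not None:
        intensity = noise_i0 * np.exp(-frames.astype(np.float64))
        noisy = rng.poisson(intensity)
        frames = (-np.log(np.maximum(noisy, 1.0) / noise_i0)).astype(np.float32)
    truth = GroundTruth(phantom, tumor_mask, D, trajectory.amplitudes.copy(),
                        centers, trajectory)
    return ProjectionSet(frames, geometry), truth


def default_geometry(n_projections: int = 660, span_deg: float = 360.0,
                     start_deg: float = 0.0, n_u: int = 256, n_v: int = 192,
                     du: float = 1.55, dv: float = 1.55, sad: float = 1000.0,
                     sdd: float = 1500.0, fps: float = 11.0) -> ScanGeometry:
    """Full-fan circular scan; defaults emulate the full-scale study setup."""
    angles = start_deg + np.arange(n_projections) * span_deg / n_projections
    return ScanGeometry(sad=sad, sdd=sdd, n_u=n_u, n_v=n_v, du=du, dv=dv,
                        angles=angles, frame_rate=fps)
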