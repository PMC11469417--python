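"""Cone-beam scan geometry, volumes, DRR forward projection and FDK.

Conventions (frozen for the whole package):
  * world coordinates in mm; x = left-right, y = anterior-posterior,
    z = superior-inferior; the rotation axis is z through the isocenter;
  * gantry angles in degrees, counter-clockwise, 0 deg = source on the +y
    axis; the flat detector is perpendicular to the source-isocenter line;
  * volume arrays are indexed ``data[ix, iy, iz]``, origin = world position
    of voxel (0,0,0) center, 0-based indices;
  * projections are stored post-log, i.e. as line integrals of attenuation
    (mm^-1 * mm, dimensionless), frame shape (n_v, n_u).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from . import _kernels as K


@dataclass
class ScanGeometry:
    """Circular cone-beam acquisition parameters.

    sad/sdd: source-axis / source-detector distance (mm); n_u, n_v: detector
    pixel counts; du, dv: pixel pitch (mm); detector_offset_u: lateral
    detector offset (mm; 0 = full-fan); angles: per-frame gantry angles
    (deg); frame_rate: frames per second.
    """

    sad: float
    sdd: float
    n_u: int
    n_v: int
    du: float
    dv: float
    angles: np.ndarray
    detector_offset_u: float = 0.0
    frame_rate: float = 11.0

    def __post_init__(self):
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        if not (self.sad > 0 and self.sdd > self.sad):
            raise ValueError("require sad > 0 and sdd > sad")
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("detector must have at least one pixel per axis")
        if self.du <= 0 or self.dv <= 0:
            raise ValueError("pixel pitch must be positive")
        if not np.all(np.isfinite(self.angles)) or self.angles.size < 1:
            raise ValueError("angles must be finite and non-empty")

    @property
    def n_projections(self) -> int:
        return int(self.angles.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_projections) / self.frame_rate

    def source_position(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return np.array([-self.sad * np.sin(th), self.sad * np.cos(th), 0.0])

    def detector_frame(self, angle_deg: float):
        """Return (pixel(0,0) world position, u step, v step) for one frame."""
        th = np.deg2rad(angle_deg)
        u_axis = np.array([np.cos(th), np.sin(th), 0.0])
        v_axis = np.array([0.0, 0.0, 1.0])
        center = (self.sdd - self.sad) * np.array([np.sin(th), -np.cos(th), 0.0])
        det00 = (center
                 + u_axis * (self.detector_offset_u - (self.n_u - 1) / 2.0 * self.du)
                 + v_axis * (-(self.n_v - 1) / 2.0 * self.dv))
        return det00, u_axis * self.du, v_axis * self.dv


_VOXEL_CENTER_CACHE: dict = {}


@dataclass
class VolumeGrid:
    """A 3D scalar field (attenuation, mm^-1) on a regular grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            # center the grid on the isocenter
            self.origin = tuple(-(n - 1) / 2.0 * s
                                for n, s in zip(self.data.shape, self.spacing))
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (Nvoxel, 3).

        The array is cached per (shape, spacing, origin) and returned
        read-only; callers needing to mutate it must copy.
        """
        key = (self.data.shape, self.spacing, self.origin)
        cached = _VOXEL_CENTER_CACHE.get(key)
        if cached is None:
            axes = [self.origin[i]
                    + np.arange(self.data.shape[i]) * self.spacing[i]
                    for i in range(3)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            cached = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
            cached.setflags(write=False)
            if len(_VOXEL_CENTER_CACHE) > 16:
                _VOXEL_CENTER_CACHE.clear()
            _VOXEL_CENTER_CACHE[key] = cached
        return cached

    def like(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data, self.spacing, self.origin)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class ProjectionSet:
    """A stack of post-log projections with their acquisition geometry."""

    frames: np.ndarray  # (Np, n_v, n_u)
    geometry: ScanGeometry
    acquisition_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (Np, n_v, n_u) stack")
        np_, nv, nu = self.frames.shape
        if (nv, nu) != (self.geometry.n_v, self.geometry.n_u):
            raise ValueError("frame shape does not match geometry")
        if np_ != self.geometry.n_projections:
            raise ValueError("frame count does not match geometry.angles")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if self.acquisition_index is None:
            self.acquisition_index = np.arange(np_)

    @property
    def n_projections(self) -> int:
        return self.frames.shape[0]


def default_step(volume: VolumeGrid, step_scale: float = 0.5) -> float:
    """Ray-marching step: `step_scale` x the smallest voxel spacing."""
    return float(min(volume.spacing) * step_scale)


def project_tensor(vol: "ad.Tensor", volume: VolumeGrid, geometry: ScanGeometry,
                   angle_deg: float, step: float | None = None) -> "ad.Tensor":
    """Differentiable DRR of a volume tensor shaped like `volume.data`."""
    if step is None:
        step = default_step(volume)
    src = geometry.source_position(angle_deg)
    det00, ustep, vstep = geometry.detector_frame(angle_deg)
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    nu, nv = geometry.n_u, geometry.n_v
    dtype = vol.data.dtype
    out = np.zeros((nv, nu), dtype=dtype)
    K.cone_fp(vol.data, spacing.astype(dtype), origin.astype(dtype),
              src.astype(dtype), det00.astype(dtype), ustep.astype(dtype),
              vstep.astype(dtype), nu, nv, dtype.type(step), out)

    def back(g):
        gvol = np.zeros_like(vol.data)
        K.cone_bp(gvol, spacing.astype(dtype), origin.astype(dtype),
                  src.astype(dtype), det00.astype(dtype), ustep.astype(dtype),
                  vstep.astype(dtype), nu, nv, dtype.type(step),
                  np.ascontiguousarray(g, dtype=dtype))
        return (gvol,)

    return ad.custom(out, [vol], back)


def forward_project(volume: VolumeGrid, geometry: ScanGeometry,
                    angle_deg: float, step: float | None = None) -> np.ndarray:
    """DRR (post-log line integrals) of `volume` at one gantry angle."""
    if volume.n_voxels == 0:
        raise ValueError("empty volume")
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume must be finite")
    return project_tensor(ad.Tensor(volume.data), volume, geometry,
                          angle_deg, step).numpy()


def project_set(volume: VolumeGrid, geometry: ScanGeometry,
                step: float | None = None) -> ProjectionSet:
    """One DRR per angle in `geometry.angles`, in order."""
    frames = np.stack([forward_project(volume, geometry, a, step)
                       for a in geometry.angles])
    return ProjectionSet(frames, geometry)


def ramp_kernel(half_size: int, du: float) -> np.ndarray:
    """Discrete spatial-domain ramp filter (Ram-Lak), indices -n..n.

    h[0] = 1/(4 du^2); h[k] = -1/(pi k du)^2 for odd k; 0 for even k.
    """
    k = np.arange(-half_size, half_size + 1)
    h = np.zeros(k.shape, dtype=np.float64)
    h[k == 0] = 1.0 / (4.0 * du ** 2)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi * k[odd] * du) ** 2
    return h


def ramp_filter_rows(rows: np.ndarray, du: float) -> np.ndarray:
    """Convolve the last axis with the discrete ramp kernel (FFT-based).

    `rows` may be any (..., n) stack of detector rows; returns the filtered
    rows scaled by du (the discrete convolution approximating the integral).
    """
    n = rows.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(4 * n)))
    h = np.zeros(nfft)
    h[:2 * n + 1] = ramp_kernel(n, du)
    h = np.roll(h, -n)
    Hf = np.fft.rfft(h)
    spec = np.fft.rfft(rows, n=nfft, axis=-1)
    out = np.fft.irfft(spec * Hf, n=nfft, axis=-1)[..., :n]
    return out * du


def _halffan_weights(u_iso: np.ndarray, offset_iso: float, half_width_iso: float) -> np.ndarray:
    """Smooth redundancy weighting for a laterally offset (half-fan) detector."""
    d = max(half_width_iso - abs(offset_iso), 1e-6)
    x = u_iso / d
    if offset_iso >= 0:
        w = 0.5 * (1.0 + np.sin(0.5 * np.pi * np.clip(x, -1.0, 1.0)))
    else:
        w = 0.5 * (1.0 - np.sin(0.5 * np.pi * np.clip(x, -1.0, 1.0)))
    return 2.0 * w


def fdk_reconstruct(projections: ProjectionSet, shape: tuple[int, int, int],
                    spacing: tuple[float, float, float],
                    origin: tuple[float, float, float] | None = None) -> VolumeGrid:
    """Feldkamp-Davis-Kress filtered backprojection.

    Used as the approximate volume for the INR warm start; it is not expected
    to be artifact-free on a moving subject.
    """
    geom = projections.geometry
    angles = geom.angles
    span = np.ptp(angles)
    if projections.n_projections < 50 or span < 200.0:
        warnings.warn("FDK with <50 views or <200 deg span is unreliable",
                      stacklevel=2)
    mag = geom.sad / geom.sdd
    du_iso = geom.du * mag
    dv_iso = geom.dv * mag
    off_iso = geom.detector_offset_u * mag
    nu, nv = geom.n_u, geom.n_v
    u = (np.arange(nu) - (nu - 1) / 2.0) * du_iso + off_iso
    v = (np.arange(nv) - (nv - 1) / 2.0) * dv_iso
    uu, vv = np.meshgrid(u, v)
    cosw = geom.sad / np.sqrt(geom.sad ** 2 + uu ** 2 + vv ** 2)
    if abs(geom.detector_offset_u) > 0:
        cosw = cosw * _halffan_weights(u, off_iso, (nu / 2.0) * du_iso)[None, :]

    weighted = projections.frames.astype(np.float64) * cosw[None]
    filt = ramp_filter_rows(weighted, du_iso)

    dbeta = np.deg2rad(span + (span / max(len(angles) - 1, 1))) / len(angles)
    weight = dbeta / 2.0

    vol = np.zeros(shape, dtype=np.float64)
    grid = VolumeGrid(vol, spacing, origin)
    K.fdk_backproject(grid.data, np.asarray(grid.spacing), np.asarray(grid.origin),
                      np.ascontiguousarray(filt), np.deg2rad(angles),
                      float(geom.sad), float(geom.sdd), du_iso, dv_iso, off_iso,
                      weight)
    return VolumeGrid(grid.data.astype(np.float32), spacing, grid.origin)
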