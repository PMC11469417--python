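"""Low-rank respiratory motion model.

A displacement field is factorized into three spatial motion basis components
(MBCs) per Cartesian direction, each a learnable cubic B-spline coefficient
grid, weighted by nine scalar scores per time point:

    d_k(x, p) = sum_i  w_{i,k}(p) * e_{i,k}(x),   i = 1..3,  k = x,y,z

The control-point count doubles at each level so the levels represent coarse
to fine spatial scales.  Volumes are warped with the pull-back convention
I(x,p) = Iref(x + d(x,p)) and inverses are computed by fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from . import _autodiff as ad
from . import _kernels as K
from ._autodiff import Tensor
from .geometry import VolumeGrid


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MBCScores:
    """Nine temporal coefficients w_{i,k}: level i in {1,2,3}, k in {x,y,z}."""

    w: np.ndarray  # (3, 3) [level, direction]

    def __post_init__(self):
        w = np.asarray(self.w, dtype=np.float64)
        if w.size != 9:
            raise ValueError("MBC scores must have exactly 9 entries")
        if not np.all(np.isfinite(w)):
            raise ValueError("MBC scores must be finite")
        self.w = w.reshape(3, 3)

    @property
    def flat(self) -> np.ndarray:
        return self.w.reshape(9)


@dataclass
class DVF:
    """Dense displacement field (mm) on a volume grid, pull-back convention."""

    displacement: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.displacement.shape[:3]

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "DVF":
        return cls(np.zeros(grid.shape + (3,), dtype=np.float32),
                   grid.spacing, grid.origin)


class MotionBasisSet:
    """Learnable B-spline coefficient grids e_{i,k}(x), three levels.

    The control lattice covers the volume extent with clamped uniform knots;
    level l has ``2**l`` times the base control-point count per axis.
    """

    def __init__(self, extent: tuple[float, float, float],
                 origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 base_control: tuple[int, int, int] = (6, 6, 4),
                 n_levels: int = 3, order: int = 3,
                 dtype=np.float32):
        self.extent = tuple(float(e) for e in extent)
        self.origin = tuple(float(o) for o in origin)
        self.order = int(order)
        self.n_levels = int(n_levels)
        self.control_dims = []
        self.coefficients: list[Tensor] = []
        for lvl in range(n_levels):
            dims = tuple(int(c) * 2 ** lvl for c in base_control)
            if min(dims) < order + 1:
                raise ValueError("control grid too small for spline order")
            self.control_dims.append(dims)
            self.coefficients.append(
                Tensor(np.zeros((3,) + dims, dtype=dtype), requires_grad=True))
        self._design_cache: dict = {}

    @classmethod
    def covering(cls, grids: list[VolumeGrid], **kwargs) -> "MotionBasisSet":
        """A basis whose spline support covers every grid in `grids`."""
        lo = np.min([g.origin for g in grids], axis=0)
        hi = np.max([np.asarray(g.origin) + np.asarray(g.extent)
                     for g in grids], axis=0)
        return cls(extent=tuple(hi - lo), origin=tuple(lo), **kwargs)

    # -- spline machinery -------------------------------------------------
    def _knots(self, n_ctrl: int, length: float) -> np.ndarray:
        k = self.order
        internal = np.linspace(0.0, length, n_ctrl - k + 1)[1:-1]
        return np.concatenate([[0.0] * (k + 1), internal, [length] * (k + 1)])

    def design_matrices(self, grid: VolumeGrid):
        """Per-axis dense design matrices (n_axis, n_ctrl) for each level."""
        key = (grid.shape, grid.spacing, grid.origin)
        if key in self._design_cache:
            return self._design_cache[key]
        mats = []
        for lvl in range(self.n_levels):
            per_axis = []
            for ax in range(3):
                n_ctrl = self.control_dims[lvl][ax]
                x = (grid.origin[ax] - self.origin[ax]
                     + np.arange(grid.shape[ax]) * grid.spacing[ax])
                if x[0] < -1e-6 or x[-1] > self.extent[ax] + 1e-6:
                    raise ValueError("grid extends beyond the B-spline support")
                x = np.clip(x, 0.0, self.extent[ax])
                t = self._knots(n_ctrl, self.extent[ax])
                B = BSpline.design_matrix(x, t, self.order).toarray()
                per_axis.append(np.ascontiguousarray(B))
            mats.append(per_axis)
        self._design_cache[key] = mats
        return mats

    def parameters(self) -> list[Tensor]:
        return self.coefficients

    def state(self) -> dict:
        return {f"level{l}": c.numpy().copy()
                for l, c in enumerate(self.coefficients)}

    def load_state(self, state: dict):
        for l, c in enumerate(self.coefficients):
            c.data = np.asarray(state[f"level{l}"], dtype=c.data.dtype)


# ---------------------------------------------------------------------------
# differentiable primitives
# ---------------------------------------------------------------------------

def _spline_field_t(coefs: Tensor, Bx: np.ndarray, By: np.ndarray,
                    Bz: np.ndarray) -> Tensor:
    """Dense (3, nx, ny, nz) field from (3, na, nb, nc) coefficients."""
    dt = coefs.data.dtype
    Bx, By, Bz = (B.astype(dt) for B in (Bx, By, Bz))

    def fwd(C):
        t = np.tensordot(C, Bx, axes=([1], [1]))      # (3, nb, nc, nx)
        t = np.tensordot(t, By, axes=([1], [1]))      # (3, nc, nx, ny)
        t = np.tensordot(t, Bz, axes=([1], [1]))      # (3, nx, ny, nz)
        return t

    def back(g):
        t = np.tensordot(g, Bx, axes=([1], [0]))      # (3, ny, nz, na)
        t = np.tensordot(t, By, axes=([1], [0]))      # (3, nz, na, nb)
        t = np.tensordot(t, Bz, axes=([1], [0]))      # (3, na, nb, nc)
        return (t,)

    return ad.custom(fwd(coefs.data), [coefs], back)


def sample_volume_t(vol: Tensor, coords: Tensor) -> Tensor:
    """Trilinear sample of a 3D tensor at (N,3) voxel-unit coordinates.

    Differentiable w.r.t. both the grid values and the coordinates
    (coordinate gradients vanish where sampling clamps at the border).
    """
    cdata = np.ascontiguousarray(coords.data, dtype=vol.data.dtype)
    out = np.empty(cdata.shape[0], dtype=vol.data.dtype)
    K.tri_gather(vol.data, cdata, out)

    def back(g):
        g = np.ascontiguousarray(g, dtype=vol.data.dtype)
        gvol = gcoords = None
        if vol.requires_grad:
            gvol = np.zeros_like(vol.data)
            K.tri_scatter(gvol, cdata, g)
        if coords.requires_grad:
            gcoords = np.empty_like(cdata)
            K.tri_coord_grad(vol.data, cdata, g, gcoords)
        return gvol, gcoords

    return ad.custom(out, [vol, coords], back)


def evaluate_basis_t(basis: MotionBasisSet, grid: VolumeGrid) -> Tensor:
    """All nine dense fields e_{i,k} stacked as (3 levels, 3 dirs, nx, ny, nz)."""
    mats = basis.design_matrices(grid)
    fields = [_spline_field_t(basis.coefficients[l], *mats[l])
              for l in range(basis.n_levels)]
    return ad.stack(fields, axis=0)


def compose_dvf_t(scores: Tensor, fields: Tensor, n_voxels: int) -> Tensor:
    """Batch DVF composition: scores (Nb,3,3) x fields (3,3,...) -> (Nb,Nvox,3)."""
    per_dir = []
    for k in range(3):
        wk = scores[:, :, k]                       # (Nb, 3)
        ek = fields[:, k].reshape(3, n_voxels)     # (3, Nvox)
        per_dir.append(wk @ ek)                    # (Nb, Nvox)
    return ad.stack(per_dir, axis=-1)              # (Nb, Nvox, 3)


_BASE_VOX_CACHE: dict = {}


def base_voxel_coords(grid: VolumeGrid, dtype=np.float32) -> np.ndarray:
    """Voxel-unit coordinates of all voxel centers (cached, read-only)."""
    key = (grid.shape, grid.spacing, grid.origin, np.dtype(dtype).str)
    cached = _BASE_VOX_CACHE.get(key)
    if cached is None:
        base = grid.voxel_centers()
        cached = ((base - np.asarray(grid.origin))
                  / np.asarray(grid.spacing)).astype(dtype)
        cached.setflags(write=False)
        if len(_BASE_VOX_CACHE) > 16:
            _BASE_VOX_CACHE.clear()
        _BASE_VOX_CACHE[key] = cached
    return cached


def warp_tensor(vol: Tensor, disp: Tensor, grid: VolumeGrid) -> Tensor:
    """Differentiable pull-back warp: out(x) = vol(x + disp(x))."""
    base_vox = base_voxel_coords(grid, vol.data.dtype)
    inv_sp = (1.0 / np.asarray(grid.spacing)).astype(vol.data.dtype)
    coords = disp.reshape(grid.n_voxels, 3) * inv_sp + Tensor(base_vox)
    out = sample_volume_t(vol, coords)
    return out.reshape(grid.shape)


# ---------------------------------------------------------------------------
# public (numpy) operations
# ---------------------------------------------------------------------------

def evaluate_basis(basis: MotionBasisSet, grid: VolumeGrid) -> np.ndarray:
    """Dense MBC fields, shape (3 levels, 3 directions, nx, ny, nz)."""
    with ad.no_grad():
        return evaluate_basis_t(basis, grid).numpy()


def compose_dvf(scores: MBCScores | np.ndarray, basis: MotionBasisSet,
                grid: VolumeGrid, fields: np.ndarray | None = None) -> DVF:
    """Score-weighted sum of the MBC fields (linear in the scores)."""
    if not isinstance(scores, MBCScores):
        scores = MBCScores(np.asarray(scores))
    if fields is None:
        fields = evaluate_basis(basis, grid)
    disp = np.einsum("ik,ik...->...k", scores.w.astype(fields.dtype), fields)
    return DVF(disp, grid.spacing, grid.origin)


def _check_same_grid(volume: VolumeGrid, dvf: DVF):
    if volume.shape != dvf.shape or \
            not np.allclose(volume.spacing, dvf.spacing) or \
            not np.allclose(volume.origin, dvf.origin):
        raise ValueError("volume and DVF grids do not match")


def warp_volume(volume: VolumeGrid, dvf: DVF) -> VolumeGrid:
    """out(x) = volume(x + d(x)), trilinear, border-clamped."""
    _check_same_grid(volume, dvf)
    with ad.no_grad():
        out = warp_tensor(Tensor(volume.data),
                          Tensor(dvf.displacement.astype(volume.data.dtype,
                                                         copy=False)),
                          volume)
    return volume.like(out.numpy())


def _sample_dvf(disp: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Trilinear sample of a vector field at (N,3) voxel-unit coords."""
    out = np.empty((coords_vox.shape[0], 3), dtype=disp.dtype)
    c = np.ascontiguousarray(coords_vox, dtype=disp.dtype)
    for k in range(3):
        K.tri_gather(np.ascontiguousarray(disp[..., k]), c, out[:, k])
    return out


def invert_dvf(dvf: DVF, iterations: int = 3,
               return_residual: bool = False):
    """Fixed-point inverse: d_inv <- -d(x + d_inv(x)), starting from zero.

    Divergence is reported through the residual diagnostic, not raised.
    """
    grid = VolumeGrid(np.empty(dvf.shape, dtype=np.uint8), dvf.spacing, dvf.origin)
    base = grid.voxel_centers().astype(dvf.displacement.dtype)
    sp = np.asarray(dvf.spacing, dtype=dvf.displacement.dtype)
    org = np.asarray(dvf.origin, dtype=dvf.displacement.dtype)
    disp = dvf.displacement
    dinv = np.zeros_like(base)
    for _ in range(max(iterations, 0)):
        coords = (base + dinv - org) / sp
        dinv = -_sample_dvf(disp, coords)
    out = DVF(dinv.reshape(dvf.shape + (3,)), dvf.spacing, dvf.origin)
    if return_residual:
        coords = (base + dinv - org) / sp
        res = _sample_dvf(disp, coords) + dinv
        return out, float(np.mean(np.linalg.norm(res, axis=1)))
    return out


def dvf_inversion_residual(dvf: DVF, inverse: DVF) -> float:
    """Mean |d(x + d_inv(x)) + d_inv(x)| in mm."""
    grid = VolumeGrid(np.empty(dvf.shape, dtype=np.uint8), dvf.spacing, dvf.origin)
    base = grid.voxel_centers().astype(dvf.displacement.dtype)
    sp = np.asarray(dvf.spacing, dtype=dvf.displacement.dtype)
    org = np.asarray(dvf.origin, dtype=dvf.displacement.dtype)
    dinv = inverse.displacement.reshape(-1, 3)
    coords = (base + dinv - org) / sp
    res = _sample_dvf(dvf.displacement, coords) + dinv
    return float(np.mean(np.linalg.norm(res, axis=1)))
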