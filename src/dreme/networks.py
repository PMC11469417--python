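"""Trainable networks: the spatial coordinate network and the motion encoder.

The reference volume is a coordinate network ("spatial INR"): normalized 3D
positions pass through a multiresolution learnable hash encoding and a small
MLP that outputs one non-negative attenuation value (softplus head).  The
motion encoder is a six-layer strided CNN that maps a single preprocessed
x-ray projection to the nine MBC scores.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from . import _autodiff as ad
from . import _kernels as K
from ._autodiff import Tensor
from .geometry import VolumeGrid
from .motion import MBCScores

_HASH_PRIMES = np.array([1, 2654435761, 805459861], dtype=np.uint32)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_std: float | None = None):
        std = np.sqrt(2.0 / n_in) if w_std is None else w_std
        self.W = Tensor(rng.normal(0.0, std, (n_in, n_out)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor, relu: bool = False) -> Tensor:
        """Fused x @ W + b (optionally + ReLU): one graph node, the
        activation mask is recovered from the output in backward."""
        xd, Wd = x.data, self.W.data
        y = xd @ Wd
        y += self.b.data
        if relu:
            np.maximum(y, 0.0, out=y)

        def back(g):
            if relu:
                g = g * (y > 0)
            else:
                g = np.ascontiguousarray(g)
            return g @ Wd.T, xd.T @ g, g.sum(axis=0)

        return ad.custom(y, [x, self.W, self.b], back)

    def parameters(self):
        return [self.W, self.b]


class Conv2d:
    """3x3 convolution, padding 1, configurable stride."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 2):
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = Tensor(rng.normal(0.0, std, (c_out, c_in, 3, 3)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        n, ci, h, w = x.shape
        oh = (h + 2 - 3) // self.stride + 1
        ow = (w + 2 - 3) // self.stride + 1
        out = np.zeros((n, self.W.shape[0], oh, ow), dtype=np.float32)
        K.conv2d_fwd(x.data, self.W.data, self.b.data, out, self.stride)

        xd, Wd, stride = x.data, self.W.data, self.stride

        def back(g):
            g = np.ascontiguousarray(g, dtype=np.float32)
            gx = np.zeros_like(xd)
            gw = np.zeros_like(Wd)
            gb = np.zeros(Wd.shape[0], dtype=np.float32)
            K.conv2d_bwd(xd, Wd, g, gx, gw, gb, stride)
            return gx, gw, gb

        return ad.custom(out, [x, self.W, self.b], back)

    def parameters(self):
        return [self.W, self.b]


class BatchNorm2d:
    """Standard batch normalization; running statistics are used in eval mode."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = (0, 2, 3)
        if training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean = self.running_mean
            var = self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
        out = xhat * self.gamma.data[None, :, None, None] \
            + self.beta.data[None, :, None, None]
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        gamma = self.gamma

        def back(g):
            gbeta = g.sum(axis=axes)
            ggamma = (g * xhat).sum(axis=axes)
            gs = gamma.data[None, :, None, None] / std[None, :, None, None]
            if training:
                gx = gs * (g
                           - gbeta[None, :, None, None] / m
                           - xhat * ggamma[None, :, None, None] / m)
            else:
                gx = gs * g
            return gx, ggamma, gbeta

        return ad.custom(out, [x, self.gamma, self.beta], back)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def load_state(self, s):
        self.running_mean = np.asarray(s["running_mean"], dtype=np.float32)
        self.running_var = np.asarray(s["running_var"], dtype=np.float32)


# ---------------------------------------------------------------------------
# hash-encoded coordinate network
# ---------------------------------------------------------------------------

class HashEncoder:
    """Multiresolution learnable hash encoding of normalized 3D coordinates."""

    def __init__(self, rng: np.random.Generator, n_levels: int = 12,
                 n_features: int = 2, log2_table: int = 19,
                 base_resolution: int = 8, growth: float = 1.38):
        self.n_levels = n_levels
        self.n_features = n_features
        self.table_size = 1 << log2_table
        self.resolutions = [max(int(np.floor(base_resolution * growth ** l)), 1)
                            for l in range(n_levels)]
        self.tables = [
            Tensor(rng.uniform(-1e-4, 1e-4,
                               (self.table_size, n_features)).astype(np.float32),
                   requires_grad=True)
            for _ in range(n_levels)]

    @property
    def n_outputs(self) -> int:
        return self.n_levels * self.n_features

    def precompute(self, coords01: np.ndarray):
        """Corner indices and trilinear weights for a fixed query set."""
        coords01 = np.clip(coords01, 0.0, 1.0)
        out = []
        offs = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                        dtype=np.int64)
        for res in self.resolutions:
            pos = coords01 * res
            c0 = np.minimum(np.floor(pos), res - 1).astype(np.int64)
            frac = (pos - c0).astype(np.float32)
            corners = c0[:, None, :] + offs[None, :, :]            # (N,8,3)
            w = np.ones((coords01.shape[0], 8), dtype=np.float32)
            for ax in range(3):
                f = frac[:, ax][:, None]
                w = w * np.where(offs[None, :, ax] == 1, f, 1.0 - f)
            n_side = res + 1
            if n_side ** 3 <= self.table_size:
                idx = (corners[..., 0] * n_side + corners[..., 1]) * n_side \
                    + corners[..., 2]
            else:
                cu = corners.astype(np.uint32)
                idx = (cu[..., 0] * _HASH_PRIMES[0]
                       ^ cu[..., 1] * _HASH_PRIMES[1]
                       ^ cu[..., 2] * _HASH_PRIMES[2]) % np.uint32(self.table_size)
                idx = idx.astype(np.int64)
            out.append((np.ascontiguousarray(idx),
                        np.ascontiguousarray(w)))
        return out

    def forward(self, precomp) -> Tensor:
        feats = []
        for table, (idx, w) in zip(self.tables, precomp):
            data = np.empty((idx.shape[0], self.n_features), dtype=np.float32)
            K.emb_gather(table.data, idx, w, data)

            def back(g, idx=idx, w=w, table=table):
                gt = np.zeros_like(table.data)
                K.emb_scatter(idx, w, np.ascontiguousarray(g, np.float32), gt)
                return (gt,)

            feats.append(ad.custom(data, [table], back))
        return ad.concat(feats, axis=1)

    def parameters(self):
        return self.tables

    def state(self):
        return {f"table{l}": t.numpy().copy() for l, t in enumerate(self.tables)}

    def load_state(self, s):
        for l, t in enumerate(self.tables):
            t.data = np.asarray(s[f"table{l}"], dtype=np.float32)


class SpatialINR:
    """Continuous reference-volume representation Iref(x).

    Coordinates are normalized to [0,1]^3 over `bounds` (world mm).  The MLP
    head ends in a softplus so rendered attenuation is non-negative.
    """

    def __init__(self, bounds_lo, bounds_hi, rng: np.random.Generator,
                 n_levels: int = 12, n_features: int = 2, log2_table: int = 19,
                 base_resolution: int = 8, growth: float = 1.38,
                 hidden: int = 64, n_hidden: int = 2,
                 output_scale: float = 0.01):
        self.bounds_lo = np.asarray(bounds_lo, dtype=np.float64)
        self.bounds_hi = np.asarray(bounds_hi, dtype=np.float64)
        self.output_scale = float(output_scale)
        self.encoder = HashEncoder(rng, n_levels, n_features, log2_table,
                                   base_resolution, growth)
        dims = [self.encoder.n_outputs] + [hidden] * n_hidden + [1]
        self.layers = [Linear(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]
        self._precomp_cache: dict = {}

    def parameters(self):
        return self.encoder.parameters() + [p for l in self.layers
                                            for p in l.parameters()]

    def normalize(self, pts_world: np.ndarray) -> np.ndarray:
        span = self.bounds_hi - self.bounds_lo
        return ((pts_world - self.bounds_lo) / span).astype(np.float32)

    def _grid_precomp(self, grid: VolumeGrid):
        key = (grid.shape, grid.spacing, grid.origin)
        if key not in self._precomp_cache:
            pts = grid.voxel_centers()
            u = self.normalize(pts)
            if u.min() < -1e-6 or u.max() > 1 + 1e-6:
                raise ValueError("grid outside the coordinate network bounds")
            self._precomp_cache[key] = self.encoder.precompute(u)
        return self._precomp_cache[key]

    def forward_precomp(self, precomp) -> Tensor:
        h = self.encoder.forward(precomp)
        for layer in self.layers[:-1]:
            h = layer(h, relu=True)
        # scale after the softplus so the untrained head starts near
        # soft-tissue attenuation (~0.007 mm^-1) rather than ~0.7
        return self.layers[-1](h).softplus() * self.output_scale

    def render_t(self, grid: VolumeGrid, subset: np.ndarray | None = None) -> Tensor:
        """Differentiable render; optionally only at `subset` voxel indices."""
        precomp = self._grid_precomp(grid)
        if subset is not None:
            precomp = [(idx[subset], w[subset]) for idx, w in precomp]
            return self.forward_precomp(precomp).reshape(subset.size)
        return self.forward_precomp(precomp).reshape(grid.shape)

    def state(self):
        s = self.encoder.state()
        for i, l in enumerate(self.layers):
            s[f"W{i}"] = l.W.numpy().copy()
            s[f"b{i}"] = l.b.numpy().copy()
        return s

    def load_state(self, s):
        self.encoder.load_state(s)
        for i, l in enumerate(self.layers):
            l.W.data = np.asarray(s[f"W{i}"], dtype=np.float32)
            l.b.data = np.asarray(s[f"b{i}"], dtype=np.float32)


def render_volume(inr: SpatialINR, grid: VolumeGrid) -> VolumeGrid:
    """Query the coordinate network at every voxel center of `grid`."""
    with ad.no_grad():
        data = inr.render_t(grid).numpy()
    return grid.like(data)


# ---------------------------------------------------------------------------
# CNN motion encoder
# ---------------------------------------------------------------------------

class MotionEncoderCNN:
    """Six 3x3 conv layers (2,4,8,16,32,32 channels) + BN + ReLU, then a
    single linear layer with nine outputs (the MBC scores)."""

    CHANNELS = (2, 4, 8, 16, 32, 32)

    def __init__(self, rng: np.random.Generator,
                 input_size: tuple[int, int] = (96, 128), verbose: bool = True):
        self.input_size = tuple(input_size)  # (rows=v, cols=u)
        chans = (1,) + self.CHANNELS
        self.convs = [Conv2d(chans[i], chans[i + 1], rng, stride=2)
                      for i in range(6)]
        self.bns = [BatchNorm2d(c) for c in self.CHANNELS]
        h, w = self.input_size
        for _ in range(6):
            h = (h + 2 - 3) // 2 + 1
            w = (w + 2 - 3) // 2 + 1
        self.flat_features = self.CHANNELS[-1] * h * w
        self.fc = Linear(self.flat_features, 9, rng, w_std=1e-3)
        n_par = sum(int(np.prod(p.shape)) for p in self.parameters())
        self.n_parameters = n_par
        if verbose:
            print(f"MotionEncoderCNN: {n_par} parameters "
                  f"(input {self.input_size[0]}x{self.input_size[1]})")

    def parameters(self):
        ps = []
        for c in self.convs:
            ps += c.parameters()
        for b in self.bns:
            ps += b.parameters()
        ps += self.fc.parameters()
        return ps

    def forward_t(self, x: Tensor, training: bool) -> Tensor:
        """x: (N, 1, H, W) preprocessed frames -> (N, 9) scores."""
        h = x
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h), training).relu()
        h = h.reshape(h.shape[0], self.flat_features)
        return self.fc(h)

    def encode(self, frames: np.ndarray, training: bool = False) -> np.ndarray:
        """Plain-numpy batch encoding of preprocessed (N,H,W) frames."""
        with ad.no_grad():
            out = self.forward_t(Tensor(frames[:, None].astype(np.float32)),
                                 training)
        return out.numpy().astype(np.float64)

    def state(self):
        s = {}
        for i, c in enumerate(self.convs):
            s[f"convW{i}"] = c.W.numpy().copy()
            s[f"convb{i}"] = c.b.numpy().copy()
        for i, b in enumerate(self.bns):
            s[f"bn_gamma{i}"] = b.gamma.numpy().copy()
            s[f"bn_beta{i}"] = b.beta.numpy().copy()
            s[f"bn_mean{i}"] = b.running_mean.copy()
            s[f"bn_var{i}"] = b.running_var.copy()
        s["fcW"] = self.fc.W.numpy().copy()
        s["fcb"] = self.fc.b.numpy().copy()
        return s

    def load_state(self, s):
        for i, c in enumerate(self.convs):
            c.W.data = np.asarray(s[f"convW{i}"], np.float32)
            c.b.data = np.asarray(s[f"convb{i}"], np.float32)
        for i, b in enumerate(self.bns):
            b.gamma.data = np.asarray(s[f"bn_gamma{i}"], np.float32)
            b.beta.data = np.asarray(s[f"bn_beta{i}"], np.float32)
            b.running_mean = np.asarray(s[f"bn_mean{i}"], np.float32)
            b.running_var = np.asarray(s[f"bn_var{i}"], np.float32)
        self.fc.W.data = np.asarray(s["fcW"], np.float32)
        self.fc.b.data = np.asarray(s["fcb"], np.float32)


def preprocess_frame(frame: np.ndarray, input_size: tuple[int, int],
                     norm: float) -> np.ndarray:
    """Resize a projection to the fixed CNN input size and scale intensities.

    `norm` is the per-scan maximum frozen at training time.
    """
    frame = np.asarray(frame, dtype=np.float32)
    if not np.all(np.isfinite(frame)):
        raise ValueError("projection contains non-finite values")
    if frame.shape != tuple(input_size):
        frame = _sk_resize(frame, input_size, order=1, preserve_range=True,
                           anti_aliasing=False).astype(np.float32)
    return frame / max(norm, 1e-12)


def encode_projection(cnn: MotionEncoderCNN, frame: np.ndarray) -> MBCScores:
    """Nine MBC scores from one preprocessed projection (eval mode)."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.shape != cnn.input_size:
        raise ValueError(f"frame must be preprocessed to {cnn.input_size}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    out = cnn.encode(frame[None])
    return MBCScores(out[0].reshape(3, 3))
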