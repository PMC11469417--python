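"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plainly as possible (explicit loops, no shared
code with the package's numerics) so it can serve as an independent check.
"""

from __future__ import annotations

import numpy as np


# -- sampling / projection --------------------------------------------------

def trilinear(vol: np.ndarray, p: np.ndarray) -> float:
    """Border-clamped trilinear interpolation at one voxel-unit coordinate."""
    nx, ny, nz = vol.shape
    cx = min(max(p[0], 0.0), nx - 1.0)
    cy = min(max(p[1], 0.0), ny - 1.0)
    cz = min(max(p[2], 0.0), nz - 1.0)
    x0 = min(int(cx), nx - 2) if nx > 1 else 0
    y0 = min(int(cy), ny - 2) if ny > 1 else 0
    z0 = min(int(cz), nz - 2) if nz > 1 else 0
    fx, fy, fz = cx - x0, cy - y0, cz - z0
    acc = 0.0
    for dx_ in (0, 1):
        for dy_ in (0, 1):
            for dz_ in (0, 1):
                w = ((fx if dx_ else 1 - fx) * (fy if dy_ else 1 - fy)
                     * (fz if dz_ else 1 - fz))
                acc += w * vol[x0 + dx_, y0 + dy_, z0 + dz_]
    return acc


def _ray_box(src, direction, lo, hi):
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        d = direction[ax]
        if abs(d) < 1e-12:
            if src[ax] < lo[ax] or src[ax] > hi[ax]:
                return 1.0, 0.0
            continue
        ta, tb = (lo[ax] - src[ax]) / d, (hi[ax] - src[ax]) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
    return t0, t1


def dense_ray_integral(volume, src, dst, step: float) -> float:
    """Very fine midpoint-rule line integral, trilinear sampling (mm units)."""
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(volume.data.shape) - 0.5) * spacing
    d = np.asarray(dst, float) - np.asarray(src, float)
    length = np.linalg.norm(d)
    d = d / length
    t0, t1 = _ray_box(np.asarray(src, float), d, lo, hi)
    if t1 <= t0:
        return 0.0
    n = int(np.ceil((t1 - t0) / step))
    ts = t0 + (np.arange(n) + 0.5) * (t1 - t0) / n
    acc = 0.0
    for t in ts:
        p = (np.asarray(src) + t * d - origin) / spacing
        acc += trilinear(volume.data, p)
    return acc * (t1 - t0) / n


def siddon_path_lengths(volume, src, dst) -> float:
    """Classic Siddon ray tracing: exact path-length-weighted sum over a
    piecewise-constant voxel volume (voxel boundaries at half-spacings)."""
    shape = np.asarray(volume.data.shape)
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    lo = origin - 0.5 * spacing
    src = np.asarray(src, float)
    d = np.asarray(dst, float) - src
    length = np.linalg.norm(d)
    u = d / length
    hi = lo + shape * spacing
    t0, t1 = _ray_box(src, u, lo, hi)
    if t1 <= t0:
        return 0.0
    t0, t1 = max(t0, 0.0), min(t1, length)
    # all plane crossings
    ts = [t0, t1]
    for ax in range(3):
        if abs(u[ax]) < 1e-12:
            continue
        for i in range(shape[ax] + 1):
            t = (lo[ax] + i * spacing[ax] - src[ax]) / u[ax]
            if t0 < t < t1:
                ts.append(t)
    ts = np.unique(np.asarray(ts))
    acc = 0.0
    for a, b in zip(ts[:-1], ts[1:]):
        mid = src + 0.5 * (a + b) * u
        idx = np.floor((mid - lo) / spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < shape):
            acc += volume.data[tuple(idx)] * (b - a)
    return acc


# -- losses -----------------------------------------------------------------

def mse_loops(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    s = 0.0
    for x, y in zip(a, b):
        s += (x - y) ** 2
    return s / a.size


def tv_loops(vol: np.ndarray) -> float:
    v = np.asarray(vol, float)
    nx, ny, nz = v.shape
    s = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                dx = v[i + 1, j, k] - v[i, j, k] if i + 1 < nx else 0.0
                dy = v[i, j + 1, k] - v[i, j, k] if j + 1 < ny else 0.0
                dz = v[i, j, k + 1] - v[i, j, k] if k + 1 < nz else 0.0
                s += np.sqrt(dx * dx + dy * dy + dz * dz)
    return s / v.size


def mbc_loops(fields: np.ndarray) -> float:
    """fields: (3 levels, 3 dirs, nx, ny, nz); voxel-mean inner products."""
    f = np.asarray(fields, float)
    n = f[0, 0].size
    total = 0.0
    for k in range(3):
        for i in range(3):
            ei = f[i, k].ravel()
            norm2 = float(ei @ ei) / n
            total += (norm2 - 1.0) ** 2
            for j in range(i + 1, 3):
                ej = f[j, k].ravel()
                total += (float(ei @ ej) / n) ** 2
    return total / 9.0


def zero_mean_loops(scores: np.ndarray) -> float:
    w = np.asarray(scores, float).reshape(-1, 9)
    total = 0.0
    for c in range(9):
        m = 0.0
        for b in range(w.shape[0]):
            m += w[b, c]
        m /= w.shape[0]
        total += m * m
    return total / 9.0


def aug_loss_loops(pred: np.ndarray, tgt: np.ndarray) -> float:
    p = np.asarray(pred, float).reshape(-1, 9)
    t = np.asarray(tgt, float).reshape(-1, 9)
    s = 0.0
    for b in range(p.shape[0]):
        for c in range(9):
            s += (p[b, c] - t[b, c]) ** 2
    return s / (9.0 * p.shape[0])


def relative_error_loops(est: np.ndarray, truth: np.ndarray) -> float:
    e = np.asarray(est, float)
    t = np.asarray(truth, float)
    if e.ndim == 3:
        e, t = e[None], t[None]
    total = 0.0
    for f in range(e.shape[0]):
        num = np.sqrt(((e[f] - t[f]) ** 2).sum())
        den = np.sqrt((t[f] ** 2).sum())
        total += num / den
    return total / e.shape[0]


def dsc_loops(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


def come_loops(a: np.ndarray, b: np.ndarray, spacing) -> float:
    sp = np.asarray(spacing, float)
    ca = np.argwhere(np.asarray(a) > 0).mean(axis=0) * sp
    cb = np.argwhere(np.asarray(b) > 0).mean(axis=0) * sp
    return float(np.sqrt(((ca - cb) ** 2).sum()))


def pearson_textbook(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    return float((n * sxy - sx * sy)
                 / np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2)))
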