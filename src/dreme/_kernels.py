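"""Numba kernels for the sampling-heavy inner loops.

Array layout conventions used throughout:
  * volumes are indexed ``vol[ix, iy, iz]`` with x=LR, y=AP, z=SI;
  * continuous coordinates are in *voxel index units* (0 .. n-1);
  * sampling is trilinear with border clamping, i.e. the field is extended
    piecewise-constant half a voxel beyond the outermost voxel centers.

The cone-beam forward/adjoint pair is an exact matrix transpose: both loops
visit identical sample points with identical weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange  # noqa: F401  (prange kept for optional parallel builds)

F = {"cache": True, "fastmath": True}


@njit(**F)
def tri_gather(vol, coords, out):
    nx, ny, nz = vol.shape
    n = coords.shape[0]
    for i in range(n):
        cx = min(max(coords[i, 0], 0.0), nx - 1.0)
        cy = min(max(coords[i, 1], 0.0), ny - 1.0)
        cz = min(max(coords[i, 2], 0.0), nz - 1.0)
        x0 = int(cx); y0 = int(cy); z0 = int(cz)
        if x0 == nx - 1: x0 -= 1
        if y0 == ny - 1: y0 -= 1
        if z0 == nz - 1: z0 -= 1
        if x0 < 0: x0 = 0
        if y0 < 0: y0 = 0
        if z0 < 0: z0 = 0
        fx = cx - x0; fy = cy - y0; fz = cz - z0
        c000 = vol[x0, y0, z0]; c100 = vol[x0 + 1, y0, z0]
        c010 = vol[x0, y0 + 1, z0]; c110 = vol[x0 + 1, y0 + 1, z0]
        c001 = vol[x0, y0, z0 + 1]; c101 = vol[x0 + 1, y0, z0 + 1]
        c011 = vol[x0, y0 + 1, z0 + 1]; c111 = vol[x0 + 1, y0 + 1, z0 + 1]
        c00 = c000 * (1 - fx) + c100 * fx
        c10 = c010 * (1 - fx) + c110 * fx
        c01 = c001 * (1 - fx) + c101 * fx
        c11 = c011 * (1 - fx) + c111 * fx
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        out[i] = c0 * (1 - fz) + c1 * fz


@njit(**F)
def tri_scatter(gvol, coords, gout):
    """Adjoint of tri_gather: accumulate gout back onto the grid."""
    nx, ny, nz = gvol.shape
    n = coords.shape[0]
    for i in range(n):
        g = gout[i]
        if g == 0.0:
            continue
        cx = min(max(coords[i, 0], 0.0), nx - 1.0)
        cy = min(max(coords[i, 1], 0.0), ny - 1.0)
        cz = min(max(coords[i, 2], 0.0), nz - 1.0)
        x0 = int(cx); y0 = int(cy); z0 = int(cz)
        if x0 == nx - 1: x0 -= 1
        if y0 == ny - 1: y0 -= 1
        if z0 == nz - 1: z0 -= 1
        if x0 < 0: x0 = 0
        if y0 < 0: y0 = 0
        if z0 < 0: z0 = 0
        fx = cx - x0; fy = cy - y0; fz = cz - z0
        gvol[x0, y0, z0] += g * (1 - fx) * (1 - fy) * (1 - fz)
        gvol[x0 + 1, y0, z0] += g * fx * (1 - fy) * (1 - fz)
        gvol[x0, y0 + 1, z0] += g * (1 - fx) * fy * (1 - fz)
        gvol[x0 + 1, y0 + 1, z0] += g * fx * fy * (1 - fz)
        gvol[x0, y0, z0 + 1] += g * (1 - fx) * (1 - fy) * fz
        gvol[x0 + 1, y0, z0 + 1] += g * fx * (1 - fy) * fz
        gvol[x0, y0 + 1, z0 + 1] += g * (1 - fx) * fy * fz
        gvol[x0 + 1, y0 + 1, z0 + 1] += g * fx * fy * fz


@njit(**F)
def tri_coord_grad(vol, coords, gout, gcoords):
    """d(gather)/d(coords), zero where the coordinate was clamped."""
    nx, ny, nz = vol.shape
    n = coords.shape[0]
    for i in range(n):
        g = gout[i]
        inx = 1.0 if (coords[i, 0] > 0.0 and coords[i, 0] < nx - 1.0) else 0.0
        iny = 1.0 if (coords[i, 1] > 0.0 and coords[i, 1] < ny - 1.0) else 0.0
        inz = 1.0 if (coords[i, 2] > 0.0 and coords[i, 2] < nz - 1.0) else 0.0
        cx = min(max(coords[i, 0], 0.0), nx - 1.0)
        cy = min(max(coords[i, 1], 0.0), ny - 1.0)
        cz = min(max(coords[i, 2], 0.0), nz - 1.0)
        x0 = int(cx); y0 = int(cy); z0 = int(cz)
        if x0 == nx - 1: x0 -= 1
        if y0 == ny - 1: y0 -= 1
        if z0 == nz - 1: z0 -= 1
        if x0 < 0: x0 = 0
        if y0 < 0: y0 = 0
        if z0 < 0: z0 = 0
        fx = cx - x0; fy = cy - y0; fz = cz - z0
        c000 = vol[x0, y0, z0]; c100 = vol[x0 + 1, y0, z0]
        c010 = vol[x0, y0 + 1, z0]; c110 = vol[x0 + 1, y0 + 1, z0]
        c001 = vol[x0, y0, z0 + 1]; c101 = vol[x0 + 1, y0, z0 + 1]
        c011 = vol[x0, y0 + 1, z0 + 1]; c111 = vol[x0 + 1, y0 + 1, z0 + 1]
        dx = ((c100 - c000) * (1 - fy) + (c110 - c010) * fy) * (1 - fz) + \
             ((c101 - c001) * (1 - fy) + (c111 - c011) * fy) * fz
        dy = ((c010 - c000) * (1 - fx) + (c110 - c100) * fx) * (1 - fz) + \
             ((c011 - c001) * (1 - fx) + (c111 - c101) * fx) * fz
        dz = ((c001 - c000) * (1 - fx) + (c101 - c100) * fx) * (1 - fy) + \
             ((c011 - c010) * (1 - fx) + (c111 - c110) * fx) * fy
        gcoords[i, 0] = g * dx * inx
        gcoords[i, 1] = g * dy * iny
        gcoords[i, 2] = g * dz * inz


@njit(**F)
def _ray_box(px, py, pz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    """Slab intersection of ray p + t*d with an AABB; returns (t0, t1)."""
    t0 = -1.0e30
    t1 = 1.0e30
    for ax in range(3):
        if ax == 0:
            p = px; d = dx; lo = lo0; hi = hi0
        elif ax == 1:
            p = py; d = dy; lo = lo1; hi = hi1
        else:
            p = pz; d = dz; lo = lo2; hi = hi2
        if abs(d) < 1e-12:
            if p < lo or p > hi:
                return 1.0, 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0: t0 = ta
            if tb < t1: t1 = tb
    return t0, t1


@njit(**F)
def cone_fp(vol, spacing, origin, src, det00, ustep, vstep, nu, nv, step, out):
    """Cone-beam forward projection (line integrals, mm^-1 * mm).

    det00 is the world position of detector pixel (v=0, u=0); ustep/vstep are
    the world-space pixel steps.  Midpoint rule with an integer number of
    steps per ray so that the companion adjoint is an exact transpose.
    """
    nx, ny, nz = vol.shape
    lo0 = origin[0] - 0.5 * spacing[0]
    lo1 = origin[1] - 0.5 * spacing[1]
    lo2 = origin[2] - 0.5 * spacing[2]
    hi0 = origin[0] + (nx - 0.5) * spacing[0]
    hi1 = origin[1] + (ny - 0.5) * spacing[1]
    hi2 = origin[2] + (nz - 0.5) * spacing[2]
    for iv in range(nv):
        for iu in range(nu):
            px = det00[0] + iu * ustep[0] + iv * vstep[0]
            py = det00[1] + iu * ustep[1] + iv * vstep[1]
            pz = det00[2] + iu * ustep[2] + iv * vstep[2]
            dx = px - src[0]; dy = py - src[1]; dz = pz - src[2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= norm; dy /= norm; dz /= norm
            t0, t1 = _ray_box(src[0], src[1], src[2], dx, dy, dz,
                              lo0, lo1, lo2, hi0, hi1, hi2)
            acc = 0.0
            if t1 > t0:
                length = t1 - t0
                nsteps = int(length / step) + 1
                ds = length / nsteps
                for j in range(nsteps):
                    t = t0 + (j + 0.5) * ds
                    wx = src[0] + t * dx
                    wy = src[1] + t * dy
                    wz = src[2] + t * dz
                    cx = (wx - origin[0]) / spacing[0]
                    cy = (wy - origin[1]) / spacing[1]
                    cz = (wz - origin[2]) / spacing[2]
                    cx = min(max(cx, 0.0), nx - 1.0)
                    cy = min(max(cy, 0.0), ny - 1.0)
                    cz = min(max(cz, 0.0), nz - 1.0)
                    x0 = int(cx); y0 = int(cy); z0 = int(cz)
                    if x0 == nx - 1: x0 -= 1
                    if y0 == ny - 1: y0 -= 1
                    if z0 == nz - 1: z0 -= 1
                    fx = cx - x0; fy = cy - y0; fz = cz - z0
                    c00 = vol[x0, y0, z0] * (1 - fx) + vol[x0 + 1, y0, z0] * fx
                    c10 = vol[x0, y0 + 1, z0] * (1 - fx) + vol[x0 + 1, y0 + 1, z0] * fx
                    c01 = vol[x0, y0, z0 + 1] * (1 - fx) + vol[x0 + 1, y0, z0 + 1] * fx
                    c11 = vol[x0, y0 + 1, z0 + 1] * (1 - fx) + vol[x0 + 1, y0 + 1, z0 + 1] * fx
                    acc += ((c00 * (1 - fy) + c10 * fy) * (1 - fz) +
                            (c01 * (1 - fy) + c11 * fy) * fz) * ds
            out[iv, iu] = acc


@njit(**F)
def cone_bp(gvol, spacing, origin, src, det00, ustep, vstep, nu, nv, step, gout):
    """Exact adjoint of cone_fp: scatter projection grads along the rays."""
    nx, ny, nz = gvol.shape
    lo0 = origin[0] - 0.5 * spacing[0]
    lo1 = origin[1] - 0.5 * spacing[1]
    lo2 = origin[2] - 0.5 * spacing[2]
    hi0 = origin[0] + (nx - 0.5) * spacing[0]
    hi1 = origin[1] + (ny - 0.5) * spacing[1]
    hi2 = origin[2] + (nz - 0.5) * spacing[2]
    for iv in range(nv):
        for iu in range(nu):
            g = gout[iv, iu]
            if g == 0.0:
                continue
            px = det00[0] + iu * ustep[0] + iv * vstep[0]
            py = det00[1] + iu * ustep[1] + iv * vstep[1]
            pz = det00[2] + iu * ustep[2] + iv * vstep[2]
            dx = px - src[0]; dy = py - src[1]; dz = pz - src[2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= norm; dy /= norm; dz /= norm
            t0, t1 = _ray_box(src[0], src[1], src[2], dx, dy, dz,
                              lo0, lo1, lo2, hi0, hi1, hi2)
            if t1 <= t0:
                continue
            length = t1 - t0
            nsteps = int(length / step) + 1
            ds = length / nsteps
            gds = g * ds
            for j in range(nsteps):
                t = t0 + (j + 0.5) * ds
                wx = src[0] + t * dx
                wy = src[1] + t * dy
                wz = src[2] + t * dz
                cx = (wx - origin[0]) / spacing[0]
                cy = (wy - origin[1]) / spacing[1]
                cz = (wz - origin[2]) / spacing[2]
                cx = min(max(cx, 0.0), nx - 1.0)
                cy = min(max(cy, 0.0), ny - 1.0)
                cz = min(max(cz, 0.0), nz - 1.0)
                x0 = int(cx); y0 = int(cy); z0 = int(cz)
                if x0 == nx - 1: x0 -= 1
                if y0 == ny - 1: y0 -= 1
                if z0 == nz - 1: z0 -= 1
                fx = cx - x0; fy = cy - y0; fz = cz - z0
                gvol[x0, y0, z0] += gds * (1 - fx) * (1 - fy) * (1 - fz)
                gvol[x0 + 1, y0, z0] += gds * fx * (1 - fy) * (1 - fz)
                gvol[x0, y0 + 1, z0] += gds * (1 - fx) * fy * (1 - fz)
                gvol[x0 + 1, y0 + 1, z0] += gds * fx * fy * (1 - fz)
                gvol[x0, y0, z0 + 1] += gds * (1 - fx) * (1 - fy) * fz
                gvol[x0 + 1, y0, z0 + 1] += gds * fx * (1 - fy) * fz
                gvol[x0, y0 + 1, z0 + 1] += gds * (1 - fx) * fy * fz
                gvol[x0 + 1, y0 + 1, z0 + 1] += gds * fx * fy * fz


@njit(**F)
def fdk_backproject(vol, spacing, origin, filtered, angles_rad, sad, sdd,
                    du_iso, dv_iso, offset_u_iso, weight):
    """Voxel-driven weighted backprojection onto `vol` (accumulates).

    `filtered` is the stack of ramp-filtered, cosine-weighted projections with
    detector coordinates rescaled to the isocenter plane (pitch du_iso/dv_iso).
    """
    nx, ny, nz = vol.shape
    nproj, nv, nu = filtered.shape
    cu = (nu - 1) / 2.0
    cv = (nv - 1) / 2.0
    for ia in range(nproj):
        beta = angles_rad[ia]
        sb = np.sin(beta)
        cb = np.cos(beta)
        proj = filtered[ia]
        for ix in range(nx):
            wx = origin[0] + ix * spacing[0]
            for iy in range(ny):
                wy = origin[1] + iy * spacing[1]
                # source at angle beta: (-sad*sb, sad*cb); ray axis toward -src
                s = wx * (-sb) + wy * cb          # component along source direction
                tt = wx * cb + wy * sb            # component along detector u axis
                U = sad - s
                if U <= 1.0:
                    continue
                w2 = weight * sad * sad / (U * U)
                u = tt * sad / U                  # isocenter-plane detector coord
                pu = (u - offset_u_iso) / du_iso + cu
                if pu < 0.0 or pu > nu - 1.0:
                    continue
                u0 = int(pu)
                if u0 == nu - 1:
                    u0 -= 1
                fu = pu - u0
                for iz in range(nz):
                    wz = origin[2] + iz * spacing[2]
                    v = wz * sad / U
                    pv = v / dv_iso + cv
                    if pv < 0.0 or pv > nv - 1.0:
                        continue
                    v0 = int(pv)
                    if v0 == nv - 1:
                        v0 -= 1
                    fv = pv - v0
                    val = (proj[v0, u0] * (1 - fu) * (1 - fv) +
                           proj[v0, u0 + 1] * fu * (1 - fv) +
                           proj[v0 + 1, u0] * (1 - fu) * fv +
                           proj[v0 + 1, u0 + 1] * fu * fv)
                    vol[ix, iy, iz] += w2 * val


@njit(**F)
def emb_gather(table, idx, w, out):
    """out[n] = sum_c w[n,c] * table[idx[n,c]]  (hash-encoding forward)."""
    n, ncorner = idx.shape
    nfeat = table.shape[1]
    for i in range(n):
        for f in range(nfeat):
            out[i, f] = 0.0
        for c in range(ncorner):
            j = idx[i, c]
            wc = w[i, c]
            for f in range(nfeat):
                out[i, f] += wc * table[j, f]


@njit(**F)
def emb_scatter(idx, w, gout, gtable):
    """Accumulate hash-table gradients: gtable[idx[n,c]] += w[n,c]*gout[n]."""
    n, ncorner = idx.shape
    nfeat = gout.shape[1]
    for i in range(n):
        for c in range(ncorner):
            j = idx[i, c]
            wc = w[i, c]
            for f in range(nfeat):
                gtable[j, f] += wc * gout[i, f]


@njit(**F)
def conv2d_fwd(x, wgt, bias, out, stride):
    """3x3 conv, padding 1."""
    n, ci, h, w = x.shape
    co = wgt.shape[0]
    oh, ow = out.shape[2], out.shape[3]
    for b in range(n):
        for o in range(co):
            for i in range(oh):
                for j in range(ow):
                    acc = bias[o]
                    i0 = i * stride - 1
                    j0 = j * stride - 1
                    for c in range(ci):
                        for ki in range(3):
                            ii = i0 + ki
                            if ii < 0 or ii >= h:
                                continue
                            for kj in range(3):
                                jj = j0 + kj
                                if jj < 0 or jj >= w:
                                    continue
                                acc += x[b, c, ii, jj] * wgt[o, c, ki, kj]
                    out[b, o, i, j] = acc


@njit(**F)
def conv2d_bwd(x, wgt, gout, gx, gw, gb, stride):
    n, ci, h, w = x.shape
    co = wgt.shape[0]
    oh, ow = gout.shape[2], gout.shape[3]
    for b in range(n):
        for o in range(co):
            for i in range(oh):
                for j in range(ow):
                    g = gout[b, o, i, j]
                    if g == 0.0:
                        continue
                    gb[o] += g
                    i0 = i * stride - 1
                    j0 = j * stride - 1
                    for c in range(ci):
                        for ki in range(3):
                            ii = i0 + ki
                            if ii < 0 or ii >= h:
                                continue
                            for kj in range(3):
                                jj = j0 + kj
                                if jj < 0 or jj >= w:
                                    continue
                                gx[b, c, ii, jj] += g * wgt[o, c, ki, kj]
                                gw[o, c, ki, kj] += g * x[b, c, ii, jj]
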