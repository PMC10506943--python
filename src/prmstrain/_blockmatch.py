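"""Numba kernels: 3D block matching (NCC) and Gaussian scatterer rendering."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def render_gaussians(pos_vox, amp, nx, ny, nz, sx, sy, sz, rx, ry, rz):
    """Sum truncated separable Gaussian contributions of point scatterers.

    ``pos_vox`` are scatterer positions in voxel units, ``s*`` the PSF
    sigma per axis (voxels), ``r*`` the kernel truncation radii.
    """
    img = np.zeros((nx, ny, nz))
    wx = np.empty(2 * rx + 1)
    wy = np.empty(2 * ry + 1)
    wz = np.empty(2 * rz + 1)
    for i in range(pos_vox.shape[0]):
        px, py, pz = pos_vox[i, 0], pos_vox[i, 1], pos_vox[i, 2]
        cx, cy, cz = int(round(px)), int(round(py)), int(round(pz))
        a = amp[i]
        for o in range(-rx, rx + 1):
            d = (cx + o - px) / sx
            wx[o + rx] = np.exp(-0.5 * d * d)
        for o in range(-ry, ry + 1):
            d = (cy + o - py) / sy
            wy[o + ry] = np.exp(-0.5 * d * d)
        for o in range(-rz, rz + 1):
            d = (cz + o - pz) / sz
            wz[o + rz] = np.exp(-0.5 * d * d)
        for ox in range(-rx, rx + 1):
            x = cx + ox
            if x < 0 or x >= nx:
                continue
            axw = a * wx[ox + rx]
            for oy in range(-ry, ry + 1):
                y = cy + oy
                if y < 0 or y >= ny:
                    continue
                axyw = axw * wy[oy + ry]
                for oz in range(-rz, rz + 1):
                    z = cz + oz
                    if z < 0 or z >= nz:
                        continue
                    img[x, y, z] += axyw * wz[oz + rz]
    return img


@njit(cache=True, fastmath=True)
def lk_blocks(vol_a, warped, centers, bx, by, bz):
    """Per-block Lucas-Kanade residual displacement (voxels).

    Solves the local linearized matching problem
    ``vol_a - warped = grad(warped) . delta`` by least squares over each
    block.  Unlike a correlation-peak readout, the estimate is exactly
    zero when the volumes already agree, so iterated warp-and-refine
    converges to the true alignment instead of a pattern-dependent
    offset.  Returns NaN where the normal matrix is ill-conditioned.
    """
    nx, ny, nz = vol_a.shape
    n = centers.shape[0]
    out = np.full((n, 3), np.nan)
    for i in range(n):
        cx, cy, cz = centers[i, 0], centers[i, 1], centers[i, 2]
        x0 = max(cx - bx, 1)
        x1 = min(cx + bx + 1, nx - 1)
        y0 = max(cy - by, 1)
        y1 = min(cy + by + 1, ny - 1)
        z0 = max(cz - bz, 1)
        z1 = min(cz + bz + 1, nz - 1)
        if x1 <= x0 or y1 <= y0 or z1 <= z0:
            continue
        a00 = a01 = a02 = a11 = a12 = a22 = 0.0
        b0 = b1 = b2 = 0.0
        for x in range(x0, x1):
            for y in range(y0, y1):
                for z in range(z0, z1):
                    gx = 0.5 * (warped[x + 1, y, z] - warped[x - 1, y, z])
                    gy = 0.5 * (warped[x, y + 1, z] - warped[x, y - 1, z])
                    gz = 0.5 * (warped[x, y, z + 1] - warped[x, y, z - 1])
                    r = vol_a[x, y, z] - warped[x, y, z]
                    a00 += gx * gx
                    a01 += gx * gy
                    a02 += gx * gz
                    a11 += gy * gy
                    a12 += gy * gz
                    a22 += gz * gz
                    b0 += gx * r
                    b1 += gy * r
                    b2 += gz * r
        det = (
            a00 * (a11 * a22 - a12 * a12)
            - a01 * (a01 * a22 - a12 * a02)
            + a02 * (a01 * a12 - a11 * a02)
        )
        tr = a00 + a11 + a22
        if tr <= 1e-12 or det <= 1e-6 * (tr / 3.0) ** 3:
            continue
        i00 = a11 * a22 - a12 * a12
        i01 = a02 * a12 - a01 * a22
        i02 = a01 * a12 - a02 * a11
        i11 = a00 * a22 - a02 * a02
        i12 = a01 * a02 - a00 * a12
        i22 = a00 * a11 - a01 * a01
        dx = (i00 * b0 + i01 * b1 + i02 * b2) / det
        dy = (i01 * b0 + i11 * b1 + i12 * b2) / det
        dz = (i02 * b0 + i12 * b1 + i22 * b2) / det
        # one linearized step cannot be trusted beyond ~a voxel
        if dx > 1.5:
            dx = 1.5
        elif dx < -1.5:
            dx = -1.5
        if dy > 1.5:
            dy = 1.5
        elif dy < -1.5:
            dy = -1.5
        if dz > 1.5:
            dz = 1.5
        elif dz < -1.5:
            dz = -1.5
        out[i, 0] = dx
        out[i, 1] = dy
        out[i, 2] = dz
    return out


@njit(cache=True, fastmath=True)
def _peak_offset(cm, c0, cp):
    """Subvoxel offset of a 1D correlation peak from 3 samples.

    Uses the Gaussian estimator on the log-correlations when all three
    values are positive (exact for a Gaussian-shaped peak), otherwise a
    parabolic fit.  Returns 0 when the curvature is not concave or the
    neighbors are missing (sentinel -2)."""
    if cm <= -2.0 or cp <= -2.0:
        return 0.0
    if cm > 1e-4 and c0 > 1e-4 and cp > 1e-4:
        lm = np.log(cm)
        l0 = np.log(c0)
        lp = np.log(cp)
        den = lm - 2.0 * l0 + lp
        if den < -1e-12:
            off = 0.5 * (lm - lp) / den
            if -1.0 < off < 1.0:
                return off
        return 0.0
    den = cm - 2.0 * c0 + cp
    if den < -1e-12:
        off = 0.5 * (cm - cp) / den
        if -1.0 < off < 1.0:
            return off
    return 0.0


@njit(cache=True, fastmath=True)
def match_blocks(vol_a, vol_b, centers, bx, by, bz, sx, sy, sz, subvoxel):
    """Best NCC displacement (voxels) and peak correlation per block center.

    ``b*`` are block half-sizes, ``s*`` search radii.  Blocks are
    truncated at volume borders; a center whose block has more than half
    of its voxels outside the volume is undefined (NaN).  Offsets whose
    shifted block leaves the volume are skipped.  Optional subvoxel
    refinement fits a parabola per axis through the integer peak.
    """
    nx, ny, nz = vol_a.shape
    n = centers.shape[0]
    disp = np.full((n, 3), np.nan)
    qual = np.full(n, np.nan)
    full_block = (2 * bx + 1) * (2 * by + 1) * (2 * bz + 1)
    corr = np.empty((2 * sx + 1, 2 * sy + 1, 2 * sz + 1))

    for i in range(n):
        cx, cy, cz = centers[i, 0], centers[i, 1], centers[i, 2]
        x0 = max(cx - bx, 0)
        x1 = min(cx + bx + 1, nx)
        y0 = max(cy - by, 0)
        y1 = min(cy + by + 1, ny)
        z0 = max(cz - bz, 0)
        z1 = min(cz + bz + 1, nz)
        m = (x1 - x0) * (y1 - y0) * (z1 - z0)
        if m * 2 < full_block:
            continue

        # template statistics
        ta = 0.0
        for x in range(x0, x1):
            for y in range(y0, y1):
                for z in range(z0, z1):
                    ta += vol_a[x, y, z]
        ta /= m
        va = 0.0
        for x in range(x0, x1):
            for y in range(y0, y1):
                for z in range(z0, z1):
                    dvv = vol_a[x, y, z] - ta
                    va += dvv * dvv
        if va < 1e-12:
            continue

        corr[:] = -2.0
        best = -2.0
        bdx = 0
        bdy = 0
        bdz = 0
        for dx in range(-sx, sx + 1):
            if x0 + dx < 0 or x1 + dx > nx:
                continue
            for dy in range(-sy, sy + 1):
                if y0 + dy < 0 or y1 + dy > ny:
                    continue
                for dz in range(-sz, sz + 1):
                    if z0 + dz < 0 or z1 + dz > nz:
                        continue
                    sb = 0.0
                    sbb = 0.0
                    sab = 0.0
                    for x in range(x0, x1):
                        for y in range(y0, y1):
                            for z in range(z0, z1):
                                bv = vol_b[x + dx, y + dy, z + dz]
                                av = vol_a[x, y, z]
                                sb += bv
                                sbb += bv * bv
                                sab += av * bv
                    vb = sbb - sb * sb / m
                    if vb < 1e-12:
                        c = 0.0
                    else:
                        c = (sab - ta * sb) / np.sqrt(va * vb)
                    corr[dx + sx, dy + sy, dz + sz] = c
                    if c > best:
                        best = c
                        bdx = dx
                        bdy = dy
                        bdz = dz
        if best <= -2.0:
            continue

        fx = float(bdx)
        fy = float(bdy)
        fz = float(bdz)
        if subvoxel:
            # per-axis peak interpolation around the integer maximum.
            # Gaussian (log-domain) fit where the three samples are
            # positive: the speckle correlation peak is near-Gaussian, so
            # this strongly reduces peak locking; fall back to a plain
            # parabola otherwise.
            ix, iy, iz = bdx + sx, bdy + sy, bdz + sz
            if 0 < ix < 2 * sx:
                cm = corr[ix - 1, iy, iz]
                cp = corr[ix + 1, iy, iz]
                c0 = corr[ix, iy, iz]
                fx += _peak_offset(cm, c0, cp)
            if 0 < iy < 2 * sy:
                cm = corr[ix, iy - 1, iz]
                cp = corr[ix, iy + 1, iz]
                c0 = corr[ix, iy, iz]
                fy += _peak_offset(cm, c0, cp)
            if 0 < iz < 2 * sz:
                cm = corr[ix, iy, iz - 1]
                cp = corr[ix, iy, iz + 1]
                c0 = corr[ix, iy, iz]
                fz += _peak_offset(cm, c0, cp)

        disp[i, 0] = fx
        disp[i, 1] = fy
        disp[i, 2] = fz
        qual[i] = min(best, 1.0)
    return disp, qual
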