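"""Numba kernels for the node-wise nonlinear registration optimizer.

Each control node carries a candidate world-mm displacement optimized by a
derivative-free Nelder-Mead simplex over the 3 translation components of a
local normalized cross-correlation objective.  Kept separate from the public
registration API so the jitted code stays free of Python objects.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _trilinear(vol, x, y, z):
    """Trilinear sample of ``vol`` at fractional voxel coords, zero outside."""
    nx, ny, nz = vol.shape
    if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1.0 or y > ny - 1.0 or z > nz - 1.0:
        return 0.0
    i0 = int(np.floor(x))
    j0 = int(np.floor(y))
    k0 = int(np.floor(z))
    if i0 == nx - 1:
        i0 -= 1
    if j0 == ny - 1:
        j0 -= 1
    if k0 == nz - 1:
        k0 -= 1
    fx = x - i0
    fy = y - j0
    fz = z - k0
    c00 = vol[i0, j0, k0] * (1 - fx) + vol[i0 + 1, j0, k0] * fx
    c10 = vol[i0, j0 + 1, k0] * (1 - fx) + vol[i0 + 1, j0 + 1, k0] * fx
    c01 = vol[i0, j0, k0 + 1] * (1 - fx) + vol[i0 + 1, j0, k0 + 1] * fx
    c11 = vol[i0, j0 + 1, k0 + 1] * (1 - fx) + vol[i0 + 1, j0 + 1, k0 + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True)
def _local_ncc(d, node_xyz, t_norm, offsets, sdata, s_ainv, s_orig, search_r,
               penalty):
    """Penalized NCC between the target patch and the shifted source patch.

    ``t_norm`` is the centered, unit-norm target patch.  A quadratic
    displacement penalty ``penalty * (|d| / search_r)^2`` biases toward
    minimal deformation (large moves must buy a real similarity gain);
    displacements beyond the spherical search radius are additionally
    penalized linearly so the simplex is steered back inside.
    """
    dn = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
    if dn > search_r:
        return -1.0 - (dn - search_r)
    k = offsets.shape[0]
    s = np.empty(k)
    ssum = 0.0
    for m in range(k):
        wx = node_xyz[0] + offsets[m, 0] + d[0]
        wy = node_xyz[1] + offsets[m, 1] + d[1]
        wz = node_xyz[2] + offsets[m, 2] + d[2]
        vx = s_ainv[0, 0] * (wx - s_orig[0]) + s_ainv[0, 1] * (wy - s_orig[1]) + s_ainv[0, 2] * (wz - s_orig[2])
        vy = s_ainv[1, 0] * (wx - s_orig[0]) + s_ainv[1, 1] * (wy - s_orig[1]) + s_ainv[1, 2] * (wz - s_orig[2])
        vz = s_ainv[2, 0] * (wx - s_orig[0]) + s_ainv[2, 1] * (wy - s_orig[1]) + s_ainv[2, 2] * (wz - s_orig[2])
        val = _trilinear(sdata, vx, vy, vz)
        s[m] = val
        ssum += val
    smean = ssum / k
    num = 0.0
    den = 0.0
    for m in range(k):
        sc = s[m] - smean
        num += t_norm[m] * sc
        den += sc * sc
    if den < 1e-12:
        return -penalty * (dn / search_r) ** 2
    return num / np.sqrt(den) - penalty * (dn / search_r) ** 2


@njit(cache=True)
def _nelder_mead_node(node_xyz, u0, t_norm, offsets, sdata, s_ainv, s_orig,
                      search_r, edge, max_eval, tie_eps, penalty):
    """Maximize local NCC over the 3 displacement components.

    Starts at the node's current displacement ``u0``; ties are broken toward
    zero displacement (minimal-deformation bias).  Returns the accepted
    displacement.
    """
    # working in "cost = -NCC" space
    n = 3
    pts = np.empty((4, 3))
    fvals = np.empty(4)
    for j in range(3):
        pts[0, j] = u0[j]
    fvals[0] = -_local_ncc(pts[0], node_xyz, t_norm, offsets, sdata, s_ainv,
                           s_orig, search_r, penalty)
    nev = 1
    zero = np.zeros(3)
    f_zero = -_local_ncc(zero, node_xyz, t_norm, offsets, sdata, s_ainv,
                         s_orig, search_r, penalty)
    nev += 1
    f_start = fvals[0]
    for i in range(1, 4):
        for j in range(3):
            pts[i, j] = pts[0, j]
        pts[i, i - 1] += edge
        fvals[i] = -_local_ncc(pts[i], node_xyz, t_norm, offsets, sdata,
                               s_ainv, s_orig, search_r, penalty)
        nev += 1

    while nev < max_eval:
        # order
        order = np.argsort(fvals)
        pts = pts[order]
        fvals = fvals[order]
        if fvals[3] - fvals[0] < 1e-7:
            break
        # centroid of best 3
        cen = np.zeros(3)
        for i in range(3):
            for j in range(3):
                cen[j] += pts[i, j] / 3.0
        xr = cen + (cen - pts[3])
        fr = -_local_ncc(xr, node_xyz, t_norm, offsets, sdata, s_ainv, s_orig,
                         search_r, penalty)
        nev += 1
        if fr < fvals[0]:
            xe = cen + 2.0 * (cen - pts[3])
            fe = -_local_ncc(xe, node_xyz, t_norm, offsets, sdata, s_ainv,
                             s_orig, search_r, penalty)
            nev += 1
            if fe < fr:
                pts[3] = xe
                fvals[3] = fe
            else:
                pts[3] = xr
                fvals[3] = fr
        elif fr < fvals[2]:
            pts[3] = xr
            fvals[3] = fr
        else:
            xc = cen + 0.5 * (pts[3] - cen)
            fc = -_local_ncc(xc, node_xyz, t_norm, offsets, sdata, s_ainv,
                             s_orig, search_r, penalty)
            nev += 1
            if fc < fvals[3]:
                pts[3] = xc
                fvals[3] = fc
            else:  # shrink toward best
                for i in range(1, 4):
                    pts[i] = pts[0] + 0.5 * (pts[i] - pts[0])
                    fvals[i] = -_local_ncc(pts[i], node_xyz, t_norm, offsets,
                                           sdata, s_ainv, s_orig, search_r, penalty)
                    nev += 1

    best = 0
    for i in range(1, 4):
        if fvals[i] < fvals[best]:
            best = i
    # tie-breaking: prefer zero displacement, then the incoming displacement,
    # over an insignificantly better optimum.  This suppresses the aperture
    # problem: moves along iso-intensity surfaces barely change local NCC, so
    # they must clear a meaningful similarity margin to be accepted.
    if f_zero <= fvals[best] + tie_eps:
        return zero
    if f_start <= fvals[best] + tie_eps:
        return u0.copy()
    return pts[best].copy()


@njit(cache=True)
def update_nodes(node_world, node_u, active, t_norm_patches, offsets, sdata,
                 s_ainv, s_orig, search_r, edge, max_eval, tie_eps, penalty):
    """One sweep of node-wise simplex optimization.

    Writes the data-driven displacement for every active node into ``out``
    (inactive nodes keep their incoming displacement).
    """
    n = node_world.shape[0]
    out = np.empty((n, 3))
    for i in range(n):
        if active[i]:
            out[i] = _nelder_mead_node(
                node_world[i], node_u[i], t_norm_patches[i], offsets, sdata,
                s_ainv, s_orig, search_r, edge, max_eval, tie_eps, penalty,
            )
        else:
            out[i, 0] = node_u[i, 0]
            out[i, 1] = node_u[i, 1]
            out[i, 2] = node_u[i, 2]
    return out
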