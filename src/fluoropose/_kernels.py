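"""Numba-accelerated inner loops for trilinear ray sampling.

The kernels fuse the per-sample gather, trilinear weights, and the per-ray
reductions (integral and the four Jacobian moments) into one pass with no
intermediate arrays.  ``rendering`` falls back to its pure-NumPy path when
numba is unavailable; both paths compute the same quantities.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def trilinear_integrate(mu_pad, s_idx, u_idx, t0, dt_tot, n):
    """Midpoint-rule line integrals through a zero-padded volume."""
    n_rays = s_idx.shape[0]
    out = np.zeros(n_rays)
    nx = mu_pad.shape[0] - 2
    ny = mu_pad.shape[1] - 2
    nz = mu_pad.shape[2] - 2
    for r in range(n_rays):
        if dt_tot[r] <= 0.0:
            continue
        dt = dt_tot[r] / n
        acc = 0.0
        for i in range(n):
            t = t0[r] + (i + 0.5) * dt
            px = s_idx[r, 0] + t * u_idx[r, 0] + 1.0
            py = s_idx[r, 1] + t * u_idx[r, 1] + 1.0
            pz = s_idx[r, 2] + t * u_idx[r, 2] + 1.0
            ix = int(np.floor(px))
            iy = int(np.floor(py))
            iz = int(np.floor(pz))
            if ix < 0:
                ix = 0
            elif ix > nx:
                ix = nx
            if iy < 0:
                iy = 0
            elif iy > ny:
                iy = ny
            if iz < 0:
                iz = 0
            elif iz > nz:
                iz = nz
            fx = px - ix
            fy = py - iy
            fz = pz - iz
            c00 = mu_pad[ix, iy, iz] + fz * (mu_pad[ix, iy, iz + 1] - mu_pad[ix, iy, iz])
            c01 = mu_pad[ix, iy + 1, iz] + fz * (
                mu_pad[ix, iy + 1, iz + 1] - mu_pad[ix, iy + 1, iz]
            )
            c10 = mu_pad[ix + 1, iy, iz] + fz * (
                mu_pad[ix + 1, iy, iz + 1] - mu_pad[ix + 1, iy, iz]
            )
            c11 = mu_pad[ix + 1, iy + 1, iz] + fz * (
                mu_pad[ix + 1, iy + 1, iz + 1] - mu_pad[ix + 1, iy + 1, iz]
            )
            c0 = c00 + fy * (c01 - c00)
            c1 = c10 + fy * (c11 - c10)
            acc += c0 + fx * (c1 - c0)
        out[r] = acc * dt
    return out


@njit(cache=True, fastmath=True)
def trilinear_integrate_moments(mu_pad, s_idx, u_idx, t0, dt_tot, n):
    """Line integrals plus the per-ray moments of the interpolation gradient
    needed for the analytic pose Jacobian.

    Returns (integral, val_sum, G0, G1, gu_sum, guf_sum) with
    G0 = sum_i grad_i, G1 = sum_i t_i grad_i, gu = grad_i . u_idx,
    gu_sum = sum_i gu_i, guf_sum = sum_i frac_i gu_i.
    """
    n_rays = s_idx.shape[0]
    integral = np.zeros(n_rays)
    val_sum = np.zeros(n_rays)
    G0 = np.zeros((n_rays, 3))
    G1 = np.zeros((n_rays, 3))
    gu_sum = np.zeros(n_rays)
    guf_sum = np.zeros(n_rays)
    nx = mu_pad.shape[0] - 2
    ny = mu_pad.shape[1] - 2
    nz = mu_pad.shape[2] - 2
    for r in range(n_rays):
        if dt_tot[r] <= 0.0:
            continue
        dt = dt_tot[r] / n
        acc = 0.0
        for i in range(n):
            frac = (i + 0.5) / n
            t = t0[r] + frac * dt_tot[r]
            px = s_idx[r, 0] + t * u_idx[r, 0] + 1.0
            py = s_idx[r, 1] + t * u_idx[r, 1] + 1.0
            pz = s_idx[r, 2] + t * u_idx[r, 2] + 1.0
            ix = int(np.floor(px))
            iy = int(np.floor(py))
            iz = int(np.floor(pz))
            if ix < 0:
                ix = 0
            elif ix > nx:
                ix = nx
            if iy < 0:
                iy = 0
            elif iy > ny:
                iy = ny
            if iz < 0:
                iz = 0
            elif iz > nz:
                iz = nz
            fx = px - ix
            fy = py - iy
            fz = pz - iz
            m000 = mu_pad[ix, iy, iz]
            m001 = mu_pad[ix, iy, iz + 1]
            m010 = mu_pad[ix, iy + 1, iz]
            m011 = mu_pad[ix, iy + 1, iz + 1]
            m100 = mu_pad[ix + 1, iy, iz]
            m101 = mu_pad[ix + 1, iy, iz + 1]
            m110 = mu_pad[ix + 1, iy + 1, iz]
            m111 = mu_pad[ix + 1, iy + 1, iz + 1]
            c00 = m000 + fz * (m001 - m000)
            c01 = m010 + fz * (m011 - m010)
            c10 = m100 + fz * (m101 - m100)
            c11 = m110 + fz * (m111 - m110)
            c0 = c00 + fy * (c01 - c00)
            c1 = c10 + fy * (c11 - c10)
            val = c0 + fx * (c1 - c0)
            gx = c1 - c0
            gy = (c01 - c00) * (1.0 - fx) + (c11 - c10) * fx
            d00 = m001 - m000
            d01 = m011 - m010
            d10 = m101 - m100
            d11 = m111 - m110
            gz = (d00 + fy * (d01 - d00)) * (1.0 - fx) + (d10 + fy * (d11 - d10)) * fx
            acc += val
            G0[r, 0] += gx
            G0[r, 1] += gy
            G0[r, 2] += gz
            G1[r, 0] += t * gx
            G1[r, 1] += t * gy
            G1[r, 2] += t * gz
            gu = gx * u_idx[r, 0] + gy * u_idx[r, 1] + gz * u_idx[r, 2]
            gu_sum[r] += gu
            guf_sum[r] += frac * gu
        integral[r] = acc * dt
        val_sum[r] = acc
    return integral, val_sum, G0, G1, gu_sum, guf_sum
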