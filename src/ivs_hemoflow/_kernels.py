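"""Numba-accelerated momentum predictor.

Single fused pass over the staggered velocity faces, replicating the
vectorised numpy predictor in :mod:`.solver` exactly (the test suite asserts
bitwise-tolerance agreement between the two paths). Ghost conventions:
tangential neighbours across a solid wall mirror with sign -1 (no-slip at the
face plane); lateral domain boundaries mirror with +1 (slip); the top
boundary mirrors tangential components with +1 (zero-gradient outflow); the
bottom with -1 (no-slip). Normal-direction neighbours read stored face
values, which carry the boundary conditions (zero on walls, the plug inflow
at the inlet, the extrapolated outflow at the top).
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
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def predict_kernel(u, v, w, act_u, act_v, act_w, hx, hy, hz, nu, dt, scheme,
                   us, vs, ws):  # pragma: no cover - exercised via solver tests
    nxp1, ny, nz = u.shape
    nx = nxp1 - 1
    hx2 = hx * hx
    hy2 = hy * hy
    hz2 = hz * hz

    for i in range(1, nx):
        for j in range(ny):
            for k in range(nz):
                if not act_u[i, j, k]:
                    continue
                uc = u[i, j, k]
                ue = u[i + 1, j, k]
                uw = u[i - 1, j, k]
                if j + 1 < ny:
                    un = u[i, j + 1, k] if act_u[i, j + 1, k] else -uc
                else:
                    un = uc
                if j - 1 >= 0:
                    usn = u[i, j - 1, k] if act_u[i, j - 1, k] else -uc
                else:
                    usn = uc
                if k + 1 < nz:
                    ut = u[i, j, k + 1] if act_u[i, j, k + 1] else -uc
                else:
                    ut = uc
                if k - 1 >= 0:
                    ub = u[i, j, k - 1] if act_u[i, j, k - 1] else -uc
                else:
                    ub = -uc
                rhs = nu * ((ue - 2 * uc + uw) / hx2 + (un - 2 * uc + usn) / hy2
                            + (ut - 2 * uc + ub) / hz2)
                if scheme > 0:
                    vb = 0.25 * (v[i - 1, j, k] + v[i - 1, j + 1, k]
                                 + v[i, j, k] + v[i, j + 1, k])
                    wb = 0.25 * (w[i - 1, j, k] + w[i - 1, j, k + 1]
                                 + w[i, j, k] + w[i, j, k + 1])
                    if scheme == 1:
                        dx = (uc - uw) / hx if uc > 0 else (ue - uc) / hx
                        dy = (uc - usn) / hy if vb > 0 else (un - uc) / hy
                        dz = (uc - ub) / hz if wb > 0 else (ut - uc) / hz
                    else:
                        dx = (ue - uw) / (2 * hx)
                        dy = (un - usn) / (2 * hy)
                        dz = (ut - ub) / (2 * hz)
                    rhs -= uc * dx + vb * dy + wb * dz
                us[i, j, k] = uc + dt * rhs

    for i in range(nx):
        for j in range(1, ny):
            for k in range(nz):
                if not act_v[i, j, k]:
                    continue
                vc = v[i, j, k]
                vn = v[i, j + 1, k]
                vsn = v[i, j - 1, k]
                if i + 1 < nx:
                    ve = v[i + 1, j, k] if act_v[i + 1, j, k] else -vc
                else:
                    ve = vc
                if i - 1 >= 0:
                    vw = v[i - 1, j, k] if act_v[i - 1, j, k] else -vc
                else:
                    vw = vc
                if k + 1 < nz:
                    vt = v[i, j, k + 1] if act_v[i, j, k + 1] else -vc
                else:
                    vt = vc
                if k - 1 >= 0:
                    vb_ = v[i, j, k - 1] if act_v[i, j, k - 1] else -vc
                else:
                    vb_ = -vc
                rhs = nu * ((ve - 2 * vc + vw) / hx2 + (vn - 2 * vc + vsn) / hy2
                            + (vt - 2 * vc + vb_) / hz2)
                if scheme > 0:
                    ub_ = 0.25 * (u[i, j - 1, k] + u[i + 1, j - 1, k]
                                  + u[i, j, k] + u[i + 1, j, k])
                    wb = 0.25 * (w[i, j - 1, k] + w[i, j - 1, k + 1]
                                 + w[i, j, k] + w[i, j, k + 1])
                    if scheme == 1:
                        dx = (vc - vw) / hx if ub_ > 0 else (ve - vc) / hx
                        dy = (vc - vsn) / hy if vc > 0 else (vn - vc) / hy
                        dz = (vc - vb_) / hz if wb > 0 else (vt - vc) / hz
                    else:
                        dx = (ve - vw) / (2 * hx)
                        dy = (vn - vsn) / (2 * hy)
                        dz = (vt - vb_) / (2 * hz)
                    rhs -= ub_ * dx + vc * dy + wb * dz
                vs[i, j, k] = vc + dt * rhs

    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                if not act_w[i, j, k]:
                    continue
                wc = w[i, j, k]
                wt = w[i, j, k + 1]
                wb_ = w[i, j, k - 1]
                if i + 1 < nx:
                    we = w[i + 1, j, k] if act_w[i + 1, j, k] else -wc
                else:
                    we = wc
                if i - 1 >= 0:
                    ww = w[i - 1, j, k] if act_w[i - 1, j, k] else -wc
                else:
                    ww = wc
                if j + 1 < ny:
                    wn = w[i, j + 1, k] if act_w[i, j + 1, k] else -wc
                else:
                    wn = wc
                if j - 1 >= 0:
                    wsn = w[i, j - 1, k] if act_w[i, j - 1, k] else -wc
                else:
                    wsn = wc
                rhs = nu * ((we - 2 * wc + ww) / hx2 + (wn - 2 * wc + wsn) / hy2
                            + (wt - 2 * wc + wb_) / hz2)
                if scheme > 0:
                    ub_ = 0.25 * (u[i, j, k - 1] + u[i + 1, j, k - 1]
                                  + u[i, j, k] + u[i + 1, j, k])
                    vb = 0.25 * (v[i, j, k - 1] + v[i, j + 1, k - 1]
                                 + v[i, j, k] + v[i, j + 1, k])
                    if scheme == 1:
                        dx = (wc - ww) / hx if ub_ > 0 else (we - wc) / hx
                        dy = (wc - wsn) / hy if vb > 0 else (wn - wc) / hy
                        dz = (wc - wb_) / hz if wc > 0 else (wt - wc) / hz
                    else:
                        dx = (we - ww) / (2 * hx)
                        dy = (wn - wsn) / (2 * hy)
                        dz = (wt - wb_) / (2 * hz)
                    rhs -= ub_ * dx + vb * dy + wc * dz
                ws[i, j, k] = wc + dt * rhs
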