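"""Fused compute kernels for the time loop.

The reference implementation of every operation lives in :mod:`.lattice`
as plain NumPy; these fused kernels produce identical numbers (asserted in
the test suite) and are used by the engine when numba is importable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


@njit(cache=True)
def macro_collide_force(f, out, c, w, opp, inv_tau_p, inv_tau_m, force, rho, u):
    """Macroscopics + TRT collision + Guo source, site by site.

    Reads populations ``f`` (n, 19), writes post-collision populations to
    ``out`` and the pre-collision macroscopic fields to ``rho``/``u``.
    """
    n, q = f.shape
    feq = np.empty(q)
    guo_even = 1.0 - 0.5 * inv_tau_p
    guo_odd = 1.0 - 0.5 * inv_tau_m
    for s in range(n):
        dens = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(q):
            fi = f[s, i]
            dens += fi
            mx += fi * c[i, 0]
            my += fi * c[i, 1]
            mz += fi * c[i, 2]
        Fx = force[s, 0]
        Fy = force[s, 1]
        Fz = force[s, 2]
        ux = (mx + 0.5 * Fx) / dens
        uy = (my + 0.5 * Fy) / dens
        uz = (mz + 0.5 * Fz) / dens
        rho[s] = dens
        u[s, 0] = ux
        u[s, 1] = uy
        u[s, 2] = uz
        usq = ux * ux + uy * uy + uz * uz
        for i in range(q):
            cu = c[i, 0] * ux + c[i, 1] * uy + c[i, 2] * uz
            feq[i] = w[i] * dens * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
        uF = ux * Fx + uy * Fy + uz * Fz
        for i in range(q):
            j = opp[i]
            fplus = 0.5 * (f[s, i] + f[s, j])
            fminus = 0.5 * (f[s, i] - f[s, j])
            eplus = 0.5 * (feq[i] + feq[j])
            eminus = 0.5 * (feq[i] - feq[j])
            val = f[s, i] - inv_tau_p * (fplus - eplus) - inv_tau_m * (fminus - eminus)
            cF = c[i, 0] * Fx + c[i, 1] * Fy + c[i, 2] * Fz
            cu = c[i, 0] * ux + c[i, 1] * uy + c[i, 2] * uz
            val += w[i] * (guo_odd * 3.0 * cF
                           + guo_even * (9.0 * cu * cF - 3.0 * uF))
            out[s, i] = val
    return out


@njit(cache=True)
def stream_pull(f, src, out):
    """Pull streaming; missing links keep their pre-stream value."""
    n, q = f.shape
    for s in range(n):
        for i in range(q):
            k = src[s, i]
            if k >= 0:
                out[s, i] = f[k, i]
            else:
                out[s, i] = f[s, i]
    return out
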