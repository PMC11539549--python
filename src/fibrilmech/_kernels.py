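"""Compiled inner loops for the force engine.

Single-threaded numba kernels, numerically identical to the vectorized
numpy path in :mod:`fibrilmech.engine` (which remains the reference
implementation and the fallback when numba is unavailable).  Each
kernel accumulates forces in place and returns (energy, axial virial).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def bond_kernel(x, bi, bj, r0, k0, k1, r1, rb, a, fb, cap, broken, maxext,
                f, box, periodic, allow_breaking, cap_extension):
    e = 0.0
    virial = 0.0
    for n in range(bi.size):
        i = bi[n]
        j = bj[n]
        dx = x[j, 0] - x[i, 0]
        if periodic:
            dx -= box * np.round(dx / box)
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if allow_breaking and r >= rb[n]:
            broken[n] = True
        if r > maxext[n]:
            maxext[n] = r
        re = r
        if cap_extension and re > rb[n] - 1e-6:
            re = rb[n] - 1e-6
        d1 = r1[n] - r0[n]
        if re < r1[n]:
            fs = -k0[n] * (re - r0[n])
            en = 0.5 * k0[n] * (re - r0[n]) ** 2
        elif re < rb[n]:
            fs = -(k0[n] * d1 + k1[n] * (re - r1[n]))
            en = (0.5 * k0[n] * d1 * d1 + k0[n] * d1 * (re - r1[n])
                  + 0.5 * k1[n] * (re - r1[n]) ** 2)
        elif re < rb[n] + a[n]:
            s = re - rb[n]
            fs = -fb[n] * (1.0 - s / a[n])
            en = cap[n] - 0.5 * fb[n] * a[n] + fb[n] * (s - s * s
                                                       / (2.0 * a[n]))
        else:
            fs = 0.0
            en = cap[n]
        if broken[n] and re < rb[n]:
            fs = 0.0
            en = cap[n]
        if cap_extension and r > re:
            # linear continuation keeps the energy consistent with the
            # capped restoring force (needed for line-search descent)
            en += fb[n] * (r - re)
        e += en
        inv_r = 1.0 / r
        fx = fs * dx * inv_r
        fy = fs * dy * inv_r
        fz = fs * dz * inv_r
        f[j, 0] += fx
        f[j, 1] += fy
        f[j, 2] += fz
        f[i, 0] -= fx
        f[i, 1] -= fy
        f[i, 2] -= fz
        virial += fs * dx * dx * inv_r
    return e, virial


@njit(cache=True)
def angle_kernel(x, ai, aj, ak, phi0, k_bend, f, box, periodic):
    e = 0.0
    virial = 0.0
    for n in range(ai.size):
        i = ai[n]
        j = aj[n]
        k = ak[n]
        ax = x[i, 0] - x[j, 0]
        bx = x[k, 0] - x[j, 0]
        if periodic:
            ax -= box * np.round(ax / box)
            bx -= box * np.round(bx / box)
        ay = x[i, 1] - x[j, 1]
        az = x[i, 2] - x[j, 2]
        by = x[k, 1] - x[j, 1]
        bz = x[k, 2] - x[j, 2]
        n1 = np.sqrt(ax * ax + ay * ay + az * az)
        n2 = np.sqrt(bx * bx + by * by + bz * bz)
        u1x, u1y, u1z = ax / n1, ay / n1, az / n1
        u2x, u2y, u2z = bx / n2, by / n2, bz / n2
        c = u1x * u2x + u1y * u2y + u1z * u2z
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = np.arccos(c)
        s = np.sqrt(max(1.0 - c * c, 0.0))
        dphi = phi - phi0[n]
        e += 0.5 * k_bend * dphi * dphi
        if s <= 1e-8:
            continue
        m = -k_bend * dphi
        inv_s = 1.0 / s
        gix = (c * u1x - u2x) * inv_s / n1
        giy = (c * u1y - u2y) * inv_s / n1
        giz = (c * u1z - u2z) * inv_s / n1
        gkx = (c * u2x - u1x) * inv_s / n2
        gky = (c * u2y - u1y) * inv_s / n2
        gkz = (c * u2z - u1z) * inv_s / n2
        fix, fiy, fiz = m * gix, m * giy, m * giz
        fkx, fky, fkz = m * gkx, m * gky, m * gkz
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
        virial += fix * ax + fkx * bx
    return e, virial


@njit(cache=True)
def pair_kernel(x, pi, pj, cls, eps, sig, lam, cut, f, box, periodic):
    e = 0.0
    virial = 0.0
    for n in range(pi.size):
        i = pi[n]
        j = pj[n]
        c = cls[n]
        dx = x[j, 0] - x[i, 0]
        if periodic:
            dx -= box * np.round(dx / box)
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut[c] * cut[c]:
            continue
        r = np.sqrt(r2)
        rcore = lam[c] * sig[c]
        re = r if r > rcore else rcore
        sr6 = (sig[c] / re) ** 6
        fs = (48.0 * eps[c] * sr6 * sr6 - 24.0 * eps[c] * sr6) / re
        sr6c = (sig[c] / cut[c]) ** 6
        en = (4.0 * eps[c] * (sr6 * sr6 - sr6)
              - 4.0 * eps[c] * (sr6c * sr6c - sr6c))
        if r < rcore:
            en += fs * (rcore - r)
        e += en
        inv_r = 1.0 / r
        fx = fs * dx * inv_r
        fy = fs * dy * inv_r
        fz = fs * dz * inv_r
        f[j, 0] += fx
        f[j, 1] += fy
        f[j, 2] += fz
        f[i, 0] -= fx
        f[i, 1] -= fy
        f[i, 2] -= fz
        virial += fs * dx * dx * inv_r
    return e, virial
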