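"""Compiled (numba) element kernels for the nonlinear solver.

These are performance-critical inner loops only; the public material laws
live in :mod:`ivdfem.materials` and are cross-checked against these kernels
by the test suite. Solid elements: isochoric Mooney-Rivlin / Neo-Hookean
(+ optional two-family HGO fiber term) at the 2x2x2 Gauss rule, volumetric
penalty at the element centroid. Membranes: one-point incompressible
Mooney-Rivlin plus two tension-only rebar fiber families.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fiber-law codes for membranes
FIBER_LINEAR = 0
FIBER_TABULATED = 1


@njit(cache=True, inline="always")
def _det3(F):
    return (F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
            - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
            + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]))


@njit(cache=True, inline="always")
def _inv3(A, out):
    d = _det3(A)
    out[0, 0] = (A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1]) / d
    out[0, 1] = (A[0, 2] * A[2, 1] - A[0, 1] * A[2, 2]) / d
    out[0, 2] = (A[0, 1] * A[1, 2] - A[0, 2] * A[1, 1]) / d
    out[1, 0] = (A[1, 2] * A[2, 0] - A[1, 0] * A[2, 2]) / d
    out[1, 1] = (A[0, 0] * A[2, 2] - A[0, 2] * A[2, 0]) / d
    out[1, 2] = (A[0, 2] * A[1, 0] - A[0, 0] * A[1, 2]) / d
    out[2, 0] = (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0]) / d
    out[2, 1] = (A[0, 1] * A[2, 0] - A[0, 0] * A[2, 1]) / d
    out[2, 2] = (A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]) / d
    return d


@njit(cache=True)
def solid_forces(Uel, dNdX, w, dNdXc, V, c10, c01, bulk, k1, k2, kappa,
                 a1, a2, out):
    """Element nodal internal forces; returns 0 on success, 1 on inversion."""
    E = Uel.shape[0]
    F = np.empty((3, 3))
    C = np.empty((3, 3))
    Cinv = np.empty((3, 3))
    S = np.empty((3, 3))
    P = np.empty((3, 3))
    for e in range(E):
        for n in range(8):
            for i in range(3):
                out[e, n, i] = 0.0
        for g in range(8):
            for i in range(3):
                for j in range(3):
                    s = 1.0 if i == j else 0.0
                    for n in range(8):
                        s += Uel[e, n, i] * dNdX[e, g, n, j]
                    F[i, j] = s
            J = _det3(F)
            if J <= 0.0:
                return 1
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[k, i] * F[k, j]
                    C[i, j] = s
            _inv3(C, Cinv)
            I1 = C[0, 0] + C[1, 1] + C[2, 2]
            J23 = J ** (-2.0 / 3.0)
            ci = 2.0 * c10[e] * J23
            for i in range(3):
                for j in range(3):
                    S[i, j] = ci * (-(I1 / 3.0) * Cinv[i, j])
                S[i, i] += ci
            if c01[e] > 0.0:
                trC2 = 0.0
                for i in range(3):
                    for j in range(3):
                        trC2 += C[i, j] * C[j, i]
                I2 = 0.5 * (I1 * I1 - trC2)
                cj = 2.0 * c01[e] * J ** (-4.0 / 3.0)
                for i in range(3):
                    for j in range(3):
                        S[i, j] += cj * (-C[i, j]
                                         - (2.0 * I2 / 3.0) * Cinv[i, j])
                    S[i, i] += cj * I1
            if k1[e] > 0.0:
                I1b = J23 * I1
                for fam in range(2):
                    a = a1[e] if fam == 0 else a2[e]
                    I4 = 0.0
                    for i in range(3):
                        for j in range(3):
                            I4 += a[i] * C[i, j] * a[j]
                    Ea = (kappa[e] * (I1b - 3.0)
                          + (1.0 - 3.0 * kappa[e]) * (J23 * I4 - 1.0))
                    if Ea > 0.0:
                        ex = k2[e] * Ea * Ea
                        if ex > 50.0:
                            ex = 50.0
                        dW = k1[e] * Ea * np.exp(ex)
                        c_i1 = 2.0 * dW * kappa[e] * J23
                        c_i4 = 2.0 * dW * (1.0 - 3.0 * kappa[e]) * J23
                        for i in range(3):
                            for j in range(3):
                                S[i, j] += (c_i1 * (-(I1 / 3.0) * Cinv[i, j])
                                            + c_i4 * (a[i] * a[j]
                                                      - (I4 / 3.0) * Cinv[i, j]))
                            S[i, i] += c_i1
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += F[i, k] * S[k, j]
                    P[i, j] = s
            wg = w[e, g]
            for n in range(8):
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += P[i, j] * dNdX[e, g, n, j]
                    out[e, n, i] += wg * s
        # volumetric penalty from the centroid deformation gradient
        for i in range(3):
            for j in range(3):
                s = 1.0 if i == j else 0.0
                for n in range(8):
                    s += Uel[e, n, i] * dNdXc[e, n, j]
                F[i, j] = s
        Jc = _inv3(F, Cinv)  # Cinv <- F^{-1}
        if Jc <= 0.0:
            return 1
        coef = V[e] * bulk[e] * (Jc - 1.0) * Jc
        for n in range(8):
            for i in range(3):
                s = 0.0
                for j in range(3):
                    s += Cinv[j, i] * dNdXc[e, n, j]  # F^{-T}[i,j] = Finv[j,i]
                out[e, n, i] += coef * s
    return 0


@njit(cache=True)
def solid_stiffness(Uel, dNdX, w, dNdXc, V, c10, c01, bulk, k1, k2, kappa,
                    a1, a2, h, Kout):
    """Forward-difference element stiffness (E, 24, 24)."""
    E = Uel.shape[0]
    f0 = np.empty((E, 8, 3))
    if solid_forces(Uel, dNdX, w, dNdXc, V, c10, c01, bulk, k1, k2, kappa,
                    a1, a2, f0):
        return 1
    fp = np.empty((E, 8, 3))
    Up = Uel.copy()
    for n in range(8):
        for i in range(3):
            d = 3 * n + i
            for e in range(E):
                Up[e, n, i] += h
            if solid_forces(Up, dNdX, w, dNdXc, V, c10, c01, bulk, k1, k2,
                            kappa, a1, a2, fp):
                return 1
            for e in range(E):
                Up[e, n, i] -= h
                for nn in range(8):
                    for ii in range(3):
                        Kout[e, 3 * nn + ii, d] = (fp[e, nn, ii]
                                                   - f0[e, nn, ii]) / h
    return 0


# ---------------------------------------------------------------------------
# membranes
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _fiber_energy(eps, kind, E_mod, tab_strain, tab_stress, tab_energy):
    if eps <= 0.0:
        return 0.0
    if kind == FIBER_LINEAR:
        return 0.5 * E_mod * eps * eps
    n = tab_strain.shape[0]
    if eps >= tab_strain[n - 1]:
        return tab_energy[n - 1] + tab_stress[n - 1] * (eps - tab_strain[n - 1])
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tab_strain[mid] <= eps:
            lo = mid
        else:
            hi = mid
    t = (eps - tab_strain[lo]) / (tab_strain[lo + 1] - tab_strain[lo])
    # exact integral of the piecewise-linear stress over the partial segment
    s_lo = tab_stress[lo]
    s_eps = s_lo + t * (tab_stress[lo + 1] - s_lo)
    return tab_energy[lo] + 0.5 * (s_lo + s_eps) * (eps - tab_strain[lo])


@njit(cache=True)
def membrane_energy(xel, Ginv, detG, A0, coef1, coef2, mult, c10, c01,
                    tmem, treb, fiber_kind, fiber_E, tab_strain, tab_stress,
                    tab_energy, out):
    """Per-quad strain energy; returns 0 on success, 1 on patch inversion."""
    Q = xel.shape[0]
    for q in range(Q):
        g1x = 0.25 * (-xel[q, 0, 0] + xel[q, 1, 0] + xel[q, 2, 0] - xel[q, 3, 0])
        g1y = 0.25 * (-xel[q, 0, 1] + xel[q, 1, 1] + xel[q, 2, 1] - xel[q, 3, 1])
        g1z = 0.25 * (-xel[q, 0, 2] + xel[q, 1, 2] + xel[q, 2, 2] - xel[q, 3, 2])
        g2x = 0.25 * (-xel[q, 0, 0] - xel[q, 1, 0] + xel[q, 2, 0] + xel[q, 3, 0])
        g2y = 0.25 * (-xel[q, 0, 1] - xel[q, 1, 1] + xel[q, 2, 1] + xel[q, 3, 1])
        g2z = 0.25 * (-xel[q, 0, 2] - xel[q, 1, 2] + xel[q, 2, 2] + xel[q, 3, 2])
        g11 = g1x * g1x + g1y * g1y + g1z * g1z
        g12 = g1x * g2x + g1y * g2y + g1z * g2z
        g22 = g2x * g2x + g2y * g2y + g2z * g2z
        detg = g11 * g22 - g12 * g12
        if detg <= 0.0:
            return 1
        J2sq = detg / detG[q]
        trC = (Ginv[q, 0, 0] * g11 + 2.0 * Ginv[q, 0, 1] * g12
               + Ginv[q, 1, 1] * g22)
        I1 = trC + 1.0 / J2sq
        I2 = J2sq + trC / J2sq
        e = A0[q] * tmem * (c10 * (I1 - 3.0) + c01 * (I2 - 3.0))
        if treb > 0.0:
            for fam in range(2):
                ca = coef1[q, 0] if fam == 0 else coef2[q, 0]
                cb = coef1[q, 1] if fam == 0 else coef2[q, 1]
                vx = ca * g1x + cb * g2x
                vy = ca * g1y + cb * g2y
                vz = ca * g1z + cb * g2z
                lam = np.sqrt(vx * vx + vy * vy + vz * vz)
                wf = _fiber_energy(lam - 1.0, fiber_kind, fiber_E,
                                   tab_strain, tab_stress, tab_energy)
                e += A0[q] * treb * mult[q] * wf
        out[q] = e
    return 0


@njit(cache=True)
def membrane_forces(xel, Ginv, detG, A0, coef1, coef2, mult, c10, c01,
                    tmem, treb, fiber_kind, fiber_E, tab_strain, tab_stress,
                    tab_energy, h, out):
    """Central-difference nodal forces (Q, 4, 3) from the patch energy."""
    Q = xel.shape[0]
    ep = np.empty(Q)
    em = np.empty(Q)
    xp = xel.copy()
    for n in range(4):
        for i in range(3):
            for q in range(Q):
                xp[q, n, i] += h
            if membrane_energy(xp, Ginv, detG, A0, coef1, coef2, mult, c10,
                               c01, tmem, treb, fiber_kind, fiber_E,
                               tab_strain, tab_stress, tab_energy, ep):
                return 1
            for q in range(Q):
                xp[q, n, i] -= 2.0 * h
            if membrane_energy(xp, Ginv, detG, A0, coef1, coef2, mult, c10,
                               c01, tmem, treb, fiber_kind, fiber_E,
                               tab_strain, tab_stress, tab_energy, em):
                return 1
            for q in range(Q):
                xp[q, n, i] += h
                out[q, n, i] = (ep[q] - em[q]) / (2.0 * h)
    return 0


@njit(cache=True)
def membrane_stiffness(xel, Ginv, detG, A0, coef1, coef2, mult, c10, c01,
                       tmem, treb, fiber_kind, fiber_E, tab_strain,
                       tab_stress, tab_energy, h, Kout):
    Q = xel.shape[0]
    f0 = np.empty((Q, 4, 3))
    if membrane_forces(xel, Ginv, detG, A0, coef1, coef2, mult, c10, c01,
                       tmem, treb, fiber_kind, fiber_E, tab_strain,
                       tab_stress, tab_energy, h, f0):
        return 1
    fp = np.empty((Q, 4, 3))
    xp = xel.copy()
    for n in range(4):
        for i in range(3):
            d = 3 * n + i
            for q in range(Q):
                xp[q, n, i] += h
            if membrane_forces(xp, Ginv, detG, A0, coef1, coef2, mult, c10,
                               c01, tmem, treb, fiber_kind, fiber_E,
                               tab_strain, tab_stress, tab_energy, h, fp):
                return 1
            for q in range(Q):
                xp[q, n, i] -= h
                for nn in range(4):
                    for ii in range(3):
                        Kout[q, 3 * nn + ii, d] = (fp[q, nn, ii]
                                                   - f0[q, nn, ii]) / h
    return 0
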