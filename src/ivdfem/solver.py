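"""Nonlinear static finite-element solver for the disc models.

Total-Lagrangian 8-node hexahedra with selective reduced integration:
the isochoric (deviatoric) part of the strain energy is integrated at the
full 2x2x2 Gauss rule while the volumetric penalty ``(K/2)(J - 1)^2`` is
evaluated from the element-centroid deformation gradient. This controls
volumetric locking of the nearly incompressible NP and AF ground substance
without a mixed formulation. Rebar models additionally carry 4-node membrane
patches (one-point integrated; the surrounding solids suppress hourglassing)
with an incompressible-membrane Mooney-Rivlin ground substance and two
tension-only rebar fiber families.

Loading replicates the in vitro pure-moment protocol: the top-surface nodes
are rigidly coupled (finite-rotation kinematic coupling) to a reference
point 10 mm above the disc, the bottom surface is fixed, and the moment is
ramped in increments. Each increment is solved by Newton iteration with
backtracking line search and automatic load-step halving; the internal
force is analytic, the tangent a forward finite difference of it, so the
converged residual is exact to machine precision regardless of the tangent
approximation. The solver is deterministic (no random state).

Outcome metrics: range of motion (RoM) -- the rotation of the coupled
reference point about the load axis, in degrees -- and intradiscal pressure
(IDP) -- the volume-averaged hydrostatic pressure ``-tr(sigma)/3`` over NP
elements inside a central sampling sphere.

Units: mm - N - MPa; moments in N*mm internally (7.5 Nm = 7500 N*mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels as _k
from .geometry import HEX_GAUSS, hex_shape_grad
from .materials import LinearFiberParams, TabulatedFiberCurve
from .model import DiscModel, MembraneSet, SolidMaterialArrays

__all__ = [
    "LoadCase",
    "LOAD_CASES",
    "SolveSettings",
    "SimulationResult",
    "solve_static",
    "simulate_curves",
    "compute_rom",
    "compute_idp",
    "uniaxial_single_element",
    "NonConvergenceError",
]

_EYE = np.eye(3)


class NonConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoadCase:
    """Pure-moment load case: anatomical name, global axis and sign."""

    name: str
    axis: np.ndarray
    sign: int = 1

    def moment_vector(self, magnitude: float) -> np.ndarray:
        return self.sign * magnitude * np.asarray(self.axis, dtype=float)


# x = left-lateral, y = posterior, z = cranial
LOAD_CASES = {
    "flexion": LoadCase("flexion", np.array([1.0, 0.0, 0.0]), +1),
    "extension": LoadCase("extension", np.array([1.0, 0.0, 0.0]), -1),
    "lateral_bending": LoadCase("lateral_bending", np.array([0.0, 1.0, 0.0]), +1),
    "axial_rotation": LoadCase("axial_rotation", np.array([0.0, 0.0, 1.0]), +1),
}


@dataclass
class SolveSettings:
    """Incremental-solve controls. ``max_moment`` in N*mm.

    If ``moment_grid`` (N*mm, increasing) is given it overrides the equally
    spaced ramp defined by ``n_increments``.
    """

    max_moment: float = 7500.0
    n_increments: int = 4
    newton_tol: float = 1e-6
    max_newton_iters: int = 30
    max_halvings: int = 4
    moment_grid: np.ndarray | None = None

    def targets(self) -> np.ndarray:
        if self.moment_grid is not None:
            g = np.asarray(self.moment_grid, dtype=float)
            if np.any(np.diff(g) <= 0) or (len(g) and g[0] <= 0):
                raise ValueError("moment_grid must be positive and increasing")
            return g
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        return np.linspace(0.0, self.max_moment, self.n_increments + 1)[1:]


@dataclass
class SimulationResult:
    """Moment-RoM and moment-IDP curves for one load case."""

    load_case: str
    moments: np.ndarray          # N*mm, starting at 0
    rom: np.ndarray              # degrees
    idp: np.ndarray              # MPa
    converged: np.ndarray        # per increment
    stats: dict = field(default_factory=dict)
    state: dict | None = None    # final displacements etc. (optional)

    @property
    def moments_nm(self) -> np.ndarray:
        return self.moments / 1000.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "load_case": self.load_case,
            "moment_Nm": self.moments_nm,
            "rom_deg": self.rom,
            "idp_MPa": self.idp,
            "converged": self.converged,
        })


# ---------------------------------------------------------------------------
# rotation helpers (finite-rotation rigid coupling)
# ---------------------------------------------------------------------------


def _skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def rotation_matrix(theta: np.ndarray) -> np.ndarray:
    """Rodrigues rotation from a rotation vector (radians)."""
    t = np.linalg.norm(theta)
    K = _skew(theta)
    if t < 1e-12:
        return _EYE + K + 0.5 * K @ K
    return _EYE + np.sin(t) / t * K + (1 - np.cos(t)) / t**2 * K @ K


def left_jacobian(theta: np.ndarray) -> np.ndarray:
    """Left Jacobian of SO(3): delta_omega = J_l(theta) * delta_theta."""
    t = np.linalg.norm(theta)
    K = _skew(theta)
    if t < 1e-6:
        return _EYE + 0.5 * K + K @ K / 6.0
    return (_EYE + (1 - np.cos(t)) / t**2 * K + (t - np.sin(t)) / t**3 * K @ K)


# ---------------------------------------------------------------------------
# element kernels (vectorized over elements / Gauss points)
# ---------------------------------------------------------------------------


class _SolidKernel:
    def __init__(self, coords, elems, mats: SolidMaterialArrays):
        self.elems = elems
        self.mats = mats
        X = coords[elems]                      # (E, 8, 3)
        g = hex_shape_grad(HEX_GAUSS)          # (8gp, 8, 3)
        Jac = np.einsum("eni,gnj->egij", X, g)
        detJ = np.linalg.det(Jac)
        if np.any(detJ <= 0):
            bad = int(np.argwhere(np.any(detJ <= 0, axis=1))[0, 0])
            raise ValueError(f"inverted/degenerate element {bad} in mesh")
        Jinv = np.linalg.inv(Jac)
        self.dNdX = np.einsum("gnj,egji->egni", g, Jinv)
        self.w = detJ                          # unit Gauss weights
        gc = hex_shape_grad(np.zeros((1, 3)))  # centroid
        Jc = np.einsum("eni,gnj->egij", X, gc)[:, 0]
        self.detJc = np.linalg.det(Jc)
        self.dNdXc = np.einsum("gnj,eji->eni", gc, np.linalg.inv(Jc))
        self.V = detJ.sum(axis=1)
        self.has_fiber = mats.k1 > 0

    def deformation(self, Uel):
        H = np.einsum("eni,egnj->egij", Uel, self.dNdX)
        F = H + _EYE
        Hc = np.einsum("eni,enj->eij", Uel, self.dNdXc)
        Fc = Hc + _EYE
        return F, Fc

    def _pk1_dev(self, F):
        """Isochoric first Piola-Kirchhoff stress (E, G, 3, 3)."""
        m = self.mats
        C = np.swapaxes(F, -1, -2) @ F
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise NonConvergenceError("element inversion during iteration")
        Cinv = np.linalg.inv(C)
        I1 = np.trace(C, axis1=-2, axis2=-1)
        J23 = J ** (-2.0 / 3.0)
        c10 = m.c10[:, None, None, None]
        S = 2.0 * c10 * J23[..., None, None] * (
            _EYE - (I1[..., None, None] / 3.0) * Cinv)
        if np.any(m.c01 > 0):
            trC2 = np.trace(C @ C, axis1=-2, axis2=-1)
            I2 = 0.5 * (I1**2 - trC2)
            c01 = m.c01[:, None, None, None]
            J43 = (J ** (-4.0 / 3.0))[..., None, None]
            S = S + 2.0 * c01 * J43 * (
                I1[..., None, None] * _EYE - C
                - (2.0 * I2[..., None, None] / 3.0) * Cinv)
        if np.any(self.has_fiber):
            I1b = J23 * I1
            k1 = m.k1[:, None]
            k2 = m.k2[:, None]
            kap = m.kappa[:, None]
            dI1b = J23[..., None, None] * (
                _EYE - (I1[..., None, None] / 3.0) * Cinv)
            for a in (m.a1, m.a2):
                I4 = np.einsum("ei,egij,ej->eg", a, C, a)
                E_a = kap * (I1b - 3.0) + (1.0 - 3.0 * kap) * (J23 * I4 - 1.0)
                Epos = np.maximum(E_a, 0.0)
                dW = k1 * Epos * np.exp(np.minimum(k2 * Epos**2, 50.0))
                aa = np.einsum("ei,ej->eij", a, a)[:, None]
                dI4b = J23[..., None, None] * (
                    aa - (I4[..., None, None] / 3.0) * Cinv)
                S = S + 2.0 * dW[..., None, None] * (
                    kap[..., None, None] * dI1b
                    + (1.0 - 3.0 * kap)[..., None, None] * dI4b)
        return F @ S

    def _args(self):
        m = self.mats
        return (self.dNdX, self.w, self.dNdXc, self.V, m.c10, m.c01, m.bulk,
                m.k1, m.k2, m.kappa, m.a1, m.a2)

    def forces(self, Uel):
        """Element nodal internal forces (E, 8, 3)."""
        out = np.empty_like(Uel)
        if _k.solid_forces(np.ascontiguousarray(Uel), *self._args(), out):
            raise NonConvergenceError("element inversion during iteration")
        return out

    def stiffness_fd(self, Uel, h):
        """Element stiffness (E, 24, 24) by forward FD of the forces."""
        K = np.empty((len(Uel), 24, 24))
        if _k.solid_stiffness(np.ascontiguousarray(Uel), *self._args(), h, K):
            raise NonConvergenceError("element inversion during iteration")
        return K

    def centroid_cauchy(self, Uel):
        """Cauchy stress at element centroids (E, 3, 3), SRI-consistent."""
        _, Fc = self.deformation(Uel)
        P = self._pk1_dev(Fc[:, None])[:, 0]
        Jc = np.linalg.det(Fc)
        P = P + (self.mats.bulk * (Jc - 1.0) * Jc)[:, None, None] * \
            np.swapaxes(np.linalg.inv(Fc), -1, -2)
        sig = P @ np.swapaxes(Fc, -1, -2) / Jc[:, None, None]
        return 0.5 * (sig + np.swapaxes(sig, -1, -2))


class _MembraneKernel:
    def __init__(self, coords, mem: MembraneSet):
        self.mem = mem
        self.quads = mem.quads
        X = coords[mem.quads]                    # (Q, 4, 3)
        xi = np.array([-1.0, 1.0, 1.0, -1.0]) / 4.0
        eta = np.array([-1.0, -1.0, 1.0, 1.0]) / 4.0
        self._dN = np.stack([xi, eta])           # (2, 4) center derivatives
        G1 = np.einsum("n,qni->qi", xi, X)
        G2 = np.einsum("n,qni->qi", eta, X)
        Gab = np.empty((len(X), 2, 2))
        Gab[:, 0, 0] = np.einsum("qi,qi->q", G1, G1)
        Gab[:, 0, 1] = Gab[:, 1, 0] = np.einsum("qi,qi->q", G1, G2)
        Gab[:, 1, 1] = np.einsum("qi,qi->q", G2, G2)
        self.detG = np.linalg.det(Gab)
        if np.any(self.detG <= 0):
            raise ValueError("degenerate membrane patch")
        self.Ginv = np.linalg.inv(Gab)
        self.A0 = 4.0 * np.sqrt(self.detG)       # reference patch area
        # reference fiber directions decomposed in the surface basis
        self.fib_coef = []
        for dirs in (mem.dirs1, mem.dirs2):
            b = np.stack([np.einsum("qi,qi->q", dirs, G1),
                          np.einsum("qi,qi->q", dirs, G2)], axis=1)
            self.fib_coef.append(np.einsum("qab,qb->qa", self.Ginv, b))
        fm = mem.fiber_material
        if isinstance(fm, LinearFiberParams):
            self._fiber = (_k.FIBER_LINEAR, fm.E, np.zeros(2), np.zeros(2),
                           np.zeros(2))
        elif isinstance(fm, TabulatedFiberCurve):
            self._fiber = (_k.FIBER_TABULATED, 0.0, fm.strain, fm.stress,
                           fm._energy)
        else:
            raise TypeError(f"unsupported rebar material {type(fm).__name__}")

    def _args(self):
        m = self.mem
        return (self.Ginv, self.detG, self.A0, self.fib_coef[0],
                self.fib_coef[1], m.multiplier, m.c10, m.c01,
                m.membrane_thickness, m.rebar_thickness, *self._fiber)

    def energy(self, xel):
        """Per-quad strain energy (Q,) from current coordinates (Q, 4, 3)."""
        out = np.empty(len(xel))
        if _k.membrane_energy(np.ascontiguousarray(xel), *self._args(), out):
            raise NonConvergenceError("membrane patch inversion")
        return out

    def forces(self, xel, h):
        """Nodal forces (Q, 4, 3) by central FD of the patch energy."""
        f = np.empty_like(xel)
        if _k.membrane_forces(np.ascontiguousarray(xel), *self._args(), h, f):
            raise NonConvergenceError("membrane patch inversion")
        return f

    def stiffness_fd(self, xel, h):
        K = np.empty((len(xel), 12, 12))
        if _k.membrane_stiffness(np.ascontiguousarray(xel), *self._args(),
                                 h, K):
            raise NonConvergenceError("membrane patch inversion")
        return K


# ---------------------------------------------------------------------------
# global system with rigid moment coupling
# ---------------------------------------------------------------------------


class _MomentSystem:
    """Reduced system: free interior nodes + 6 reference-point DOFs.

    Bottom-surface nodes are fixed; top-surface nodes follow the load
    reference point rigidly (finite rotation).
    """

    def __init__(self, model: DiscModel):
        mesh = model.mesh
        self.coords = mesh.node_coords
        self.N = mesh.n_nodes
        self.solid = _SolidKernel(self.coords, mesh.elements, model.solids)
        self.membrane = (None if model.membranes is None
                         else _MembraneKernel(self.coords, model.membranes))
        self.top = mesh.top_nodes()
        self.bottom = mesh.bottom_nodes()
        fixed = np.zeros(self.N, dtype=bool)
        fixed[self.top] = True
        fixed[self.bottom] = True
        self.free = np.where(~fixed)[0]
        self.nq = 3 * len(self.free) + 6
        self.ref = np.asarray(model.ref_points["load"], dtype=float)
        self.p_top = self.coords[self.top] - self.ref  # lever arms
        self.h = 1e-6 * float(np.mean(self.solid.V) ** (1.0 / 3.0))
        # COO scatter indices for the full stiffness
        ed = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 24)
        self.solid_rows = np.repeat(ed, 24, axis=1).ravel()
        self.solid_cols = np.tile(ed, (1, 24)).ravel()
        if self.membrane is not None:
            qd = (3 * model.membranes.quads[:, :, None]
                  + np.arange(3)).reshape(-1, 12)
            self.mem_rows = np.repeat(qd, 12, axis=1).ravel()
            self.mem_cols = np.tile(qd, (1, 12)).ravel()
        # P-matrix skeleton for the free block (constant)
        fr = (3 * self.free[:, None] + np.arange(3)).ravel()
        self._free_rows = fr
        self._free_cols = np.arange(3 * len(self.free))

    # -- kinematics ---------------------------------------------------------

    def split(self, q):
        nf = 3 * len(self.free)
        return q[:nf].reshape(-1, 3), q[nf:nf + 3], q[nf + 3:]

    def full_displacement(self, q):
        uf, t, th = self.split(q)
        U = np.zeros((self.N, 3))
        U[self.free] = uf
        R = rotation_matrix(th)
        U[self.top] = t + self.p_top @ (R.T - _EYE)
        return U

    def coupling_blocks(self, th):
        """(T, 3, 3) blocks du_top/dtheta = -skew(R p) @ J_l(theta)."""
        R = rotation_matrix(th)
        Jl = left_jacobian(th)
        Rp = self.p_top @ R.T
        blocks = np.empty((len(self.top), 3, 3))
        for i, rp in enumerate(Rp):
            blocks[i] = -_skew(rp) @ Jl
        return blocks

    def P_matrix(self, th) -> sp.csr_matrix:
        nf = 3 * len(self.free)
        rows = [self._free_rows]
        cols = [self._free_cols]
        vals = [np.ones(nf)]
        tr = (3 * self.top[:, None] + np.arange(3)).ravel()
        # translation block
        rows.append(tr)
        cols.append(np.tile(nf + np.arange(3), len(self.top)))
        vals.append(np.ones(3 * len(self.top)))
        # rotation block
        blocks = self.coupling_blocks(th)
        rows.append(np.repeat(tr, 3))
        cols.append(np.tile(nf + 3 + np.arange(3), 3 * len(self.top)))
        vals.append(blocks.reshape(-1))
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * self.N, self.nq))

    # -- forces -------------------------------------------------------------

    def internal_force(self, U):
        f = np.zeros((self.N, 3))
        fel = self.solid.forces(U[self.solid.elems])
        np.add.at(f, self.solid.elems.ravel(), fel.reshape(-1, 3))
        if self.membrane is not None:
            x = (self.coords + U)[self.membrane.quads]
            fm = self.membrane.forces(x, self.h)
            np.add.at(f, self.membrane.quads.ravel(), fm.reshape(-1, 3))
        return f

    def external_gen_force(self, th, moment_vec):
        g = np.zeros(self.nq)
        g[-3:] = left_jacobian(th).T @ moment_vec
        return g

    def residual(self, q, moment_vec):
        _, _, th = self.split(q)
        U = self.full_displacement(q)
        f = self.internal_force(U).ravel()
        P = self.P_matrix(th)
        return P.T @ f - self.external_gen_force(th, moment_vec)

    def tangent(self, q, moment_vec, r0):
        _, _, th = self.split(q)
        U = self.full_displacement(q)
        Kel = self.solid.stiffness_fd(U[self.solid.elems], self.h)
        K = sp.coo_matrix((Kel.ravel(), (self.solid_rows, self.solid_cols)),
                          shape=(3 * self.N, 3 * self.N))
        if self.membrane is not None:
            x = (self.coords + U)[self.membrane.quads]
            Km = self.membrane.stiffness_fd(x, self.h)
            K = K + sp.coo_matrix((Km.ravel(), (self.mem_rows, self.mem_cols)),
                                  shape=(3 * self.N, 3 * self.N))
        P = self.P_matrix(th)
        A = (P.T @ K.tocsr() @ P).tocsc()
        # exact FD columns for the 6 reference DOFs (captures the geometric
        # coupling and external-moment tangents)
        nf = self.nq - 6
        B = np.empty((self.nq, 6))
        hr = 1e-6
        for j in range(6):
            qp = q.copy()
            qp[nf + j] += hr
            B[:, j] = (self.residual(qp, moment_vec) - r0) / hr
        A = sp.hstack([A[:, :nf], sp.csc_matrix(B)]).tocsc()
        return A


def _newton(system: _MomentSystem, q, moment_vec, settings: SolveSettings):
    g = system.external_gen_force(q[-3:], moment_vec)
    scale = 1.0 + np.linalg.norm(g)
    r = system.residual(q, moment_vec)
    rn = np.linalg.norm(r)
    iters = 0
    lu = None  # reused tangent factor (modified Newton) while progress is good
    n_crawl = 0  # consecutive heavily backtracked iterations
    for _ in range(settings.max_newton_iters):
        if rn <= settings.newton_tol * scale:
            return q, True, iters
        fresh = lu is None
        if fresh:
            A = system.tangent(q, moment_vec, r)
            try:
                lu = spla.splu(A)
            except RuntimeError:
                return q, False, iters
        dq = lu.solve(-r)
        alpha, best_q, best_r, best_rn = 1.0, None, None, np.inf
        for _ls in range(9):
            try:
                q_try = q + alpha * dq
                r_try = system.residual(q_try, moment_vec)
            except NonConvergenceError:
                alpha *= 0.5
                continue
            rn_try = np.linalg.norm(r_try)
            if rn_try < best_rn:
                best_q, best_r, best_rn = q_try, r_try, rn_try
            if rn_try < (1.0 - 1e-4 * alpha) * rn:
                break
            alpha *= 0.5
        if best_q is None or best_rn >= rn * (1.0 + 1e-12):
            if not fresh:
                lu = None  # stale tangent: retry with a fresh assembly
                continue
            return q, False, iters  # stagnated with a fresh tangent
        if fresh and alpha <= 0.0625:
            # the full step is badly off even with a fresh tangent: the
            # increment is too large, let the caller sub-step instead of
            # crawling along the line search
            n_crawl += 1
            if n_crawl >= 2:
                return q, False, iters
        else:
            n_crawl = 0
        if alpha < 1.0 or best_rn > 0.2 * rn:
            lu = None  # slow progress: reassemble next iteration
        q, r, rn = best_q, best_r, best_rn
        iters += 1
    return q, rn <= settings.newton_tol * scale, iters


def solve_static(model: DiscModel, load_case: LoadCase | str,
                 settings: SolveSettings,
                 return_state: bool = False) -> SimulationResult:
    """Incremental pure-moment solve; returns RoM/IDP curves.

    On non-convergence the result is flagged and the partial curve up to the
    last converged increment is returned.
    """
    if isinstance(load_case, str):
        load_case = LOAD_CASES[load_case]
    system = _MomentSystem(model)
    targets = settings.targets()
    moments = [0.0]
    rom = [0.0]
    idp = [0.0]
    converged = [True]
    total_iters = 0

    q = np.zeros(system.nq)
    q_hist = [(0.0, q.copy())]
    ok_all = True
    for m_target in targets:
        # predictor: linear extrapolation in the moment, kept only when it
        # actually lowers the residual (extrapolating a stiffening curve
        # can badly overshoot)
        m_prev, q_prev = q_hist[-1]
        q = q_prev.copy()
        if len(q_hist) >= 2 and m_prev > q_hist[-2][0]:
            m_pp, q_pp = q_hist[-2]
            fac = (m_target - m_prev) / (m_prev - m_pp)
            q_ex = q_prev + fac * (q_prev - q_pp)
            mv0 = load_case.moment_vector(m_target)
            try:
                rn_ex = np.linalg.norm(system.residual(q_ex, mv0))
                rn_prev = np.linalg.norm(system.residual(q_prev, mv0))
                if rn_ex < rn_prev:
                    q = q_ex
            except NonConvergenceError:
                pass
        # adaptive sub-stepping toward the target
        m_lo, q_lo = m_prev, q_prev.copy()
        pending = [m_target]
        halvings = 0
        failed = False
        while pending:
            m_try = pending[-1]
            mv = load_case.moment_vector(m_try)
            try:
                q_sol, ok, iters = _newton(system, q, mv, settings)
            except NonConvergenceError:
                q_sol, ok, iters = q, False, 0
            total_iters += iters
            if ok:
                pending.pop()
                m_lo, q_lo = m_try, q_sol.copy()
                q = q_sol
            else:
                halvings += 1
                if halvings > settings.max_halvings:
                    failed = True
                    break
                pending.append(0.5 * (m_lo + m_try))
                q = q_lo.copy()
        if failed:
            ok_all = False
            converged.append(False)
            moments.append(m_target)
            rom.append(np.nan)
            idp.append(np.nan)
            break
        q_hist.append((m_target, q.copy()))
        U = system.full_displacement(q)
        moments.append(m_target)
        rom.append(compute_rom(q[-3:], load_case))
        idp.append(compute_idp(system.solid.centroid_cauchy(
            U[system.solid.elems]), model.mesh))
        converged.append(True)

    result = SimulationResult(
        load_case.name, np.array(moments), np.array(rom), np.array(idp),
        np.array(converged), stats={"newton_iters": total_iters})
    if return_state:
        result.state = {"q": q, "U": system.full_displacement(q),
                        "system": system}
    if not ok_all:
        result.stats["failed_at_Nmm"] = moments[-1]
    return result


def simulate_curves(model: DiscModel, moment_grid_nm, load_cases=None,
                    newton_tol: float = 1e-6) -> dict:
    """RoM/IDP curves for several load cases at a moment grid given in Nm."""
    if load_cases is None:
        load_cases = list(LOAD_CASES)
    grid = 1000.0 * np.asarray(moment_grid_nm, dtype=float)
    out = {}
    for lc in load_cases:
        settings = SolveSettings(max_moment=grid[-1], moment_grid=grid,
                                 newton_tol=newton_tol)
        out[lc] = solve_static(model, lc, settings)
    return out


def export_state_vtk(model: DiscModel, U: np.ndarray, path) -> None:
    """Write a VTK snapshot of a solved state: nodal displacements plus
    centroid Cauchy stress invariants (pressure, von Mises) as cell data."""
    from .geometry import write_vtk

    system = _MomentSystem(model)
    sig = system.solid.centroid_cauchy(U[system.solid.elems])
    p = -np.trace(sig, axis1=-2, axis2=-1) / 3.0
    dev = sig + p[:, None, None] * _EYE
    vm = np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))
    write_vtk(model.mesh, path,
              cell_data={"pressure_MPa": p, "von_mises_MPa": vm},
              cell_vectors={"fiber_dir_1": model.layout.dirs1,
                            "fiber_dir_2": model.layout.dirs2},
              point_vectors={"displacement_mm": U})


def compute_rom(rotation_vector: np.ndarray, load_case: LoadCase | str) -> float:
    """RoM in degrees: reference-point rotation about the load axis,
    positive in the loading direction."""
    if isinstance(load_case, str):
        load_case = LOAD_CASES[load_case]
    axis = load_case.sign * np.asarray(load_case.axis, dtype=float)
    return float(np.degrees(np.dot(rotation_vector, axis)))


def compute_idp(centroid_stress: np.ndarray, mesh,
                sampling_fraction: float = 0.25) -> float:
    """Intradiscal pressure: volume-weighted mean of ``-tr(sigma)/3`` over
    NP elements within a central sampling sphere (radius =
    ``sampling_fraction`` x NP half-width around the NP centroid)."""
    from .geometry import hex_volumes

    np_mask = mesh.region_kind == 0
    centroids = mesh.node_coords[mesh.elements].mean(axis=1)
    center = mesh.metadata.get("np_center")
    radius = sampling_fraction * mesh.metadata.get("np_half_width", np.inf)
    if center is None:
        vols_all = hex_volumes(mesh)
        center = np.average(centroids[np_mask], axis=0,
                            weights=vols_all[np_mask])
    sel = np_mask & (np.linalg.norm(centroids - center, axis=1) <= radius)
    if not np.any(sel):
        sel = np_mask  # tiny meshes: fall back to the whole NP
    if not np.any(sel):
        raise ValueError("empty IDP sampling region: mesh has no NP elements")
    vols = hex_volumes(mesh)[sel]
    p = -np.trace(centroid_stress[sel], axis1=-2, axis2=-1) / 3.0
    return float(np.average(p, weights=vols))


# ---------------------------------------------------------------------------
# displacement-driven single-element surrogate (verification aid)
# ---------------------------------------------------------------------------


def uniaxial_single_element(c10: float, stretch: float, bulk_penalty=None,
                            n_steps: int = 4) -> float:
    """Axial Cauchy stress of a single incompressible Neo-Hookean hex under
    prescribed uniaxial stretch (lateral faces free).

    Verification surrogate for the solver assembly: the converged homogeneous
    state is compared against the closed-form incompressible solution
    ``sigma = 2 C10 (lambda^2 - 1/lambda)``.
    """
    from .materials import MooneyRivlinParams, mr_cauchy_stress

    p = MooneyRivlinParams(C10=c10, C01=0.0, bulk_penalty=bulk_penalty)
    coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                       [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                      dtype=float)
    elems = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    mats = SolidMaterialArrays(
        c10=np.array([p.C10]), c01=np.array([0.0]),
        bulk=np.array([p.bulk_penalty]), k1=np.zeros(1), k2=np.ones(1),
        kappa=np.zeros(1), a1=np.zeros((1, 3)), a2=np.zeros((1, 3)))
    kern = _SolidKernel(coords, elems, mats)

    # prescribed: symmetry planes x=0, y=0, z=0; top face z-stretch
    presc = {}
    for n, (x, y, z) in enumerate(coords):
        if x == 0:
            presc[3 * n] = 0.0
        if y == 0:
            presc[3 * n + 1] = 0.0
        if z == 0:
            presc[3 * n + 2] = 0.0
    top_dofs = [3 * n + 2 for n, c in enumerate(coords) if c[2] == 1.0]
    free = np.array([d for d in range(24)
                     if d not in presc and d not in top_dofs])

    U = np.zeros(24)
    for step in range(1, n_steps + 1):
        w = (stretch - 1.0) * step / n_steps
        for d in top_dofs:
            U[d] = w
        for _ in range(60):
            f = kern.forces(U.reshape(1, 8, 3)).ravel()
            if np.linalg.norm(f[free]) < 1e-10 * max(1.0, p.C10):
                break
            K = kern.stiffness_fd(U.reshape(1, 8, 3), 1e-7)[0]
            dU = np.linalg.solve(K[np.ix_(free, free)], -f[free])
            U[free] += dU
    F = _EYE + np.einsum("ni,nj->ij", U.reshape(8, 3), kern.dNdXc[0])
    sig = mr_cauchy_stress(F, p)
    return float(sig[2, 2])
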