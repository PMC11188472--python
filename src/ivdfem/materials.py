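"""Constitutive laws for the intervertebral-disc model.

Three material families are implemented:

* **Mooney-Rivlin** (nucleus pulposus and, in the rebar models, the annulus
  ground substance) with an isochoric/volumetric split,

  ``W = C10*(I1b - 3) + C01*(I2b - 3) + (K/2)*(J - 1)**2``

  where ``I1b, I2b`` are the isochoric invariants of the right Cauchy-Green
  tensor and ``K`` is a penalty bulk modulus enforcing near-incompressibility.

* **Holzapfel-Gasser-Ogden (HGO)** for the fiber-reinforced annulus: a
  Neo-Hookean ground substance plus two exponential, tension-only collagen
  fiber families with dispersion ``kappa`` in ``[0, 1/3]``:

  ``W = C10*(I1b - 3) + (K/2)*(J - 1)**2
        + k1/(2 k2) * sum_a [exp(k2 <E_a>^2) - 1]``
  ``E_a = kappa*(I1b - 3) + (1 - 3 kappa)*(I4b_a - 1)``

  with ``<x> = max(x, 0)`` (Macaulay bracket: fibers resist tension only)
  and ``I4b_a`` the isochoric pseudo-invariant of fiber family ``a``.

* **1-D tension-only fiber laws** used by the structural rebar models:
  linear elastic (Young's modulus ``E``) and a tabulated hyperelastic law
  defined directly from a uniaxial engineering strain-stress curve
  (Marlow-type definition restricted to the uniaxial rebar setting, where
  the two are response-identical).

All stresses are in MPa, strains/stretches dimensionless. Cauchy stresses
are obtained analytically from the second Piola-Kirchhoff tensor
``S = 2 dW/dC`` via the push-forward ``sigma = F S F^T / J``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MooneyRivlinParams",
    "HGOParams",
    "LinearFiberParams",
    "TabulatedFiberCurve",
    "mr_energy",
    "mr_cauchy_stress",
    "hgo_energy",
    "hgo_cauchy_stress",
    "fiber_1d_stress",
    "fiber_1d_energy",
    "default_fiber_curve",
]

_EYE = np.eye(3)


class InvertedDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Mooney-Rivlin ground-substance parameters (MPa)."""

    C10: float
    C01: float
    bulk_penalty: float | None = None  # default: 1000 * (C10 + C01)

    def __post_init__(self):
        if self.C10 < 0 or self.C01 < 0 or self.C10 + self.C01 <= 0:
            raise ValueError("require C10 >= 0, C01 >= 0, C10 + C01 > 0")
        if self.bulk_penalty is None:
            object.__setattr__(self, "bulk_penalty", 1000.0 * (self.C10 + self.C01))
        if self.bulk_penalty <= 0:
            raise ValueError("bulk_penalty must be positive")


@dataclass(frozen=True)
class HGOParams:
    """Holzapfel-Gasser-Ogden parameters.

    ``fiber_dirs`` holds the two unit reference fiber directions (rows).
    """

    C10: float
    k1: float
    k2: float
    kappa: float
    fiber_dirs: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0, 0], [1.0, 0, 0]])
    )
    bulk_penalty: float | None = None  # default: 1000 * C10

    def __post_init__(self):
        if self.C10 <= 0:
            raise ValueError("C10 must be positive")
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError("kappa must lie in [0, 1/3]")
        dirs = np.atleast_2d(np.asarray(self.fiber_dirs, dtype=float))
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("fiber directions must be unit vectors")
        object.__setattr__(self, "fiber_dirs", dirs)
        if self.bulk_penalty is None:
            object.__setattr__(self, "bulk_penalty", 1000.0 * self.C10)
        if self.bulk_penalty <= 0:
            raise ValueError("bulk_penalty must be positive")


@dataclass(frozen=True)
class LinearFiberParams:
    """Linear-elastic tension-only rebar fiber.

    ``nu`` is stored for completeness (it parametrizes the 3-D solid the
    value was fitted from) but has no effect on the uniaxial response.
    """

    E: float
    nu: float = 0.375

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")


class TabulatedFiberCurve:
    """Tension-branch uniaxial stress-strain table (engineering strain, MPa).

    Strains must be strictly increasing starting at 0 with stress(0) = 0 and
    non-decreasing stresses. ``out_of_range`` controls behavior past the last
    tabulated strain: ``"clamp"`` (constant tangent-free extension, with a
    warning) or ``"error"``.
    """

    def __init__(self, strain, stress, out_of_range: str = "clamp"):
        strain = np.asarray(strain, dtype=float)
        stress = np.asarray(stress, dtype=float)
        if strain.ndim != 1 or strain.shape != stress.shape or strain.size < 2:
            raise ValueError("strain and stress must be equal-length 1-D arrays")
        if strain[0] != 0.0 or stress[0] != 0.0:
            raise ValueError("curve must start at (0, 0)")
        if np.any(np.diff(strain) <= 0):
            raise ValueError("strains must be strictly increasing")
        if np.any(stress < 0) or np.any(np.diff(stress) < 0):
            raise ValueError("stresses must be non-negative and non-decreasing")
        if out_of_range not in ("clamp", "error"):
            raise ValueError("out_of_range must be 'clamp' or 'error'")
        self.strain = strain
        self.stress = stress
        self.out_of_range = out_of_range
        # cumulative strain energy per unit volume (trapezoid), for energy-based
        # finite elements
        self._energy = np.concatenate(
            [[0.0], np.cumsum(0.5 * (stress[1:] + stress[:-1]) * np.diff(strain))]
        )

    def stress_at(self, strain):
        strain = np.asarray(strain, dtype=float)
        if np.any(strain > self.strain[-1] + 1e-12):
            if self.out_of_range == "error":
                raise ValueError(
                    f"strain {float(np.max(strain)):.4g} beyond tabulated range "
                    f"(max {self.strain[-1]:.4g})"
                )
            warnings.warn(
                "fiber strain beyond tabulated range; stress clamped at the "
                "last tabulated value",
                stacklevel=2,
            )
        s = np.interp(np.clip(strain, 0.0, self.strain[-1]), self.strain, self.stress)
        return s if s.ndim else float(s)

    def energy_at(self, strain):
        """Strain energy density (MPa) of the tension branch at given strain."""
        strain = np.asarray(strain, dtype=float)
        e_clamped = np.clip(strain, 0.0, self.strain[-1])
        w = np.interp(e_clamped, self.strain, self._energy)
        # clamped extension continues at constant stress
        w = w + self.stress[-1] * np.maximum(strain - self.strain[-1], 0.0)
        return w if w.ndim else float(w)

    @classmethod
    def from_csv(cls, path_or_buffer, **kwargs) -> "TabulatedFiberCurve":
        """Read a 2-column CSV ``strain,stress_MPa`` (header required)."""
        import pandas as pd

        df = pd.read_csv(path_or_buffer)
        if df.shape[1] < 2:
            raise ValueError("expected 2 columns: strain, stress_MPa")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), **kwargs)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"strain": self.strain, "stress_MPa": self.stress}).to_csv(
            path, index=False
        )


def default_fiber_curve() -> TabulatedFiberCurve:
    """Synthetic placeholder collagen-fiber stress-strain curve.

    An exponential-toe curve ``sigma = c1*(exp(c2*eps) - 1)`` sampled up to
    25% strain, emulating the toe-then-stiffening shape of annulus collagen
    bundle data. It is a synthetic stand-in, not a digitized literature curve.
    """
    eps = np.linspace(0.0, 0.25, 21)
    c1, c2 = 1.5, 22.0
    return TabulatedFiberCurve(eps, c1 * (np.exp(c2 * eps) - 1.0))


# ---------------------------------------------------------------------------
# invariants and analytic stresses (batched: F may be (..., 3, 3))
# ---------------------------------------------------------------------------


def _check_F(F):
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedDeformationError("deformation gradient has det(F) <= 0")
    return F, J


def _invariants(F):
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    trC2 = np.trace(C @ C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - trC2)
    return C, I1, I2


def mr_energy(F, p: MooneyRivlinParams):
    """Mooney-Rivlin strain energy density (MPa) with volumetric penalty."""
    F, J = _check_F(F)
    _, I1, I2 = _invariants(F)
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    W = p.C10 * (I1b - 3.0) + p.C01 * (I2b - 3.0) + 0.5 * p.bulk_penalty * (J - 1) ** 2
    return W if np.ndim(W) else float(W)


def _mr_pk2(F, J, C10, C01, K):
    """Second Piola-Kirchhoff stress of the Mooney-Rivlin split (batched)."""
    C, I1, I2 = _invariants(F)
    Cinv = np.linalg.inv(C)
    J23 = J ** (-2.0 / 3.0)
    J43 = J ** (-4.0 / 3.0)
    I1e = I1[..., None, None]
    I2e = I2[..., None, None]
    S = 2.0 * C10 * J23[..., None, None] * (_EYE - (I1e / 3.0) * Cinv)
    S = S + 2.0 * C01 * J43[..., None, None] * (
        I1e * _EYE - C - (2.0 * I2e / 3.0) * Cinv
    )
    S = S + (K * (J - 1.0) * J)[..., None, None] * Cinv
    return S


def mr_cauchy_stress(F, p: MooneyRivlinParams):
    """Cauchy stress (MPa, symmetric 3x3) of the Mooney-Rivlin law."""
    F, J = _check_F(F)
    S = _mr_pk2(F, J, p.C10, p.C01, p.bulk_penalty)
    sig = F @ S @ np.swapaxes(F, -1, -2) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


def _hgo_fiber_terms(F, J, dirs, k1, k2, kappa):
    """Per-family (E_a, dW/dE_a, I4_a) with the Macaulay tension switch."""
    C, I1, _ = _invariants(F)
    J23 = J ** (-2.0 / 3.0)
    I1b = J23 * I1
    out = []
    for a in dirs:
        I4 = np.einsum("i,...ij,j->...", a, C, a)
        I4b = J23 * I4
        E = kappa * (I1b - 3.0) + (1.0 - 3.0 * kappa) * (I4b - 1.0)
        Epos = np.maximum(E, 0.0)
        dW_dE = k1 * Epos * np.exp(k2 * Epos**2)
        out.append((Epos, dW_dE, I4))
    return out, C, I1, J23


def hgo_energy(F, p: HGOParams):
    """HGO strain energy density (MPa): Neo-Hookean matrix + fiber families."""
    F, J = _check_F(F)
    terms, _, I1, J23 = _hgo_fiber_terms(F, J, p.fiber_dirs, p.k1, p.k2, p.kappa)
    W = p.C10 * (J23 * I1 - 3.0) + 0.5 * p.bulk_penalty * (J - 1.0) ** 2
    if p.k1 > 0:
        for Epos, _, _ in terms:
            W = W + p.k1 / (2.0 * p.k2) * (np.exp(p.k2 * Epos**2) - 1.0)
    return W if np.ndim(W) else float(W)


def hgo_cauchy_stress(F, p: HGOParams):
    """Cauchy stress (MPa) of the HGO law; fiber terms active in tension only."""
    F, J = _check_F(F)
    S = _mr_pk2(F, J, p.C10, 0.0, p.bulk_penalty)
    terms, C, I1, J23 = _hgo_fiber_terms(F, J, p.fiber_dirs, p.k1, p.k2, p.kappa)
    if p.k1 > 0:
        Cinv = np.linalg.inv(C)
        I1e = I1[..., None, None]
        dI1b = J23[..., None, None] * (_EYE - (I1e / 3.0) * Cinv)
        for a, (Epos, dW_dE, I4) in zip(p.fiber_dirs, terms):
            aa = np.multiply.outer(a, a)
            dI4b = J23[..., None, None] * (aa - (I4[..., None, None] / 3.0) * Cinv)
            S = S + 2.0 * dW_dE[..., None, None] * (
                p.kappa * dI1b + (1.0 - 3.0 * p.kappa) * dI4b
            )
    sig = F @ S @ np.swapaxes(F, -1, -2) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


# ---------------------------------------------------------------------------
# 1-D tension-only rebar fiber laws
# ---------------------------------------------------------------------------


def fiber_1d_stress(stretch, material, multiplier: float = 1.0):
    """Uniaxial tension-only fiber stress (MPa, nominal).

    Zero for ``stretch <= 1``; for the linear law ``multiplier*E*(stretch-1)``;
    for the tabulated law the interpolated tabulated stress at engineering
    strain ``stretch - 1``, scaled by ``multiplier``. Continuous at
    ``stretch = 1``.
    """
    stretch = np.asarray(stretch, dtype=float)
    if np.any(stretch <= 0):
        raise ValueError("stretch must be positive")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    eps = np.maximum(stretch - 1.0, 0.0)
    if isinstance(material, LinearFiberParams):
        s = multiplier * material.E * eps
    elif isinstance(material, TabulatedFiberCurve):
        s = multiplier * np.asarray(material.stress_at(eps))
    else:
        raise TypeError(f"unsupported fiber material: {type(material).__name__}")
    return s if s.ndim else float(s)


def fiber_1d_energy(stretch, material, multiplier: float = 1.0):
    """Strain energy density (MPa) of the tension-only fiber laws."""
    stretch = np.asarray(stretch, dtype=float)
    eps = np.maximum(stretch - 1.0, 0.0)
    if isinstance(material, LinearFiberParams):
        w = multiplier * 0.5 * material.E * eps**2
    elif isinstance(material, TabulatedFiberCurve):
        w = multiplier * np.asarray(material.energy_at(eps))
    else:
        raise TypeError(f"unsupported fiber material: {type(material).__name__}")
    return w if w.ndim else float(w)
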