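"""Collagen-fiber architecture of the annulus fibrosus.

Each annulus lamella carries two criss-crossing collagen fiber families at
+/- theta to the transverse (xy) plane, where theta varies with radial layer
and circumferential subregion:

``theta(L, s) = alpha * (1 + alpha_r * (L - 1)) * (1 + alpha_c * s)``

with layer ``L`` counted from the outside (L = 1 outermost) and subregion
index ``s`` = 0 (A, anterior) .. 4 (E, posterior). A radial scaling
``alpha_r = 0.1`` therefore means a 10% angle increase per layer step, and
``alpha_c`` the analogous per-subregion step. Fiber *stiffness* scales the
same way: the HGO parameters ``k1, k2`` via per-step fractional changes
``(k1c, k1r, k2c, k2r)``, and the rebar fiber laws via a single multiplier
``lambda * (1 + lambda_r*(L-1)) * (1 + lambda_c*s)`` applied to the Young's
modulus (linear rebars) or to the stress ordinate of the tabulated curve
(nonlinear rebars). Radial and circumferential steps combine
multiplicatively, which keeps each one-directional definition exact when
the other scaling is zero and preserves positivity over the admissible
parameter ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SUBREGION_LETTERS, HexMesh

__all__ = [
    "FiberAngleParams",
    "HGOStiffnessScaling",
    "RebarStiffnessScaling",
    "FiberLayout",
    "fiber_angle",
    "hgo_scaled_params",
    "rebar_stiffness_multiplier",
    "build_fiber_layout",
]


def _subregion_to_index(subregion) -> int:
    if isinstance(subregion, str):
        subregion = SUBREGION_LETTERS.index(subregion.upper())
    return int(subregion)


@dataclass(frozen=True)
class FiberAngleParams:
    """Base fiber angle (degrees to the transverse plane) and its scalings."""

    alpha: float = 30.0
    alpha_r: float = 0.0
    alpha_c: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 90.0:
            raise ValueError("alpha must lie in (0, 90) degrees")
        if self.alpha_r < 0 or self.alpha_c < 0:
            raise ValueError("angle scalings must be non-negative")


@dataclass(frozen=True)
class HGOStiffnessScaling:
    """Per-step fractional changes of k1/k2 (circumferential c, radial r)."""

    k1c: float = 0.0
    k2c: float = 0.0
    k1r: float = 0.0
    k2r: float = 0.0

    def __post_init__(self):
        for name in ("k1c", "k2c", "k1r", "k2r"):
            v = getattr(self, name)
            if not -0.25 < v <= 0.0:
                raise ValueError(f"{name} must lie in (-0.25, 0] "
                                 "(stiffness can only decrease, and must stay "
                                 "positive over 4 steps)")


@dataclass(frozen=True)
class RebarStiffnessScaling:
    """Global rebar stiffness scale and its per-step fractional changes."""

    lambda_: float = 1.0
    lambda_c: float = 0.0
    lambda_r: float = 0.0

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        for name in ("lambda_c", "lambda_r"):
            v = getattr(self, name)
            if not -0.25 < v <= 0.0:
                raise ValueError(f"{name} must lie in (-0.25, 0]")


def fiber_angle(p: FiberAngleParams, layer: int, subregion) -> float:
    """Fiber angle (degrees) for a given AF layer (1 = outermost) and subregion."""
    s = _subregion_to_index(subregion)
    ang = p.alpha * (1.0 + p.alpha_r * (layer - 1)) * (1.0 + p.alpha_c * s)
    if ang >= 90.0:
        raise ValueError(
            f"scaled fiber angle {ang:.2f} deg >= 90 deg at layer {layer}, "
            f"subregion {SUBREGION_LETTERS[s]}"
        )
    return ang


def hgo_scaled_params(k1: float, k2: float, s: HGOStiffnessScaling,
                      layer: int, subregion) -> tuple[float, float]:
    """Regionally scaled (k1, k2) for the HGO fiber term."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("k1 and k2 must be positive before scaling")
    si = _subregion_to_index(subregion)
    k1s = k1 * (1.0 + s.k1r * (layer - 1)) * (1.0 + s.k1c * si)
    k2s = k2 * (1.0 + s.k2r * (layer - 1)) * (1.0 + s.k2c * si)
    if k1s <= 0 or k2s <= 0:
        raise ValueError("scaled fiber stiffness became non-positive")
    return k1s, k2s


def rebar_stiffness_multiplier(s: RebarStiffnessScaling, layer: int,
                               subregion) -> float:
    """Dimensionless stiffness multiplier for rebar fibers at (layer, subregion)."""
    si = _subregion_to_index(subregion)
    mult = s.lambda_ * (1.0 + s.lambda_r * (layer - 1)) * (1.0 + s.lambda_c * si)
    if mult <= 0:
        raise ValueError("rebar stiffness multiplier became non-positive")
    return mult


class FiberLayout:
    """Per-element fiber directions and effective angles for the AF.

    ``dirs1``/``dirs2`` are (E, 3) unit vectors (zero rows for NP elements);
    ``angles`` holds the effective angle in degrees (NaN for NP).
    """

    def __init__(self, dirs1, dirs2, angles, angle_params: FiberAngleParams):
        self.dirs1 = np.asarray(dirs1, dtype=float)
        self.dirs2 = np.asarray(dirs2, dtype=float)
        self.angles = np.asarray(angles, dtype=float)
        self.angle_params = angle_params


def circumferential_tangent(xy: np.ndarray, a: float, b: float) -> np.ndarray:
    """Unit circumferential tangent(s) in the transverse plane.

    Computed from the gradient of the elliptical angular coordinate
    ``theta = atan2(y/b, x/a)``: the tangent is grad(theta) rotated into the
    direction of increasing theta, i.e. proportional to (-a*sin t, b*cos t)
    at parameter angle t.
    """
    xy = np.atleast_2d(xy)
    t = np.arctan2(xy[:, 1] / b, xy[:, 0] / a)
    tang = np.column_stack([-a * np.sin(t), b * np.cos(t)])
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("degenerate circumferential tangent (point at center?)")
    return tang / norm


def build_fiber_layout(mesh: HexMesh, p: FiberAngleParams) -> FiberLayout:
    """Two unit fiber directions per AF element at +/- theta to the xy-plane.

    Directions lie in the plane spanned by the local circumferential tangent
    and the axial (z) direction -- the local lamella tangent plane of the
    extruded geometry.
    """
    E = mesh.n_elements
    dirs1 = np.zeros((E, 3))
    dirs2 = np.zeros((E, 3))
    angles = np.full(E, np.nan)
    af = np.where(mesh.region_kind == 1)[0]
    if len(af) == 0:
        raise ValueError("mesh has no AF elements")
    params = mesh.metadata.get("params")
    a = params.lateral_width / 2.0 if params else 1.0
    b = params.ap_depth / 2.0 if params else 1.0
    centroids = mesh.node_coords[mesh.elements[af]].mean(axis=1)
    tang = circumferential_tangent(centroids[:, :2], a, b)
    for row, e in enumerate(af):
        lay = int(mesh.region_layer[e])
        sub = int(mesh.region_subregion[e])
        ang = np.deg2rad(fiber_angle(p, lay, sub))
        t3 = np.array([tang[row, 0], tang[row, 1], 0.0])
        z3 = np.array([0.0, 0.0, 1.0])
        dirs1[e] = np.cos(ang) * t3 + np.sin(ang) * z3
        dirs2[e] = np.cos(ang) * t3 - np.sin(ang) * z3
        angles[e] = np.rad2deg(ang)
    return FiberLayout(dirs1, dirs2, angles, p)
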