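"""Assembly of complete disc models (geometry + materials + fiber layout).

``MaterialConfig`` is the flat parameter vector the sensitivity analysis and
the genetic-algorithm calibration operate on; ``build_disc_model`` turns a
geometry and such a configuration into a ``DiscModel`` with per-element
material arrays ready for the nonlinear solver.

Three model kinds share one mesh:

* ``hgo`` -- NP: Mooney-Rivlin; AF solids: HGO with regionally scaled
  (k1, k2) and two per-element fiber directions. No membranes.
* ``linear_rebar`` / ``nonlinear_rebar`` -- NP and AF solids: Mooney-Rivlin;
  fibers carried by rebar-reinforced membrane surfaces embedded at the
  lamellar interfaces, with a linear-elastic or tabulated tension-only
  fiber law scaled by the lambda multipliers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import fibers as fib
from .geometry import DiscGeometryParams, HexMesh, build_disc
from .materials import (LinearFiberParams, TabulatedFiberCurve,
                        default_fiber_curve)

__all__ = ["MaterialConfig", "DiscModel", "build_disc_model",
            "SolidMaterialArrays", "MODEL_KINDS"]

MODEL_KINDS = ("hgo", "linear_rebar", "nonlinear_rebar")

# Literature median values (MPa / dimensionless) used as sensitivity-analysis
# centers and calibration defaults. For the scaling parameters without
# literature medians, the midpoint of the admissible range is used
# (kappa in [0, 0.33]; k/lambda scalings in [-0.2, 0]; lambda in [0.3, 2];
# alpha_c in [0, 0.3]; alpha_r in [0, 0.2]).
MEDIANS = {
    "c10n": 0.12, "c01n": 0.03,
    "c10a_hgo": 0.26,
    "c10a_mr": 0.19, "c01a_mr": 0.05,
    "k1": 2.8, "k2": 90.0, "kappa": 0.165,
    "k1c": -0.1, "k2c": -0.1, "k1r": -0.1, "k2r": -0.1,
    "lambda_": 1.15, "lambda_c": -0.1, "lambda_r": -0.1,
    "nu": 0.375,
    "alpha": 30.0, "alpha_c": 0.15, "alpha_r": 0.1,
}


@dataclass
class MaterialConfig:
    """Material parameter vector for one disc model.

    Stresses in MPa, angles in degrees. ``fiber_E`` is the linear rebar
    Young's modulus; ``fiber_curve`` the tabulated rebar law (defaults to a
    synthetic exponential-toe placeholder curve). ``bulk_scale`` sets the
    incompressibility penalty as a multiple of the leading shear parameter.
    """

    model_kind: str = "hgo"
    c10n: float = MEDIANS["c10n"]
    c01n: float = MEDIANS["c01n"]
    c10a_hgo: float = MEDIANS["c10a_hgo"]
    c10a_mr: float = MEDIANS["c10a_mr"]
    c01a_mr: float = MEDIANS["c01a_mr"]
    k1: float = MEDIANS["k1"]
    k2: float = MEDIANS["k2"]
    kappa: float = MEDIANS["kappa"]
    k1c: float = MEDIANS["k1c"]
    k2c: float = MEDIANS["k2c"]
    k1r: float = MEDIANS["k1r"]
    k2r: float = MEDIANS["k2r"]
    lambda_: float = MEDIANS["lambda_"]
    lambda_c: float = MEDIANS["lambda_c"]
    lambda_r: float = MEDIANS["lambda_r"]
    nu: float = MEDIANS["nu"]
    alpha: float = MEDIANS["alpha"]
    alpha_c: float = MEDIANS["alpha_c"]
    alpha_r: float = MEDIANS["alpha_r"]
    fiber_E: float = 220.0
    fiber_curve: TabulatedFiberCurve | None = None
    bulk_scale: float = 1000.0
    membrane_thickness: float = 0.1  # mm
    rebar_area: float = 0.1          # mm^2
    rebar_spacing: float = 0.5       # mm

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.fiber_curve is None and self.model_kind == "nonlinear_rebar":
            self.fiber_curve = default_fiber_curve()

    @classmethod
    def median(cls, model_kind: str = "hgo", **overrides) -> "MaterialConfig":
        return cls(model_kind=model_kind, **overrides)

    def replace(self, **kwargs) -> "MaterialConfig":
        return dataclasses.replace(self, **kwargs)

    def angle_params(self) -> fib.FiberAngleParams:
        return fib.FiberAngleParams(self.alpha, self.alpha_r, self.alpha_c)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("fiber_curve")
        return d


@dataclass
class SolidMaterialArrays:
    """Per-element solid material parameters (vectorized over elements)."""

    c10: np.ndarray
    c01: np.ndarray
    bulk: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    kappa: np.ndarray
    a1: np.ndarray  # (E, 3) fiber family 1 (zero rows where fiber-free)
    a2: np.ndarray


@dataclass
class MembraneSet:
    """Rebar-reinforced membrane surfaces embedded at lamellar interfaces."""

    quads: np.ndarray        # (Q, 4) node connectivity
    layer: np.ndarray        # (Q,)
    subregion: np.ndarray    # (Q,)
    dirs1: np.ndarray        # (Q, 3) reference fiber directions (unit)
    dirs2: np.ndarray
    multiplier: np.ndarray   # (Q,) rebar stiffness multipliers
    membrane_thickness: float
    rebar_thickness: float   # equivalent thickness = rebar_area / spacing
    c10: float               # membrane ground substance (Mooney-Rivlin)
    c01: float
    fiber_material: object   # LinearFiberParams | TabulatedFiberCurve

    @property
    def n_quads(self) -> int:
        return len(self.quads)


def embed_rebar_surfaces(mesh: HexMesh, layout: fib.FiberLayout,
                         membrane_thickness: float, rebar_area: float,
                         rebar_spacing: float,
                         rebar_scaling: fib.RebarStiffnessScaling | None = None,
                         ground_c10: float = MEDIANS["c10a_mr"],
                         ground_c01: float = MEDIANS["c01a_mr"],
                         fiber_material=None) -> MembraneSet:
    """Build membrane patches on the outer boundary surface of each AF layer.

    Each patch carries the AF ground-substance Mooney-Rivlin response at
    ``membrane_thickness`` plus two tension-only rebar families of
    equivalent thickness ``rebar_area / rebar_spacing`` along the criss-cross
    fiber directions of its (layer, subregion).
    """
    if rebar_scaling is None:
        rebar_scaling = fib.RebarStiffnessScaling()
    if fiber_material is None:
        fiber_material = LinearFiberParams(E=220.0)
    if rebar_spacing <= 0 or membrane_thickness <= 0 or rebar_area < 0:
        raise ValueError("membrane/rebar geometry must be positive "
                         "(rebar_area may be zero)")
    surf = mesh.metadata.get("layer_surface_quads")
    if not surf:
        raise ValueError("mesh does not expose AF layer interface surfaces")
    params = mesh.metadata["params"]
    a = params.lateral_width / 2.0
    b = params.ap_depth / 2.0
    p = layout.angle_params

    quads, lay_arr, sub_arr = [], [], []
    for lay, faces in sorted(surf.items()):
        quads.append(faces)
        lay_arr.append(np.full(len(faces), lay))
    quads = np.vstack(quads)
    lay_arr = np.concatenate(lay_arr)
    centroids = mesh.node_coords[quads].mean(axis=1)
    from .geometry import _subregion_index
    sub_arr = _subregion_index(centroids[:, :2], params.n_subregions)

    tang = fib.circumferential_tangent(centroids[:, :2], a, b)
    Q = len(quads)
    dirs1 = np.zeros((Q, 3))
    dirs2 = np.zeros((Q, 3))
    mult = np.zeros(Q)
    z3 = np.array([0.0, 0.0, 1.0])
    for q in range(Q):
        ang = np.deg2rad(fib.fiber_angle(p, int(lay_arr[q]), int(sub_arr[q])))
        t3 = np.array([tang[q, 0], tang[q, 1], 0.0])
        dirs1[q] = np.cos(ang) * t3 + np.sin(ang) * z3
        dirs2[q] = np.cos(ang) * t3 - np.sin(ang) * z3
        mult[q] = fib.rebar_stiffness_multiplier(
            rebar_scaling, int(lay_arr[q]), int(sub_arr[q]))
    return MembraneSet(quads, lay_arr, sub_arr, dirs1, dirs2, mult,
                       membrane_thickness, rebar_area / rebar_spacing,
                       ground_c10, ground_c01, fiber_material)


@dataclass
class DiscModel:
    """A solvable disc model: mesh, reference points and material arrays."""

    mesh: HexMesh
    ref_points: dict
    config: MaterialConfig
    layout: fib.FiberLayout
    solids: SolidMaterialArrays
    membranes: MembraneSet | None = None


def _solid_arrays(mesh: HexMesh, cfg: MaterialConfig,
                  layout: fib.FiberLayout) -> SolidMaterialArrays:
    E = mesh.n_elements
    c10 = np.empty(E)
    c01 = np.empty(E)
    bulk = np.empty(E)
    k1 = np.zeros(E)
    k2 = np.ones(E)
    kappa = np.zeros(E)
    np_mask = mesh.region_kind == 0
    af = ~np_mask
    c10[np_mask] = cfg.c10n
    c01[np_mask] = cfg.c01n
    bulk[np_mask] = cfg.bulk_scale * (cfg.c10n + cfg.c01n)
    if cfg.model_kind == "hgo":
        c10[af] = cfg.c10a_hgo
        c01[af] = 0.0
        bulk[af] = cfg.bulk_scale * cfg.c10a_hgo
        scaling = fib.HGOStiffnessScaling(cfg.k1c, cfg.k2c, cfg.k1r, cfg.k2r)
        kappa[af] = cfg.kappa
        for e in np.where(af)[0]:
            k1[e], k2[e] = fib.hgo_scaled_params(
                cfg.k1, cfg.k2, scaling, int(mesh.region_layer[e]),
                int(mesh.region_subregion[e]))
    else:
        c10[af] = cfg.c10a_mr
        c01[af] = cfg.c01a_mr
        bulk[af] = cfg.bulk_scale * (cfg.c10a_mr + cfg.c01a_mr)
    return SolidMaterialArrays(c10, c01, bulk, k1, k2, kappa,
                               layout.dirs1.copy(), layout.dirs2.copy())


def build_disc_model(geom: DiscGeometryParams | HexMesh,
                     config: MaterialConfig,
                     ref_points: dict | None = None) -> DiscModel:
    """Build a ``DiscModel`` from geometry parameters (or a prebuilt mesh)."""
    if isinstance(geom, HexMesh):
        mesh = geom
        if ref_points is None:
            raise ValueError("ref_points required when passing a prebuilt mesh")
    else:
        mesh, ref_points = build_disc(geom)
    layout = fib.build_fiber_layout(mesh, config.angle_params())
    solids = _solid_arrays(mesh, config, layout)
    membranes = None
    if config.model_kind != "hgo":
        if config.model_kind == "linear_rebar":
            fiber_material = LinearFiberParams(E=config.fiber_E, nu=config.nu)
        else:
            fiber_material = config.fiber_curve or default_fiber_curve()
        membranes = embed_rebar_surfaces(
            mesh, layout, config.membrane_thickness, config.rebar_area,
            config.rebar_spacing,
            rebar_scaling=fib.RebarStiffnessScaling(
                config.lambda_, config.lambda_c, config.lambda_r),
            ground_c10=config.c10a_mr, ground_c01=config.c01a_mr,
            fiber_material=fiber_material)
    return DiscModel(mesh, ref_points, config, layout, solids, membranes)
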