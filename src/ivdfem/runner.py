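"""Forward-simulation service shared by sensitivity analysis and calibration.

A :class:`ForwardRunner` owns one mesh (built once) and evaluates disc-model
configurations on it, returning moment-RoM/IDP curves on a fixed moment
grid. Parameter dictionaries use the :class:`~ivdfem.model.MaterialConfig`
field names.
"""

from __future__ import annotations

import numpy as np

from .geometry import DiscGeometryParams, build_disc
from .model import MaterialConfig, build_disc_model
from .solver import LOAD_CASES, SolveSettings, solve_static

__all__ = ["ForwardRunner", "ForwardFailure"]


class ForwardFailure(RuntimeError):
    """A forward solve failed to converge at one or more moments."""


class ForwardRunner:
    """Evaluate material configurations on a shared disc mesh.

    Parameters
    ----------
    geometry : DiscGeometryParams
    moment_grid_nm : increasing grid of applied moments in Nm
    load_cases : subset of flexion/extension/lateral_bending/axial_rotation
    """

    def __init__(self, geometry: DiscGeometryParams | None = None,
                 moment_grid_nm=(1.0, 2.5, 5.0, 7.5),
                 load_cases=tuple(LOAD_CASES), newton_tol: float = 1e-6):
        self.geometry = geometry or DiscGeometryParams()
        self.mesh, self.ref_points = build_disc(self.geometry)
        self.moment_grid_nm = np.asarray(moment_grid_nm, dtype=float)
        self.load_cases = tuple(load_cases)
        self.newton_tol = newton_tol
        self.n_solves = 0

    def config(self, model_kind: str, values: dict | None = None,
               **base) -> MaterialConfig:
        merged = dict(base)
        merged.update(values or {})
        return MaterialConfig(model_kind=model_kind, **merged)

    def curves(self, config: MaterialConfig, strict: bool = True) -> dict:
        """Per-load-case ``SimulationResult`` at the runner's moment grid."""
        model = build_disc_model(self.mesh, config, self.ref_points)
        settings = SolveSettings(max_moment=1000.0 * self.moment_grid_nm[-1],
                                 moment_grid=1000.0 * self.moment_grid_nm,
                                 newton_tol=self.newton_tol)
        out = {}
        for lc in self.load_cases:
            res = solve_static(model, lc, settings)
            self.n_solves += 1
            if strict and not res.converged.all():
                raise ForwardFailure(
                    f"{lc}: failed at moments "
                    f"{res.moments[~res.converged] / 1000.0} Nm")
            out[lc] = res
        return out

    def rom_curves(self, config: MaterialConfig) -> dict:
        """Load case -> RoM array (degrees) aligned with the moment grid."""
        return {lc: r.rom[1:] for lc, r in self.curves(config).items()}

    def responses(self, config: MaterialConfig) -> dict:
        """(load_case, metric) -> response at the grid's final moment."""
        res = self.curves(config)
        out = {}
        for lc, r in res.items():
            out[(lc, "rom")] = float(r.rom[-1])
            out[(lc, "idp")] = float(r.idp[-1])
        return out
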