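"""Synthetic "in vitro" datasets standing in for the unavailable references.

The calibration and validation references (stepwise-reduction RoM curves of
disc-only lumbar segments up to 7.5 Nm, IDP curves, and an independent RoM
dataset up to 8 Nm) are not deposited anywhere, so this module generates
datasets with the same structure: per-load-case moment-RoM curves (degrees,
concave-stiffening shape) and moment-IDP curves (MPa), with optional
specimen-level multiplicative log-normal noise (responses are positive
scale quantities). Two sources are available:

* the package's own forward model at chosen "truth" parameters -- the
  workhorse for parameter-recovery and order-robustness experiments, and
* a parametric saturating-exponential shape
  ``RoM(M) = a (1 - exp(-M/b)) + c M`` (monotone, stiffening, zero at zero
  moment), with a linear ``IDP(M) = d + e M`` variant -- emulating the
  published experimental curve shapes without claiming equivalence to the
  real specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ExperimentalDataset
from .model import MaterialConfig
from .runner import ForwardRunner
from .solver import LOAD_CASES

__all__ = [
    "SyntheticProtocol",
    "generate_from_forward_model",
    "generate_parametric_sigmoid",
    "CALIBRATION_SHAPES",
    "VALIDATION_SHAPES",
    "IDP_SHAPES",
]

# Shape parameters (a: saturation amplitude in degrees, b: saturation moment
# scale in Nm, c: residual linear slope deg/Nm) chosen to land in the RoM
# range reported for disc-only L4-L5 segments. The validation-like flavor is
# deliberately stiffer in extension than the calibration-like one.
CALIBRATION_SHAPES = {
    "flexion": (6.0, 3.0, 0.30),
    "extension": (4.0, 2.5, 0.25),
    "lateral_bending": (5.0, 3.0, 0.25),
    "axial_rotation": (2.5, 2.0, 0.15),
}
VALIDATION_SHAPES = {
    "flexion": (6.5, 3.0, 0.30),
    "extension": (2.5, 2.0, 0.15),
    "lateral_bending": (5.5, 3.0, 0.25),
    "axial_rotation": (3.0, 2.0, 0.15),
}
# IDP(M) = d + e*M (MPa, Nm)
IDP_SHAPES = {
    "flexion": (0.0, 0.050),
    "extension": (0.0, 0.030),
    "lateral_bending": (0.0, 0.040),
    "axial_rotation": (0.0, 0.020),
}


@dataclass
class SyntheticProtocol:
    """Loading protocol and noise model of a synthetic dataset.

    ``noise_sd`` is the log-scale standard deviation of the multiplicative
    log-normal specimen noise (mean-one); 0 gives exact curves.
    """

    moment_grid_nm: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 2.5, 5.0, 7.5]))
    load_cases: tuple = tuple(LOAD_CASES)
    n_specimens: int = 8
    noise_sd: float = 0.1
    seed: int = 0
    metric: str = "rom"

    def __post_init__(self):
        self.moment_grid_nm = np.asarray(self.moment_grid_nm, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.moment_grid_nm) and (
                self.moment_grid_nm[0] <= 0
                or np.any(np.diff(self.moment_grid_nm) <= 0)):
            raise ValueError("moment grid must be increasing and start > 0")
        if self.metric not in ("rom", "idp"):
            raise ValueError("metric must be 'rom' or 'idp'")


def _apply_specimen_noise(curves: dict, protocol: SyntheticProtocol):
    """Average of per-specimen noisy curves; returns (means, sds)."""
    if protocol.noise_sd == 0:
        return dict(curves), {lc: np.zeros_like(c) for lc, c in curves.items()}
    rng = np.random.default_rng(protocol.seed)
    means, sds = {}, {}
    sd = protocol.noise_sd
    for lc in protocol.load_cases:
        c = curves[lc]
        # mean-one log-normal: E[exp(N(-sd^2/2, sd^2))] = 1
        noise = rng.lognormal(-0.5 * sd * sd, sd,
                              size=(protocol.n_specimens, len(c)))
        specimens = c[None, :] * noise
        means[lc] = specimens.mean(axis=0)
        sds[lc] = specimens.std(axis=0, ddof=1)
    return means, sds


def generate_from_forward_model(truth: MaterialConfig,
                                protocol: SyntheticProtocol,
                                runner: ForwardRunner | None = None
                                ) -> ExperimentalDataset:
    """Dataset whose mean curves derive from the forward model at ``truth``.

    With ``noise_sd = 0`` the dataset reproduces the forward curves exactly,
    which makes it the reference for self-consistency and parameter-recovery
    experiments. Raises :class:`ForwardFailure` listing the failing moments
    if the forward model does not converge on the grid.
    """
    if runner is None:
        runner = ForwardRunner(moment_grid_nm=protocol.moment_grid_nm,
                               load_cases=protocol.load_cases)
    res = runner.curves(truth)  # strict: raises ForwardFailure
    if protocol.metric == "rom":
        curves = {lc: r.rom[1:].copy() for lc, r in res.items()}
    else:
        curves = {lc: r.idp[1:].copy() for lc, r in res.items()}
    means, sds = _apply_specimen_noise(curves, protocol)
    return ExperimentalDataset(protocol.metric, protocol.moment_grid_nm,
                               means, sds)


def sigmoid_rom(moment_nm, a: float, b: float, c: float):
    """Concave-stiffening moment-rotation shape ``a(1 - exp(-M/b)) + cM``."""
    m = np.asarray(moment_nm, dtype=float)
    return a * (1.0 - np.exp(-m / b)) + c * m


def generate_parametric_sigmoid(shapes: dict | None,
                                protocol: SyntheticProtocol
                                ) -> ExperimentalDataset:
    """Dataset from the parametric curve family.

    ``shapes`` maps load cases to (a, b, c) for RoM data or (d, e) for IDP
    data; defaults to the calibration-like RoM / IDP shapes.
    """
    if shapes is None:
        shapes = (CALIBRATION_SHAPES if protocol.metric == "rom"
                  else IDP_SHAPES)
    curves = {}
    for lc in protocol.load_cases:
        p = shapes[lc]
        if protocol.metric == "rom":
            a, b, c = p
            if a < 0 or b <= 0 or c < 0 or (a == 0 and c == 0):
                raise ValueError(f"{lc}: non-monotone or degenerate shape")
            curves[lc] = sigmoid_rom(protocol.moment_grid_nm, a, b, c)
        else:
            d, e = p
            if e < 0 or d < 0:
                raise ValueError(f"{lc}: decreasing IDP shape")
            curves[lc] = d + e * protocol.moment_grid_nm
    means, sds = _apply_specimen_noise(curves, protocol)
    return ExperimentalDataset(protocol.metric, protocol.moment_grid_nm,
                               means, sds)
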