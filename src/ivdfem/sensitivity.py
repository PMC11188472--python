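"""One-factor-at-a-time (OFAT) sensitivity analysis.

Each model parameter is varied alone over its admissible range while all
others stay at their median values; the response change of the disc model
(range of motion and intradiscal pressure, four load cases, pure 5 Nm
moments) is expressed as a dimensionless sensitivity score

``S = (percent change of the response) / (percent change of the parameter)``

relative to the shared all-median reference run. The per-parameter score for
a (load case, metric) pair is the signed mean of the scores of the four
variations; a parameter is selected for calibration when the absolute value
of at least one of its eight scores reaches the critical threshold
(default 0.1, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MEDIANS

__all__ = [
    "ParameterSpec",
    "SensitivityScore",
    "parameter_specs",
    "ofat_design",
    "sensitivity_score_single",
    "aggregate_scores",
    "select_parameters",
    "run_ofat",
]

METRICS = ("rom", "idp")

# Parameter vectors of the two models entering the sensitivity analysis
# (the nonlinear rebar model shares the linear one's definition except for
# the fiber law and is therefore not analyzed separately).
HGO_PARAMS = ("c10n", "c01n", "c10a_hgo", "k1", "k2", "kappa", "alpha",
              "k1c", "k2c", "k1r", "k2r", "alpha_c", "alpha_r")
REBAR_PARAMS = ("c10n", "c01n", "c10a_mr", "c01a_mr", "lambda_", "nu",
                "alpha", "lambda_c", "lambda_r", "alpha_c", "alpha_r")

# ranges fixed by parameter definitions rather than the 50-150% median rule
_DEFINED_RANGES = {
    "kappa": (0.0, 0.33),
    "k1c": (-0.2, 0.0), "k2c": (-0.2, 0.0),
    "k1r": (-0.2, 0.0), "k2r": (-0.2, 0.0),
    "lambda_": (0.3, 2.0),
    "lambda_c": (-0.2, 0.0), "lambda_r": (-0.2, 0.0),
    "alpha_c": (0.0, 0.3), "alpha_r": (0.0, 0.2),
}


@dataclass(frozen=True)
class ParameterSpec:
    """Name, median and bounds of one sensitivity/calibration parameter."""

    name: str
    median: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower <= self.median <= self.upper:
            raise ValueError(f"{self.name}: require lower <= median <= upper")

    @classmethod
    def from_median(cls, name: str, median: float) -> "ParameterSpec":
        """50%/150%-of-median bounds (the default range rule)."""
        lo, hi = sorted((0.5 * median, 1.5 * median))
        return cls(name, median, lo, hi)


@dataclass(frozen=True)
class SensitivityScore:
    parameter: str
    load_case: str
    metric: str
    score: float


def parameter_specs(model_kind: str) -> list[ParameterSpec]:
    """Default parameter specs for the HGO or (linear) rebar model."""
    names = HGO_PARAMS if model_kind == "hgo" else REBAR_PARAMS
    specs = []
    for n in names:
        med = MEDIANS[n]
        if n in _DEFINED_RANGES:
            lo, hi = _DEFINED_RANGES[n]
            specs.append(ParameterSpec(n, med, lo, hi))
        elif n == "nu":
            # 150% of the median would exceed the physical limit of 0.5
            specs.append(ParameterSpec(n, med, 0.5 * med, 0.499))
        else:
            specs.append(ParameterSpec.from_median(n, med))
    return specs


def _variation_values(spec: ParameterSpec, n_variations: int) -> np.ndarray:
    if spec.upper <= spec.lower:
        raise ValueError(f"{spec.name}: zero-width range")
    if n_variations < 1:
        raise ValueError("n_variations must be >= 1")
    if n_variations == 1:
        return np.array([spec.upper])
    return np.linspace(spec.lower, spec.upper, n_variations)


def ofat_design(params: list[ParameterSpec], n_variations: int = 4):
    """OFAT run list: one all-median reference plus, per parameter,
    ``n_variations`` equidistant values spanning [lower, upper] with all
    other parameters at median.

    Returns ``(reference, runs)`` where ``reference`` maps names to medians
    and ``runs`` is a list of ``(param_name, value, full_value_dict)``.
    """
    reference = {p.name: p.median for p in params}
    runs = []
    for p in params:
        for v in _variation_values(p, n_variations):
            values = dict(reference)
            values[p.name] = float(v)
            runs.append((p.name, float(v), values))
    return reference, runs


def sensitivity_score_single(delta_response_pct: float,
                             delta_param_pct: float) -> float:
    """Signed ratio of percentage changes for a single OFAT variation."""
    if delta_param_pct == 0:
        raise ValueError("parameter variation must be nonzero")
    return delta_response_pct / delta_param_pct


def aggregate_scores(scores) -> float:
    """Signed mean of the per-variation scores of one (P, L, M) triple."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no variation scores to aggregate")
    return float(scores.mean())


def select_parameters(scores: pd.DataFrame, threshold: float = 0.1):
    """Split parameters into (included, excluded) by the critical score.

    ``scores`` is tidy (columns parameter, load_case, metric, score); each
    parameter must carry a complete score set (same load cases and metrics
    for all). A parameter is included iff max |score| >= threshold.
    """
    required = len(scores[["load_case", "metric"]].drop_duplicates())
    counts = scores.groupby("parameter").size()
    if (counts != required).any():
        bad = counts.index[counts != required].tolist()
        raise ValueError(f"incomplete score sets for parameters: {bad}")
    agg = scores.groupby("parameter")["score"].apply(
        lambda s: np.max(np.abs(s.to_numpy())))
    included = sorted(agg.index[agg >= threshold])
    excluded = sorted(agg.index[agg < threshold])
    return included, excluded


def run_ofat(forward, params: list[ParameterSpec], n_variations: int = 4,
             threshold: float = 0.1, on_error: str = "raise"):
    """Run the OFAT analysis against a forward model.

    ``forward(values: dict) -> dict[(load_case, metric), response]`` is
    called once for the shared all-median reference and once per variation
    (4*P + 1 calls for the default design). Returns
    ``(scores_df, included, excluded)``.

    ``on_error='skip'`` logs failed forward runs (their variations are
    dropped from the mean) instead of raising.
    """
    reference, runs = ofat_design(params, n_variations)
    ref_resp = forward(reference)
    records = []
    for pname, value, values in runs:
        med = reference[pname]
        if med == 0:
            raise ValueError(f"{pname}: zero median, percent variation undefined")
        dp = 100.0 * (value - med) / med
        if dp == 0.0:
            continue  # variation coincides with the median: no information
        try:
            resp = forward(values)
        except Exception:
            if on_error == "skip":
                continue
            raise
        for key, ref_val in ref_resp.items():
            if ref_val == 0:
                raise ValueError(f"zero reference response for {key}")
            dr = 100.0 * (resp[key] - ref_val) / ref_val
            records.append({"parameter": pname, "load_case": key[0],
                            "metric": key[1], "value": value,
                            "score_single": sensitivity_score_single(dr, dp)})
    per_var = pd.DataFrame(records)
    scores = (per_var.groupby(["parameter", "load_case", "metric"])
              ["score_single"].apply(aggregate_scores).rename("score")
              .reset_index())
    included, excluded = select_parameters(scores, threshold)
    return scores, included, excluded
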