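"""Genetic-algorithm calibration of the disc models against RoM curves.

The calibration minimizes the disagreement between simulated and reference
moment-RoM curves, quantified per load case by the coefficient of
determination R^2 (``1 - SS_res / SS_tot`` with the reference curve as
``y``), averaged over the load cases. The GA uses a population of 20 built
each generation from 6 elites (kept unchanged), 4 uniform-crossover children
of random elite pairs, 4 mutants (one parameter of a random elite redrawn
uniformly within its bounds) and 6 random immigrants; it stops at an R^2
threshold or a generation cap.

Each model is calibrated in two steps -- stiffness parameters first
(threshold 0.85, up to 20 generations for the larger steps), then the fiber
angle and its regional scalings (threshold 0.9, up to 10 generations). The
nucleus parameters calibrated for the first model in a sequence are reused
by the others, and the nonlinear rebar model additionally inherits the
annulus ground substance of the linear one. Two sequence orders are
supported (HGO first, or linear rebar first) to probe order robustness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .runner import ForwardFailure, ForwardRunner

__all__ = [
    "r_squared",
    "ExperimentalDataset",
    "GAConfig",
    "Individual",
    "CalibrationStep",
    "TABLE_BOUNDS",
    "default_steps",
    "fitness",
    "run_ga",
    "run_sequence",
]

FAIL_FITNESS = -np.inf

# Calibration parameter bounds (stress parameters follow the 50-150% median
# rule; the scaling parameters their physiological/model-defined ranges).
TABLE_BOUNDS = {
    "c10n": (0.06, 0.18),
    "c10a_hgo": (0.13, 0.39),
    "c10a_mr": (0.1, 0.3),
    "c01a_mr": (0.03, 0.075),
    "k1": (1.0, 5.0),
    "k2": (45.0, 135.0),
    "kappa": (0.0, 0.33),
    "k1c": (-0.2, 0.0), "k2c": (-0.2, 0.0),
    "k1r": (-0.2, 0.0), "k2r": (-0.2, 0.0),
    "lambda_": (0.3, 2.0),
    "lambda_c": (-0.2, 0.0), "lambda_r": (-0.2, 0.0),
    "alpha": (15.0, 45.0),
    "alpha_c": (0.0, 0.3),
    "alpha_r": (0.0, 0.2),
}

STIFFNESS_FREE = {
    "hgo": ("c10n", "c10a_hgo", "k1", "k2", "kappa",
            "k1c", "k2c", "k1r", "k2r"),
    "linear_rebar": ("c10n", "c10a_mr", "c01a_mr",
                     "lambda_", "lambda_c", "lambda_r"),
    "nonlinear_rebar": ("lambda_", "lambda_c", "lambda_r"),
}
ANGLE_FREE = ("alpha", "alpha_c", "alpha_r")


def r_squared(y_exp, y_num) -> float:
    """Coefficient of determination of a simulated curve vs. a reference."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_num = np.asarray(y_num, dtype=float)
    if y_exp.shape != y_num.shape or y_exp.size < 2:
        raise ValueError("need equal-length arrays with at least 2 points")
    ss_tot = np.sum((y_exp - y_exp.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant reference curve: R^2 undefined")
    return float(1.0 - np.sum((y_exp - y_num) ** 2) / ss_tot)


@dataclass
class ExperimentalDataset:
    """Reference moment-grid curves used as calibration/validation targets."""

    metric: str                       # "rom" (degrees) or "idp" (MPa)
    moments_nm: np.ndarray            # increasing, shared by all load cases
    curves: dict                      # load_case -> mean values
    spread: dict | None = None        # load_case -> sd (optional)

    def __post_init__(self):
        self.moments_nm = np.asarray(self.moments_nm, dtype=float)
        if np.any(np.diff(self.moments_nm) <= 0):
            raise ValueError("moment grid must be strictly increasing")
        for lc, c in self.curves.items():
            self.curves[lc] = np.asarray(c, dtype=float)
            if self.curves[lc].shape != self.moments_nm.shape:
                raise ValueError(f"{lc}: curve length does not match grid")

    @property
    def load_cases(self) -> tuple:
        return tuple(self.curves)

    def to_csv(self, path) -> None:
        col = "rom_deg" if self.metric == "rom" else "idp_MPa"
        rows = []
        for lc, c in self.curves.items():
            sd = (self.spread or {}).get(lc, np.full_like(c, np.nan))
            for m, v, s in zip(self.moments_nm, c, sd):
                rows.append({"load_case": lc, "moment_Nm": m, col: v, "sd": s})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExperimentalDataset":
        df = pd.read_csv(path)
        metric = "rom" if "rom_deg" in df.columns else "idp"
        col = "rom_deg" if metric == "rom" else "idp_MPa"
        curves, spread = {}, {}
        grid = None
        for lc, g in df.groupby("load_case", sort=False):
            g = g.sort_values("moment_Nm")
            m = g["moment_Nm"].to_numpy()
            if grid is None:
                grid = m
            elif not np.array_equal(grid, m):
                raise ValueError("inconsistent moment grids across load cases")
            curves[lc] = g[col].to_numpy()
            if "sd" in g and not g["sd"].isna().all():
                spread[lc] = g["sd"].to_numpy()
        return cls(metric, grid, curves, spread or None)


@dataclass
class GAConfig:
    """Population structure, stopping rule and seed of the GA."""

    population: int = 20
    n_elite: int = 6
    n_crossover: int = 4
    n_mutation: int = 4
    n_immigration: int = 6
    max_generations: int | None = None   # None -> use the step's budget
    r2_threshold: float | None = None    # None -> use the step's threshold
    seed: int = 0

    def __post_init__(self):
        if (self.n_elite + self.n_crossover + self.n_mutation
                + self.n_immigration) != self.population:
            raise ValueError("elite + crossover + mutation + immigration "
                             "must equal the population size")
        if self.n_elite < 2:
            raise ValueError("need at least two elites for crossover pairs")


@dataclass
class Individual:
    values: dict
    fitness: float | None = None
    birth: int = 0  # creation index (stable tie-break: earlier wins)


@dataclass
class CalibrationStep:
    """One GA step: which parameters are free, at which bounds."""

    name: str
    model_kind: str
    free: dict                 # name -> (lower, upper)
    fixed: dict = field(default_factory=dict)
    r2_threshold: float = 0.85
    max_generations: int = 20

    def __post_init__(self):
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")


def default_steps(order: str = "hgo_first", selected: dict | None = None,
                  bounds: dict | None = None) -> list[CalibrationStep]:
    """The two-step-per-model calibration sequence in either order.

    ``selected`` optionally maps a model kind to the parameter names chosen
    by the sensitivity analysis; unselected stiffness parameters are dropped
    from the free set (they stay at their configuration medians).
    """
    b = dict(TABLE_BOUNDS)
    b.update(bounds or {})
    if order == "hgo_first":
        kinds = ["hgo", "linear_rebar", "nonlinear_rebar"]
    elif order == "rebar_first":
        kinds = ["linear_rebar", "nonlinear_rebar", "hgo"]
    else:
        raise ValueError("order must be 'hgo_first' or 'rebar_first'")

    steps = []
    for i, kind in enumerate(kinds, start=1):
        free_names = list(STIFFNESS_FREE[kind])
        if i > 1 and kind != "nonlinear_rebar":
            # NP calibrated by the first model of the sequence
            free_names = [n for n in free_names if n != "c10n"]
        if i == 1 and kind == "linear_rebar":
            pass  # first model calibrates the NP itself
        if selected and kind in selected:
            free_names = [n for n in free_names if n in selected[kind]]
        big = len(free_names) > 4
        steps.append(CalibrationStep(
            name=f"{i}a", model_kind=kind,
            free={n: b[n] for n in free_names},
            r2_threshold=0.85, max_generations=20 if big else 10))
        steps.append(CalibrationStep(
            name=f"{i}b", model_kind=kind,
            free={n: b[n] for n in ANGLE_FREE},
            r2_threshold=0.9, max_generations=10))
    return steps


def fitness(values: dict, step: CalibrationStep,
            dataset: ExperimentalDataset, runner: ForwardRunner,
            base: dict | None = None) -> float:
    """Mean R^2 over the dataset's load cases; -inf on solver failure."""
    merged = dict(base or {})
    merged.update(step.fixed)
    merged.update(values)
    try:
        config = runner.config(step.model_kind, merged)
        curves = runner.rom_curves(config)
    except (ForwardFailure, ValueError):
        # infeasible corner of parameter space (e.g. combined angle scalings
        # pushing a fiber angle past 90 deg) or a non-converged solve:
        # deselect the individual instead of aborting the GA
        return FAIL_FITNESS
    r2s = [r_squared(dataset.curves[lc], curves[lc])
           for lc in dataset.load_cases]
    return float(np.mean(r2s))


def _random_individual(step, rng, birth):
    vals = {n: float(rng.uniform(lo, hi)) for n, (lo, hi) in step.free.items()}
    return Individual(vals, None, birth)


def run_ga(step: CalibrationStep, ga: GAConfig,
           dataset: ExperimentalDataset, runner: ForwardRunner,
           rng: np.random.Generator | None = None,
           base: dict | None = None, incumbent: dict | None = None,
           log=None):
    """Run the GA for one calibration step.

    Returns ``(best, history)``: the best-ever individual and a per-generation
    DataFrame (generation, best and mean fitness, evaluations). Fully
    reproducible for a given seed; bounds are respected for every individual
    ever evaluated.

    ``incumbent`` optionally supplies the configuration the step starts from
    (medians, or the previous step's values): it is injected as one
    individual of the otherwise random initial population so that a step can
    never end worse than it began -- important when the generation budget is
    small.
    """
    if rng is None:
        rng = np.random.default_rng(ga.seed)
    threshold = (ga.r2_threshold if ga.r2_threshold is not None
                 else step.r2_threshold)
    max_gen = (ga.max_generations if ga.max_generations is not None
               else step.max_generations)
    names = list(step.free)
    birth = 0
    n_eval = 0

    def evaluate(ind):
        nonlocal n_eval
        for n, v in ind.values.items():
            lo, hi = step.free[n]
            assert lo - 1e-12 <= v <= hi + 1e-12, "bounds violated"
        ind.fitness = fitness(ind.values, step, dataset, runner, base)
        n_eval += 1

    pop = []
    if incumbent is not None and all(n in incumbent for n in names):
        vals = {n: float(np.clip(incumbent[n], *step.free[n])) for n in names}
        ind = Individual(vals, None, birth)
        birth += 1
        evaluate(ind)
        pop.append(ind)
    while len(pop) < ga.population:
        ind = _random_individual(step, rng, birth)
        birth += 1
        evaluate(ind)
        pop.append(ind)

    history = []
    best_ever = max(pop, key=lambda i: (i.fitness, -i.birth))
    for gen in range(max_gen + 1):
        pop.sort(key=lambda i: (-i.fitness, i.birth))
        if pop[0].fitness > best_ever.fitness:
            best_ever = pop[0]
        finite = [i.fitness for i in pop if np.isfinite(i.fitness)]
        history.append({"generation": gen, "best": pop[0].fitness,
                        "mean": float(np.mean(finite)) if finite else np.nan,
                        "evaluations": n_eval})
        if log:
            log(f"step {step.name} gen {gen}: best R2 = {pop[0].fitness:.4f}")
        if best_ever.fitness >= threshold or gen == max_gen:
            break
        elites = pop[:ga.n_elite]
        nxt = list(elites)  # carried over, not re-evaluated (deterministic)
        for _ in range(ga.n_crossover):
            i, j = rng.choice(ga.n_elite, size=2, replace=False)
            child = {}
            for n in names:
                src = elites[i] if rng.random() < 0.5 else elites[j]
                child[n] = src.values[n]
            ind = Individual(child, None, birth)
            birth += 1
            evaluate(ind)
            nxt.append(ind)
        for _ in range(ga.n_mutation):
            src = elites[int(rng.integers(ga.n_elite))]
            vals = dict(src.values)
            n = names[int(rng.integers(len(names)))]
            lo, hi = step.free[n]
            vals[n] = float(rng.uniform(lo, hi))
            ind = Individual(vals, None, birth)
            birth += 1
            evaluate(ind)
            nxt.append(ind)
        for _ in range(ga.n_immigration):
            ind = _random_individual(step, rng, birth)
            birth += 1
            evaluate(ind)
            nxt.append(ind)
        pop = nxt

    return best_ever, pd.DataFrame(history)


def run_sequence(order: str, dataset: ExperimentalDataset,
                 ga: GAConfig, runner: ForwardRunner,
                 selected: dict | None = None, log=None) -> dict:
    """Run the full two-step-per-model calibration sequence.

    Returns a dict ``model_kind -> {"values", "mean_r2", "per_load_case",
    "history", "calibrated_names"}``. The NP parameters of the first model
    propagate to the others; the nonlinear rebar model inherits the linear
    one's annulus ground substance.
    """
    steps = default_steps(order, selected)
    rng = np.random.default_rng(ga.seed)
    results: dict = {}
    inherited: dict = {}
    for step in steps:
        base = dict(inherited.get(step.model_kind, {}))
        if step.name.endswith("a"):
            carry: dict = {}
        else:  # step b builds on the best of step a
            carry = results[step.model_kind]["values"]
        step = dataclasses.replace(step, fixed={**step.fixed, **carry})
        from .model import MEDIANS
        prev_vals = results.get(step.model_kind, {}).get("values", {})
        incumbent = {n: prev_vals.get(n, base.get(n, MEDIANS[n]))
                     for n in step.free}
        best, hist = run_ga(step, ga, dataset, runner, rng=rng, base=base,
                            incumbent=incumbent, log=log)
        all_vals = {**base, **step.fixed, **best.values}
        prev = results.get(step.model_kind, {})
        results[step.model_kind] = {
            "values": {**prev.get("values", {}), **step.fixed, **best.values},
            "mean_r2": best.fitness,
            "history": pd.concat([prev.get("history", pd.DataFrame()),
                                  hist.assign(step=step.name)],
                                 ignore_index=True),
            "calibrated_names": sorted(set(prev.get("calibrated_names", []))
                                       | set(best.values)),
        }
        # propagate shared parameters to the models calibrated later
        first_kind = steps[0].model_kind
        if step.model_kind == first_kind and step.name.endswith("a"):
            np_vals = {k: v for k, v in all_vals.items() if k == "c10n"}
            for kind in ("hgo", "linear_rebar", "nonlinear_rebar"):
                if kind != first_kind:
                    inherited.setdefault(kind, {}).update(np_vals)
        if step.model_kind == "linear_rebar" and step.name.endswith("a"):
            ground = {k: v for k, v in all_vals.items()
                      if k in ("c10a_mr", "c01a_mr")}
            inherited.setdefault("nonlinear_rebar", {}).update(ground)

    # final per-load-case R^2 at each model's calibrated configuration
    for kind, res in results.items():
        merged = {**inherited.get(kind, {}), **res["values"]}
        # inherited parameters carry calibrated values from another model
        res["calibrated_names"] = sorted(set(res["calibrated_names"])
                                         | set(inherited.get(kind, {})))
        config = runner.config(kind, merged)
        curves = runner.rom_curves(config)
        per_lc = {lc: r_squared(dataset.curves[lc], curves[lc])
                  for lc in dataset.load_cases}
        res["values"] = merged
        res["per_load_case"] = per_lc
        res["mean_r2"] = float(np.mean(list(per_lc.values())))
    return results


def results_table(results: dict) -> pd.DataFrame:
    """Calibrated-configuration table (one row per model).

    Parameters that were not part of the calibration are marked with ``*``
    in the companion ``calibrated`` column and sit at their median values.
    """
    from .model import MEDIANS

    rows = []
    for kind, res in results.items():
        row = {"model": kind, "mean_r2": res["mean_r2"]}
        names = (set(STIFFNESS_FREE[kind]) | set(ANGLE_FREE)
                 | {"c10n", "c01n"})
        for n in sorted(names):
            v = res["values"].get(n, MEDIANS.get(n))
            mark = "" if n in res["calibrated_names"] else "*"
            row[n] = v
            row[f"{n}_calibrated"] = mark == ""
        rows.append(row)
    return pd.DataFrame(rows)
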