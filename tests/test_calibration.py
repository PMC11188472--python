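import numpy as np
import pandas as pd
import pytest

from ivdfem.calibration import (CalibrationStep, ExperimentalDataset,
                                GAConfig, TABLE_BOUNDS, default_steps,
                                fitness, r_squared, results_table, run_ga,
                                run_sequence)

LOAD_CASES = ("flexion", "extension", "lateral_bending", "axial_rotation")
GRID = np.array([1.0, 2.5, 5.0, 7.5])


class SurrogateRunner:
    """Analytic stand-in for the FE forward runner (duck-typed).

    RoM(M) = A_lc * M / (1 + s(params)) with a smooth stiffness index s, so
    calibration against surrogate-generated data is a well-posed recovery
    problem with a cheap closed form.
    """

    AMP = {"flexion": 2.0, "extension": 1.6, "lateral_bending": 1.2,
           "axial_rotation": 0.8}

    def __init__(self):
        self.evaluated = []
        self.moment_grid_nm = GRID

    @staticmethod
    def stiffness_index(kind, v):
        s = 2.0 * v.get("c10n", 0.12)
        if kind == "hgo":
            s += (v.get("c10a_hgo", 0.26)
                  + 0.2 * v.get("k1", 2.8) * (1 + v.get("k1c", -0.1))
                  + 0.002 * v.get("k2", 90.0))
        else:
            s += (v.get("c10a_mr", 0.19) + 2 * v.get("c01a_mr", 0.05)
                  + 0.5 * v.get("lambda_", 1.15)
                  * (1 + 2 * v.get("lambda_c", -0.1)))
        s *= 1.0 + 0.01 * (v.get("alpha", 30.0) - 30.0) \
            + 0.5 * v.get("alpha_r", 0.1) - 0.3 * v.get("alpha_c", 0.15)
        return s

    def config(self, kind, values):
        return (kind, dict(values))

    def rom_curves(self, config):
        kind, v = config
        self.evaluated.append((kind, dict(v)))
        s = self.stiffness_index(kind, v)
        return {lc: a * GRID / (1.0 + s) for lc, a in self.AMP.items()}


def surrogate_dataset(kind="hgo", values=None):
    runner = SurrogateRunner()
    curves = runner.rom_curves(runner.config(kind, values or {}))
    return ExperimentalDataset("rom", GRID, curves)


class TestRSquared:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SS_res = 0.06, SS_tot = 2 -> R^2 = 0.97
        assert r_squared([1, 2, 3], [1.1, 1.9, 3.2]) == pytest.approx(0.97)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestDataset:
    def test_csv_roundtrip_preserves_values(self, tmp_path):
        ds = surrogate_dataset()
        ds.spread = {lc: 0.1 * np.abs(c) for lc, c in ds.curves.items()}
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = ExperimentalDataset.from_csv(path)
        assert back.metric == "rom"
        assert np.allclose(back.moments_nm, ds.moments_nm, atol=1e-12)
        for lc in ds.load_cases:
            assert np.allclose(back.curves[lc], ds.curves[lc], atol=1e-12)
            assert np.allclose(back.spread[lc], ds.spread[lc], atol=1e-12)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            ExperimentalDataset("rom", [1.0, 0.5], {"flexion": [1.0, 2.0]})


class TestGAConfig:
    def test_population_composition_must_sum(self):
        with pytest.raises(ValueError):
            GAConfig(population=20, n_elite=6, n_crossover=4, n_mutation=4,
                     n_immigration=5)

    def test_paper_composition_is_the_default(self):
        ga = GAConfig()
        assert (ga.population, ga.n_elite, ga.n_crossover, ga.n_mutation,
                ga.n_immigration) == (20, 6, 4, 4, 6)


class TestFitness:
    def test_self_consistency_gives_r2_of_one(self):
        truth = {"c10n": 0.15, "c10a_hgo": 0.3, "k1": 2.0}
        ds = surrogate_dataset("hgo", truth)
        step = CalibrationStep("1a", "hgo",
                               {n: TABLE_BOUNDS[n] for n in truth})
        f = fitness(truth, step, ds, SurrogateRunner())
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_fitness_bounded_above_by_one_and_deterministic(self):
        ds = surrogate_dataset("hgo", {"c10n": 0.15})
        step = CalibrationStep("1a", "hgo", {"c10n": TABLE_BOUNDS["c10n"]})
        runner = SurrogateRunner()
        f1 = fitness({"c10n": 0.07}, step, ds, runner)
        f2 = fitness({"c10n": 0.07}, step, ds, runner)
        assert f1 == f2 < 1.0

    def test_invalid_configuration_maps_to_sentinel(self, mini_geometry):
        from ivdfem.runner import ForwardRunner
        runner = ForwardRunner(geometry=mini_geometry, moment_grid_nm=[5.0])
        ds = ExperimentalDataset("rom", [5.0, 7.5],
                                 {lc: [3.0, 4.0] for lc in LOAD_CASES})
        ds = ExperimentalDataset(
            "rom", GRID, {lc: np.linspace(1, 4, 4) for lc in LOAD_CASES})
        runner = ForwardRunner(geometry=mini_geometry, moment_grid_nm=GRID)
        step = CalibrationStep("1b", "hgo",
                               {n: TABLE_BOUNDS[n]
                                for n in ("alpha", "alpha_c", "alpha_r")})
        # combined angle scalings beyond 90 degrees -> infeasible corner
        f = fitness({"alpha": 45.0, "alpha_c": 0.3, "alpha_r": 0.2},
                    step, ds, runner)
        assert f == -np.inf


class TestRunGA:
    STEP = CalibrationStep(
        "1a", "hgo",
        {n: TABLE_BOUNDS[n] for n in ("c10n", "c10a_hgo", "k1", "k2", "k1c")},
        r2_threshold=0.995, max_generations=6)

    def test_generation_audit_and_elitist_monotonicity(self):
        ds = surrogate_dataset("hgo", {"c10n": 0.16, "c10a_hgo": 0.35,
                                       "k1": 4.0})
        runner = SurrogateRunner()
        ga = GAConfig(seed=5)
        best, hist = run_ga(self.STEP, ga, ds, runner)
        # 20 initial evaluations, then 4 + 4 + 6 = 14 per generation
        evals = hist.evaluations.to_numpy()
        assert evals[0] == 20
        assert np.all(np.diff(evals) == 14)
        assert np.all(np.diff(hist.best.to_numpy()) >= 0)

    def test_reproducible_trajectory_for_fixed_seed(self):
        ds = surrogate_dataset("hgo", {"c10n": 0.16})
        a = run_ga(self.STEP, GAConfig(seed=11), ds, SurrogateRunner())
        b = run_ga(self.STEP, GAConfig(seed=11), ds, SurrogateRunner())
        assert a[0].values == b[0].values
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_every_evaluated_individual_within_bounds(self):
        ds = surrogate_dataset("hgo", {"c10n": 0.16})
        runner = SurrogateRunner()
        run_ga(self.STEP, GAConfig(seed=3), ds, runner)
        for kind, v in runner.evaluated:
            for n, (lo, hi) in self.STEP.free.items():
                assert lo - 1e-12 <= v[n] <= hi + 1e-12

    def test_surrogate_parameter_recovery(self):
        truth = {"c10n": 0.16, "c10a_hgo": 0.35, "k1": 4.0, "k2": 60.0,
                 "k1c": -0.15}
        ds = surrogate_dataset("hgo", truth)
        best, _ = run_ga(self.STEP, GAConfig(seed=2, r2_threshold=0.9),
                         ds, SurrogateRunner())
        assert best.fitness >= 0.9

    def test_incumbent_seeding_never_degrades_the_start(self):
        truth = {"c10n": 0.16, "c10a_hgo": 0.35, "k1": 4.0, "k2": 60.0,
                 "k1c": -0.15}
        ds = surrogate_dataset("hgo", truth)
        best, _ = run_ga(self.STEP, GAConfig(seed=8, max_generations=0),
                         ds, SurrogateRunner(), incumbent=truth)
        assert best.fitness == pytest.approx(1.0, abs=1e-12)


class TestSequences:
    def test_default_step_budgets_follow_parameter_count(self):
        steps = default_steps("hgo_first")
        by_name = {s.name: s for s in steps}
        assert by_name["1a"].max_generations == 20
        assert by_name["2a"].max_generations == 20
        assert by_name["3a"].max_generations == 10  # few free parameters
        assert all(by_name[f"{i}b"].max_generations == 10 for i in (1, 2, 3))
        assert all(by_name[f"{i}b"].r2_threshold == 0.9 for i in (1, 2, 3))
        assert by_name["1a"].model_kind == "hgo"
        steps_r = default_steps("rebar_first")
        assert steps_r[0].model_kind == "linear_rebar"
        assert steps_r[-1].model_kind == "hgo"

    @pytest.fixture(scope="class")
    def sequence_results(self):
        ds = surrogate_dataset("hgo", {"c10n": 0.16, "c10a_hgo": 0.35})
        ga = GAConfig(seed=4, max_generations=2)
        out = {}
        for order in ("hgo_first", "rebar_first"):
            out[order] = run_sequence(order, ds, ga, SurrogateRunner())
        return out

    def test_np_parameters_shared_across_models(self, sequence_results):
        res = sequence_results["hgo_first"]
        c10n = res["hgo"]["values"]["c10n"]
        assert res["linear_rebar"]["values"]["c10n"] == c10n
        assert res["nonlinear_rebar"]["values"]["c10n"] == c10n

    def test_nonlinear_rebar_inherits_ground_substance(self, sequence_results):
        res = sequence_results["hgo_first"]
        for n in ("c10a_mr", "c01a_mr"):
            assert res["nonlinear_rebar"]["values"][n] \
                == res["linear_rebar"]["values"][n]

    def test_both_orders_produce_complete_tables(self, sequence_results):
        for order, res in sequence_results.items():
            table = results_table(res)
            assert set(table["model"]) == {"hgo", "linear_rebar",
                                           "nonlinear_rebar"}
            assert "mean_r2" in table
            # parameters outside the calibration are flagged
            row = table[table.model == "hgo"].iloc[0]
            assert not row["c01n_calibrated"]
            assert row["c10n_calibrated"]

    def test_orders_agree_on_surrogate(self, sequence_results):
        a = sequence_results["hgo_first"]
        b = sequence_results["rebar_first"]
        for kind in a:
            assert abs(a[kind]["mean_r2"] - b[kind]["mean_r2"]) <= 0.05
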