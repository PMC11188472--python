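import numpy as np
import pytest

from ivdfem.model import (MaterialConfig, build_disc_model,
                          embed_rebar_surfaces)
from ivdfem.solver import (LOAD_CASES, SolveSettings, compute_idp,
                           compute_rom, solve_static,
                           uniaxial_single_element, _MomentSystem)

GRID = [1000.0, 2500.0, 5000.0, 7500.0]  # N*mm


class TestEquilibriumBasics:
    def test_zero_moment_gives_zero_motion(self, mini_hgo_model):
        res = solve_static(mini_hgo_model, "flexion",
                           SolveSettings(max_moment=0.0, n_increments=1),
                           return_state=True)
        assert res.rom[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.abs(res.state["U"]).max() == pytest.approx(0.0, abs=1e-12)

    def test_solver_is_deterministic(self, mini_hgo_model):
        s = SolveSettings(moment_grid=[2500.0, 5000.0])
        a = solve_static(mini_hgo_model, "flexion", s)
        b = solve_static(mini_hgo_model, "flexion", s)
        assert np.array_equal(a.rom, b.rom)
        assert np.array_equal(a.idp, b.idp)

    def test_rigid_translation_generates_no_internal_force(self,
                                                           mini_hgo_model):
        system = _MomentSystem(mini_hgo_model)
        U = np.tile([1.3, -0.7, 2.1], (mini_hgo_model.mesh.n_nodes, 1))
        f = system.internal_force(U)
        assert np.abs(f).max() < 1e-8

    def test_single_element_uniaxial_matches_closed_form(self):
        lam = 1.2
        sigma = uniaxial_single_element(0.26, lam)
        exact = 2 * 0.26 * (lam**2 - 1 / lam)
        assert sigma == pytest.approx(exact, rel=0.01)


class TestOutcomeMetrics:
    def test_rom_of_prescribed_rigid_rotation(self):
        axis = LOAD_CASES["flexion"].axis
        rot = np.deg2rad(5.0) * axis
        assert compute_rom(rot, "flexion") == pytest.approx(5.0, abs=1e-9)
        assert compute_rom(-rot, "extension") == pytest.approx(5.0, abs=1e-9)
        assert compute_rom(np.zeros(3), "axial_rotation") == 0.0

    def test_idp_of_uniform_hydrostatic_state(self, mini_hgo_model):
        mesh = mini_hgo_model.mesh
        p = 0.37
        sig = np.tile(-p * np.eye(3), (mesh.n_elements, 1, 1))
        assert compute_idp(sig, mesh) == pytest.approx(p, rel=1e-12)

    def test_idp_positive_under_flexion(self, mini_hgo_model):
        res = solve_static(mini_hgo_model, "flexion",
                           SolveSettings(moment_grid=GRID))
        assert res.converged.all()
        assert res.idp[-1] > 0

    def test_flexion_rom_positive_and_monotone_in_moment(self,
                                                         mini_hgo_model):
        res = solve_static(mini_hgo_model, "flexion",
                           SolveSettings(moment_grid=GRID))
        assert res.rom[1] > 0
        assert np.all(np.diff(res.rom) > 0)

    def test_state_vtk_export(self, tmp_path, mini_hgo_model):
        from ivdfem.solver import export_state_vtk
        res = solve_static(mini_hgo_model, "flexion",
                           SolveSettings(moment_grid=[2500.0]),
                           return_state=True)
        path = tmp_path / "state.vtk"
        export_state_vtk(mini_hgo_model, res.state["U"], path)
        text = path.read_text()
        assert "VECTORS displacement_mm double" in text
        assert "SCALARS pressure_MPa double" in text

    def test_result_dataframe_units(self, mini_hgo_model):
        res = solve_static(mini_hgo_model, "flexion",
                           SolveSettings(moment_grid=[5000.0]))
        df = res.to_dataframe()
        assert df.moment_Nm.tolist() == [0.0, 5.0]


class TestMonotoneStiffening:
    @pytest.mark.parametrize("load_case", list(LOAD_CASES))
    def test_rom_monotone_in_moment_all_models(self, load_case, mini_geometry):
        for kind in ("hgo", "linear_rebar", "nonlinear_rebar"):
            model = build_disc_model(mini_geometry, MaterialConfig.median(kind))
            res = solve_static(model, load_case,
                               SolveSettings(moment_grid=GRID))
            assert res.converged.all(), (kind, load_case)
            assert np.all(np.diff(res.rom) > 0), (kind, load_case)

    def test_stiffer_fibers_reduce_rom(self, mini_geometry):
        roms = {}
        for k1 in (1.0, 5.0):
            model = build_disc_model(mini_geometry,
                                     MaterialConfig.median("hgo", k1=k1))
            for lc in ("flexion", "axial_rotation"):
                res = solve_static(model, lc,
                                   SolveSettings(moment_grid=[7500.0]))
                roms[(k1, lc)] = res.rom[-1]
        assert roms[(5.0, "flexion")] < roms[(1.0, "flexion")]
        assert roms[(5.0, "axial_rotation")] < roms[(1.0, "axial_rotation")]

    def test_stiffer_rebars_reduce_rom(self, mini_geometry):
        roms = []
        for lam in (0.5, 2.0):
            model = build_disc_model(
                mini_geometry, MaterialConfig.median("linear_rebar",
                                                     lambda_=lam))
            res = solve_static(model, "flexion",
                               SolveSettings(moment_grid=[7500.0]))
            roms.append(res.rom[-1])
        assert roms[1] < roms[0]


class TestIncompressibility:
    def test_volume_ratio_within_bounds_at_max_load(self, mini_hgo_model):
        res = solve_static(mini_hgo_model, "flexion",
                           SolveSettings(moment_grid=[7500.0]),
                           return_state=True)
        system = res.state["system"]
        Uel = res.state["U"][system.solid.elems]
        _, Fc = system.solid.deformation(Uel)
        J = np.linalg.det(Fc)
        assert J.min() > 0.98 and J.max() < 1.02


class TestRebarMembranes:
    def test_membrane_count_is_interface_quads_times_layers(self,
                                                            default_mesh):
        mesh, _ = default_mesh
        from ivdfem.fibers import FiberAngleParams, build_fiber_layout
        layout = build_fiber_layout(mesh, FiberAngleParams(30))
        mem = embed_rebar_surfaces(mesh, layout, 0.1, 0.1, 0.5)
        nt, nz = mesh.metadata["n_theta"], mesh.metadata["n_z"]
        assert mem.n_quads == 5 * nt * nz

    def test_solids_identical_across_model_kinds(self, mini_geometry):
        hgo = build_disc_model(mini_geometry, MaterialConfig.median("hgo"))
        reb = build_disc_model(mini_geometry,
                               MaterialConfig.median("linear_rebar"))
        assert hgo.mesh.n_nodes == reb.mesh.n_nodes
        assert np.array_equal(hgo.mesh.elements, reb.mesh.elements)
        assert reb.membranes is not None and hgo.membranes is None

    def test_zero_rebar_area_equals_fiber_free_membranes(self, mini_geometry):
        cfg0 = MaterialConfig.median("linear_rebar", rebar_area=0.0)
        # vanishing fiber stiffness is the same limit reached differently
        cfg1 = MaterialConfig.median("linear_rebar", fiber_E=1e-9)
        roms = []
        for cfg in (cfg0, cfg1):
            model = build_disc_model(mini_geometry, cfg)
            res = solve_static(model, "flexion",
                               SolveSettings(moment_grid=[5000.0]))
            roms.append(res.rom[-1])
        assert roms[0] == pytest.approx(roms[1], rel=1e-5)

    def test_doubling_rebar_area_stiffens_flexion(self, mini_geometry):
        roms = []
        for area in (0.1, 0.2):
            model = build_disc_model(
                mini_geometry, MaterialConfig.median("linear_rebar",
                                                     rebar_area=area))
            res = solve_static(model, "flexion",
                               SolveSettings(moment_grid=[7500.0]))
            roms.append(res.rom[-1])
        assert roms[1] < roms[0]

    def test_mesh_without_surface_metadata_rejected(self, mini_geometry):
        from ivdfem.fibers import FiberAngleParams, build_fiber_layout
        from ivdfem.geometry import build_disc
        mesh, _ = build_disc(mini_geometry)
        layout = build_fiber_layout(mesh, FiberAngleParams(30))
        mesh.metadata.pop("layer_surface_quads")
        with pytest.raises(ValueError, match="interface"):
            embed_rebar_surfaces(mesh, layout, 0.1, 0.1, 0.5)


class TestFailureHandling:
    def test_non_convergence_is_flagged_with_partial_curve(self,
                                                           mini_hgo_model):
        settings = SolveSettings(moment_grid=[2500.0, 500000.0],
                                 max_newton_iters=8, max_halvings=0)
        res = solve_static(mini_hgo_model, "flexion", settings)
        assert not res.converged.all()
        assert "failed_at_Nmm" in res.stats
        # the partial curve up to the last converged increment is returned
        assert res.converged[1]
        assert np.isfinite(res.rom[1])
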