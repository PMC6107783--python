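"""Navier-Stokes solver: analytic benchmarks, conservation, probes."""

import warnings

import numpy as np
import pytest

from renalflow.bcs import FlowCase
from renalflow.geometry import StenosisSpec, build_stenosed_vessel
from renalflow.meshing import MeshResolution, VolumeMesh, generate_volume_mesh
from renalflow.solver import (
    MM,
    FlowSolution,
    ProbeError,
    SolverError,
    SolverParams,
    probe_plane,
    reynolds_number,
    solve_steady_flow,
)
from tests.conftest import POISEUILLE_D_MM, poiseuille_flow_rate


def poiseuille_dp(length_m, flow, radius_m, mu=0.0035):
    """Hagen-Poiseuille pressure drop 8 mu L Q / (pi R^4)."""
    return 8.0 * mu * length_m * flow / (np.pi * radius_m**4)


class TestPoiseuilleBenchmark:
    def test_pressure_drop_within_2pct(self, poiseuille_solution, poiseuille_case):
        sol = poiseuille_solution
        q = poiseuille_case.flow_rate
        p1 = probe_plane(sol, np.array([0.0, 0.0, 10.0]), np.array([0.0, 0.0, 1.0]))
        p2 = probe_plane(sol, np.array([0.0, 0.0, 30.0]), np.array([0.0, 0.0, 1.0]))
        analytic = poiseuille_dp(20.0e-3, q, 0.5 * POISEUILLE_D_MM * 1e-3)
        assert p1["pressure"] - p2["pressure"] == pytest.approx(analytic, rel=0.02)

    def test_global_mass_conservation(self, poiseuille_solution):
        assert poiseuille_solution.mass_imbalance <= 1.0e-3

    def test_interior_plane_flux_matches_inlet_flow(self, poiseuille_solution):
        sol = poiseuille_solution
        for z in (8.0, 20.0, 33.0):
            r = probe_plane(sol, np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0]))
            assert r["flux"] == pytest.approx(sol.inlet_flow, rel=0.005)

    def test_no_slip_on_wall(self, poiseuille_solution):
        mesh = poiseuille_solution.mesh
        wall = mesh.patch_nodes("wall")
        assert np.abs(poiseuille_solution.velocity[wall]).max() == 0.0

    def test_converged_flag_and_residual(self, poiseuille_solution):
        assert poiseuille_solution.converged
        assert poiseuille_solution.residual_history[-1] <= 1.0e-5


class TestStokesLimit:
    def test_pressure_drop_linear_in_flow(self):
        # at creeping flow, doubling Q doubles the stenotic pressure drop
        g = build_stenosed_vessel(
            4.0, 30.0, [StenosisSpec(center=15.0, length=8.0, severity=50.0)]
        )
        mesh = generate_volume_mesh(g, resolution=MeshResolution(10, 3, 24))
        drops = []
        for q in (2.0e-9, 4.0e-9):  # Re ~ 0.0005: viscous-dominated
            case = FlowCase(
                flow_rate=q, outlet_mode="fixed_pressure", outlet_pressure=10.0
            )
            sol = solve_steady_flow(mesh, case, SolverParams())
            up = probe_plane(sol, np.array([0, 0, 5.0]), np.array([0, 0, 1.0]))
            dn = probe_plane(sol, np.array([0, 0, 25.0]), np.array([0, 0, 1.0]))
            drops.append(up["pressure"] - dn["pressure"])
        assert drops[1] == pytest.approx(2.0 * drops[0], rel=0.01)


class TestGridConvergence:
    def test_observed_order_at_least_one(self):
        # plane-averaged pressure drop on three nested refinements of the
        # Poiseuille case; low tau so the Galerkin error dominates and the
        # sequence is monotone
        q = poiseuille_flow_rate()
        g = build_stenosed_vessel(POISEUILLE_D_MM, 40.0)
        errors = []
        for res in (
            MeshResolution(8, 2, 12),
            MeshResolution(12, 3, 18),
            MeshResolution(18, 5, 27),
        ):
            mesh = generate_volume_mesh(g, resolution=res)
            case = FlowCase(
                flow_rate=q, outlet_mode="fixed_pressure", outlet_pressure=100.0
            )
            sol = solve_steady_flow(mesh, case, SolverParams(tau_scale=0.1))
            p1 = probe_plane(sol, np.array([0, 0, 10.0]), np.array([0, 0, 1.0]))
            p2 = probe_plane(sol, np.array([0, 0, 30.0]), np.array([0, 0, 1.0]))
            analytic = poiseuille_dp(20.0e-3, q, 0.5 * POISEUILLE_D_MM * 1e-3)
            errors.append(abs(p1["pressure"] - p2["pressure"] - analytic))
        order1 = np.log(errors[0] / errors[1]) / np.log(1.5)
        order2 = np.log(errors[1] / errors[2]) / np.log(1.5)
        assert order1 >= 1.0
        assert order2 >= 1.0


class TestRotationInvariance:
    def test_vpdpa_invariant_under_rigid_rotation(self):
        # solve the same stenosed tube in two orientations; the pressure
        # ratio across matched planes must agree to tight tolerance
        g = build_stenosed_vessel(
            4.0, 30.0, [StenosisSpec(center=10.0, length=6.0, severity=50.0)]
        )
        mesh = generate_volume_mesh(g, resolution=MeshResolution(10, 3, 24))
        case = FlowCase(
            flow_rate=0.3e-6, outlet_mode="fixed_pressure", outlet_pressure=1000.0
        )
        params = SolverParams(nonlinear_tolerance=1e-7)
        sol = solve_steady_flow(mesh, case, params)

        theta = 0.35
        rot = np.array(
            [
                [np.cos(theta), 0.0, np.sin(theta)],
                [0.0, 1.0, 0.0],
                [-np.sin(theta), 0.0, np.cos(theta)],
            ]
        )
        rmesh = VolumeMesh(
            nodes=mesh.nodes @ rot.T,
            tets=mesh.tets,
            patches=mesh.patches,
            n_wall_layers=mesh.n_wall_layers,
            growth_ratio=mesh.growth_ratio,
            ring_radii=mesh.ring_radii,
            n_theta=mesh.n_theta,
            stations=mesh.stations,
            nodes_per_station=mesh.nodes_per_station,
            geometry=None,  # solver must infer the inlet direction
        )
        rsol = solve_steady_flow(rmesh, case, params)

        def ratio(solution, rotm):
            axis = rotm @ np.array([0.0, 0.0, 1.0])
            pa = probe_plane(solution, rotm @ np.array([0, 0, 4.0]), axis)
            pd = probe_plane(solution, rotm @ np.array([0, 0, 25.0]), axis)
            return pd["pressure"] / pa["pressure"]

        assert ratio(rsol, rot) == pytest.approx(ratio(sol, np.eye(3)), abs=1e-6)


class TestWarmStart:
    def test_mesh_sequencing_reproduces_cold_solution(self):
        # solve coarse, interpolate onto a finer structured mesh, and check
        # the warm-started solve lands on the cold-start solution
        g = build_stenosed_vessel(
            4.0, 30.0, [StenosisSpec(center=10.0, length=6.0, severity=50.0)]
        )
        coarse_mesh = generate_volume_mesh(g, resolution=MeshResolution(10, 3, 24))
        fine_mesh = generate_volume_mesh(g, resolution=MeshResolution(12, 4, 30))
        case = FlowCase(
            flow_rate=1.0e-6, outlet_mode="fixed_pressure", outlet_pressure=1000.0
        )
        coarse = solve_steady_flow(coarse_mesh, case, SolverParams())
        cold = solve_steady_flow(fine_mesh, case, SolverParams())
        warm = solve_steady_flow(
            fine_mesh, case, SolverParams(), warm_start=coarse
        )
        assert np.abs(warm.pressure - cold.pressure).max() < 0.05  # Pa
        assert len(warm.residual_history) <= len(cold.residual_history)


class TestErrors:
    def test_inverted_cells_rejected_before_assembly(self, poiseuille_mesh):
        import copy

        bad = copy.copy(poiseuille_mesh)
        bad_tets = poiseuille_mesh.tets.copy()
        bad_tets[0] = bad_tets[0][[0, 1, 3, 2]]  # invert one cell
        bad.tets = bad_tets
        bad.__dict__.pop("cell_volumes", None)  # reset cached property
        with pytest.raises(SolverError, match="inverted"):
            solve_steady_flow(bad, FlowCase(), SolverParams())

    def test_nonconvergence_reports_history(self, poiseuille_mesh, poiseuille_case):
        with pytest.raises(SolverError) as err:
            solve_steady_flow(
                poiseuille_mesh,
                poiseuille_case,
                SolverParams(
                    max_nonlinear_iterations=2, nonlinear_tolerance=1e-14
                ),
            )
        assert len(err.value.residual_history) > 0


class TestReynoldsNumber:
    def test_arithmetic(self):
        case = FlowCase(flow_rate=8.0e-6)
        # U = Q/A ~ 0.4074 m/s in a 5 mm tube: Re = rho U D / mu ~ 620
        assert reynolds_number(case, 5.0e-3) == pytest.approx(620.4, abs=1.0)

    def test_zero_flow_no_warning(self):
        case = FlowCase(flow_rate=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert reynolds_number(case, 5.0e-3) == 0.0

    def test_laminar_warning_above_2000(self):
        case = FlowCase(flow_rate=3.0e-5)
        with pytest.warns(UserWarning, match="laminar"):
            re = reynolds_number(case, 5.0e-3)
        assert re > 2000.0

    def test_default_case_set_is_laminar(self):
        # the synthetic study conditions stay in the laminar pipe-flow range
        case = FlowCase()
        for d_mm in (4.0, 5.0, 6.0):
            assert reynolds_number(case, d_mm * 1e-3) < 2000.0


class TestProbePlane:
    def test_uniform_pressure_returned_exactly(self, poiseuille_mesh):
        n = poiseuille_mesh.n_nodes
        sol = FlowSolution(
            mesh=poiseuille_mesh,
            velocity=np.zeros((n, 3)),
            pressure=np.full(n, 777.0),
            residual_history=[],
            converged=True,
            inlet_flow=1e-6,
            outlet_flow=1e-6,
            outlet_pressure=777.0,
        )
        r = probe_plane(sol, np.array([0, 0, 17.3]), np.array([0, 0, 1.0]))
        assert r["pressure"] == pytest.approx(777.0, rel=1e-12)

    def test_linear_pressure_profile_matches_analytic(self, poiseuille_mesh):
        n = poiseuille_mesh.n_nodes
        a, b = 500.0, 10.0
        sol = FlowSolution(
            mesh=poiseuille_mesh,
            velocity=np.zeros((n, 3)),
            pressure=a - b * poiseuille_mesh.nodes[:, 2],
            residual_history=[],
            converged=True,
            inlet_flow=1e-6,
            outlet_flow=1e-6,
            outlet_pressure=a,
        )
        for z in (5.0, 17.0, 33.0):
            r = probe_plane(sol, np.array([0, 0, z]), np.array([0, 0, 1.0]))
            assert r["pressure"] == pytest.approx(a - b * z, rel=0.01)

    def test_plane_missing_lumen_rejected(self, poiseuille_solution):
        with pytest.raises(ProbeError):
            probe_plane(
                poiseuille_solution,
                np.array([0.0, 0.0, 200.0]),
                np.array([0.0, 0.0, 1.0]),
            )

    def test_area_matches_lumen_cross_section(self, poiseuille_solution):
        r = probe_plane(
            poiseuille_solution, np.array([0, 0, 20.0]), np.array([0, 0, 1.0])
        )
        analytic = np.pi * (0.5 * POISEUILLE_D_MM * MM) ** 2
        assert r["area"] == pytest.approx(analytic, rel=0.01)
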