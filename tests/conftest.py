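"""Shared fixtures.

Flow solves are expensive, so every converged solution used by more than one
test is session-scoped: a Poiseuille benchmark tube (driven through the
resistance outlet so the closed-loop outlet check comes for free) and the
stenosis-severity sweep on the renal template, whose rows also serve the
monotonicity, classification and unobstructed-limit tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from renalflow.bcs import FlowCase
from renalflow.geometry import build_stenosed_vessel
from renalflow.meshing import MeshResolution, generate_volume_mesh
from renalflow.pipeline import PipelineConfig, run_severity_sweep
from renalflow.solver import SolverParams, solve_steady_flow

POISEUILLE_D_MM = 4.0
POISEUILLE_L_MM = 40.0
POISEUILLE_RE = 50.0


def poiseuille_flow_rate(d_mm: float = POISEUILLE_D_MM, re: float = POISEUILLE_RE):
    """Flow rate giving the requested Reynolds number in a straight tube."""
    nu = 0.0035 / 1066.0
    d = d_mm * 1e-3
    u = re * nu / d
    return u * np.pi * (0.5 * d) ** 2


@pytest.fixture(scope="session")
def poiseuille_geometry():
    return build_stenosed_vessel(POISEUILLE_D_MM, POISEUILLE_L_MM)


@pytest.fixture(scope="session")
def poiseuille_mesh(poiseuille_geometry):
    return generate_volume_mesh(
        poiseuille_geometry, resolution=MeshResolution(16, 5, 40)
    )


@pytest.fixture(scope="session")
def poiseuille_case():
    q = poiseuille_flow_rate()
    return FlowCase(
        flow_rate=q,
        outlet_mode="resistance",
        resistance=200.0 / q,  # ~200 Pa above the distal reference
        reference_pressure=100.0,
    )


@pytest.fixture(scope="session")
def poiseuille_solution(poiseuille_mesh, poiseuille_case):
    return solve_steady_flow(poiseuille_mesh, poiseuille_case, SolverParams())


@pytest.fixture(scope="session")
def sweep_config():
    """Coarse-mesh template configuration used for the severity sweep."""
    cfg = PipelineConfig()
    cfg.mesh.n_theta = 12
    cfg.mesh.n_core = 4
    cfg.mesh.n_axial = 48
    return cfg


@pytest.fixture(scope="session")
def severity_sweep(sweep_config):
    """vPd/Pa over severities {0, 20, 40, 60, 72}% on the renal template."""
    return run_severity_sweep(sweep_config, (0.0, 20.0, 40.0, 60.0, 72.0))


@pytest.fixture(scope="session")
def fine_72_vpdpa():
    """vPd/Pa of the 72% template one ~1.3x refinement above the sweep mesh.

    Solved at nonlinear tolerance 1e-4, far below the vPd/Pa resolution
    compared in the self-convergence check (the sweep's 72% row provides
    the coarse value on the same template).
    """
    from renalflow.extraction import extract_pd_pa
    from renalflow.geometry import renal_template

    geom = renal_template(72.0)
    params = SolverParams(nonlinear_tolerance=1e-4)
    mesh = generate_volume_mesh(geom, resolution=MeshResolution(16, 5, 62))
    solution = solve_steady_flow(mesh, FlowCase(), params)
    return extract_pd_pa(solution, geom).vPdPa
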