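"""Shared fixtures.

The ventricle fixtures use a reduced-scale synthetic geometry (0.35 of the
physical size, ~10 um target edge, ~2000 cells) so that every PDE solve in
the suite stays within a few seconds to a few minutes on one CPU; the
package defaults remain the full-scale geometry.  Flow solves are
session-scoped because several tests interrogate the same fields.
"""

from __future__ import annotations

import numpy as np
import pytest

from ciliaflow.geometry import VentricleParams, build_synthetic_ventricles
from ciliaflow.mesh import box_mesh
from ciliaflow.stokes import (
    CiliaTractionSpec,
    FlowScenario,
    solve_steady_stokes,
    solve_transient_cycle,
)

FIXTURE_SCALE = 0.35
FIXTURE_EDGE = 10.0


@pytest.fixture(scope="session")
def fixture_params() -> VentricleParams:
    return VentricleParams.default(
        scale=FIXTURE_SCALE, target_edge_length=FIXTURE_EDGE, refine_factor=1.5
    )


@pytest.fixture(scope="session")
def ventricle_mesh(fixture_params):
    return build_synthetic_ventricles(fixture_params)


@pytest.fixture(scope="session")
def steady_cilia_flow(ventricle_mesh):
    """Cilia-driven/no-cardiac flow (closed caps)."""
    return solve_steady_stokes(
        ventricle_mesh, cilia=CiliaTractionSpec(), closed_caps=True
    )


@pytest.fixture(scope="session")
def baseline_flow(ventricle_mesh):
    return solve_transient_cycle(ventricle_mesh, scenario=FlowScenario("baseline"))


@pytest.fixture(scope="session")
def cardiac_flow(ventricle_mesh):
    return solve_transient_cycle(ventricle_mesh, scenario=FlowScenario("cardiac_only"))


@pytest.fixture(scope="session")
def unit_cube():
    return box_mesh((4, 4, 4))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
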