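"""Stokes solver: boundary conditions, conservation structure, scenarios."""

import numpy as np
import pytest

from ciliaflow.mesh import CILIA_LABELS, FacetLabel, UM, box_mesh
from ciliaflow.quadrature import tetrahedron_rule
from ciliaflow.stokes import (
    CardiacForcing,
    CiliaTractionSpec,
    FlowScenario,
    FluidProperties,
    StokesDiscretization,
    StokesSystem,
    divergence_residual,
    flow_statistics,
    solve_steady_stokes,
    solve_transient_cycle,
    velocity_at_cell_points,
)


class TestSpecs:
    def test_fluid_properties_validated(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)

    def test_cardiac_defaults(self):
        cardiac = CardiacForcing()
        assert cardiac.omega == pytest.approx(2 * np.pi * 2.22)
        assert cardiac.posterior_pressure(0.0) == 0.0
        assert cardiac.anterior_pressure(1.0) == 0.0

    def test_discretization_period_check(self):
        disc = StokesDiscretization(dt=0.023, steps_per_cycle=20)
        disc.check_period(CardiacForcing())  # 0.46 s vs 0.4505 s: accepted
        with pytest.raises(ValueError):
            StokesDiscretization(dt=0.1, steps_per_cycle=20).check_period(
                CardiacForcing()
            )

    def test_scenario_resolution(self):
        cilia = CiliaTractionSpec()
        cardiac = CardiacForcing()
        c2, k2 = FlowScenario("cilia_only").resolve(cilia, cardiac)
        assert k2 is None and c2.active == cilia.active
        c3, k3 = FlowScenario("cardiac_only").resolve(cilia, cardiac)
        assert k3 is cardiac and not c3.active
        c4, _ = FlowScenario(
            "paralysis", frozenset({int(FacetLabel.CILIA_DORSAL_MID)})
        ).resolve(cilia, cardiac)
        assert int(FacetLabel.CILIA_DORSAL_MID) not in c4.active

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            FlowScenario("warp_drive")


class TestTrivialSolutions:
    def test_zero_forcing_zero_flow(self, unit_cube):
        field = solve_steady_stokes(unit_cube)
        assert np.abs(field.velocity[0]).max() < 1e-12
        p = field.pressure[0]
        assert np.abs(p - p.mean()).max() < 1e-9

    def test_statistics_of_uniform_field(self, unit_cube):
        from ciliaflow.stokes import FlowField, StokesSystem

        u = np.tile([3e-6, 0.0, 0.0], (len(unit_cube.facets), 1))
        field = FlowField(
            mesh=unit_cube,
            velocity=[u],
            pressure=[np.zeros(unit_cube.num_cells)],
            facet_fluxes=[np.zeros(len(unit_cube.facets))],
            phase_times=np.array([0.0]),
            steady=True,
        )
        stats = flow_statistics(field)
        assert stats["max_speed"] == pytest.approx(3e-6, rel=1e-9)
        assert stats["mean_speed"] == pytest.approx(3e-6, rel=1e-9)

    def test_empty_snapshot_set_rejected(self, unit_cube):
        from ciliaflow.stokes import FlowField

        field = FlowField(
            mesh=unit_cube, velocity=[], pressure=[], facet_fluxes=[],
            phase_times=np.array([]),
        )
        with pytest.raises(ValueError):
            flow_statistics(field)


class TestConservationStructure:
    def test_wall_impermeability_machine_precision(self, ventricle_mesh, steady_cilia_flow):
        mesh = ventricle_mesh
        u = steady_cilia_flow.velocity[0]
        walls = mesh.facets_with_label(
            [int(FacetLabel.SLIP_WALL), *[int(l) for l in CILIA_LABELS]]
        )
        un = np.einsum("fd,fd->f", u[walls], mesh.facet_normals[walls])
        assert np.abs(un).max() < 1e-18  # machine zero relative to ~1e-5 speeds

    def test_divergence_residual_scaled_bound(self, steady_cilia_flow, ventricle_mesh):
        stats = flow_statistics(steady_cilia_flow)
        scale = stats["max_speed"] / ventricle_mesh.edge_lengths.min()
        assert divergence_residual(steady_cilia_flow) <= 1e-10 * scale

    def test_divergence_grows_under_nonsolenoidal_perturbation(
        self, ventricle_mesh, steady_cilia_flow
    ):
        from ciliaflow.stokes import FlowField

        base = divergence_residual(steady_cilia_flow)
        q = steady_cilia_flow.facet_fluxes[0].copy()
        rng = np.random.default_rng(7)
        for eps, expect in ((1e-12, None), (1e-9, None)):
            pert = rng.standard_normal(len(q)) * eps * np.abs(q).max()
            field = FlowField(
                mesh=ventricle_mesh,
                velocity=steady_cilia_flow.velocity,
                pressure=steady_cilia_flow.pressure,
                facet_fluxes=[q + pert],
                phase_times=np.array([0.0]),
                steady=True,
            )
            res = divergence_residual(field)
            assert res > 10 * base
        # linearity: 1000x the perturbation -> ~1000x the residual
        pert = rng.standard_normal(len(q)) * np.abs(q).max()
        r1 = divergence_residual(
            FlowField(ventricle_mesh, steady_cilia_flow.velocity,
                      steady_cilia_flow.pressure, [q + 1e-9 * pert],
                      np.array([0.0]), True)
        )
        r2 = divergence_residual(
            FlowField(ventricle_mesh, steady_cilia_flow.velocity,
                      steady_cilia_flow.pressure, [q + 1e-6 * pert],
                      np.array([0.0]), True)
        )
        assert r2 / r1 == pytest.approx(1e3, rel=1e-3)

    @staticmethod
    def _energy_split(mesh):
        system = StokesSystem(
            mesh, FluidProperties(), StokesDiscretization(), closed_caps=True
        )
        cilia = CiliaTractionSpec()
        field = solve_steady_stokes(mesh, cilia=cilia, system=system)
        u = field.velocity[0].ravel()
        total = float(u @ (system.A @ u))           # viscous + jump penalty
        penalty = float(u @ (system._jump_penalty() @ u))
        work = float(system.traction_rhs(cilia) @ u)
        return total, penalty, work

    def test_energy_balance_viscous_vs_boundary_work(self, ventricle_mesh):
        """Steady state: total dissipation (viscous + consistent
        nonconformity penalty) equals the cilia boundary work exactly; the
        penalty share shrinks under mesh refinement, recovering the physical
        balance between strain-rate dissipation and boundary work."""
        total, penalty, work = self._energy_split(ventricle_mesh)
        assert total == pytest.approx(work, rel=1e-6)  # discrete identity
        share = penalty / total
        assert 0.0 <= share < 0.5
        from ciliaflow.geometry import VentricleParams, build_synthetic_ventricles

        coarse = build_synthetic_ventricles(
            VentricleParams.default(
                scale=0.35, target_edge_length=14.0, refine_factor=1.5
            )
        )
        total_c, penalty_c, _ = self._energy_split(coarse)
        assert share < penalty_c / total_c  # consistency: share decays with h


class TestTransientScenarios:
    def test_zero_amplitude_cycle_equals_steady(self, ventricle_mesh):
        disc = StokesDiscretization(startup_cycles=2)
        cycle = solve_transient_cycle(
            ventricle_mesh,
            cardiac=CardiacForcing(amplitude=0.0),
            disc=disc,
            scenario=FlowScenario("baseline"),
        )
        steady = solve_steady_stokes(ventricle_mesh, cilia=CiliaTractionSpec())
        scale = np.abs(steady.velocity[0]).max()
        for u in cycle.velocity:
            assert np.abs(u - steady.velocity[0]).max() / scale < 1e-8

    def test_cardiac_only_phase_average_small(self, cardiac_flow):
        mean_u = np.mean(cardiac_flow.velocity, axis=0)
        peak = max(np.abs(u).max() for u in cardiac_flow.velocity)
        assert np.abs(mean_u).max() <= 0.02 * peak

    def test_scenario_speed_ordering(self, baseline_flow, cardiac_flow):
        assert (
            flow_statistics(cardiac_flow)["max_speed"]
            < flow_statistics(baseline_flow)["max_speed"]
        )

    def test_inconsistent_timestep_rejected(self, ventricle_mesh):
        with pytest.raises(ValueError, match="inconsistent"):
            solve_transient_cycle(
                ventricle_mesh,
                disc=StokesDiscretization(dt=0.1, steps_per_cycle=20),
            )

    def test_stored_cycle_length(self, baseline_flow):
        assert baseline_flow.num_snapshots == 20
        assert not baseline_flow.steady


def test_recirculation_in_cilia_driven_middle_chamber(
    ventricle_mesh, steady_cilia_flow, fixture_params
):
    """Opposed dorsal/ventral traction drives a rostrocaudal vortex: the
    axial velocity changes sign along the dorsoventral axis."""
    rp, _ = tetrahedron_rule(2)
    uq = velocity_at_cell_points(ventricle_mesh, steady_cilia_flow.velocity[0], rp)
    from ciliaflow.quadrature import map_to_cells

    pts = map_to_cells(rp, ventricle_mesh.points[ventricle_mesh.cells])
    half_x = 0.3 * fixture_params.middle_semi_axes[0] * UM
    sel = (np.abs(pts[:, :, 0]) < half_x) & (np.abs(pts[:, :, 1]) < half_x)
    ux = uq[:, :, 0][sel]
    z = pts[:, :, 2][sel]
    assert ux[z > 0].max() > 0 and ux[z < 0].min() < 0
    # dorsal drive is rostrocaudal (+x), ventral return flow is caudorostral
    zq = 0.3 * fixture_params.middle_semi_axes[2] * UM
    assert ux[z > zq].mean() > 0 > ux[z < -zq].mean()
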