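"""Transport solver: photoconversion curve, initialization, stepping,
periodic-flux bookkeeping and conservation."""

import numpy as np
import pytest

from ciliaflow.dg import DGSpace
from ciliaflow.mesh import PHOTOCONVERSION, box_mesh
from ciliaflow.stokes import FlowField
from ciliaflow.transport import (
    PeriodicFluxState,
    PhotoconversionSpec,
    SoluteSpec,
    TransportDiscretization,
    TransportSolver,
    TransportState,
    photoconversion_value,
    run_transport,
)


class TestPhotoconversionCurve:
    def test_endpoints(self):
        spec = PhotoconversionSpec(final_time=856.0, curve_time=65.0)
        assert spec.value(0.0) == 0.0
        assert spec.value(856.0) == pytest.approx(1.0)

    def test_interior_value(self):
        spec = PhotoconversionSpec(final_time=856.0, curve_time=65.0)
        expected = np.log(2.0) / np.log(1.0 + 856.0 / 65.0)
        assert photoconversion_value(65.0, spec) == pytest.approx(expected)
        assert expected == pytest.approx(0.261, abs=5e-3)

    def test_monotone(self):
        spec = PhotoconversionSpec(final_time=100.0)
        ts = np.linspace(0, 100, 33)
        vals = [spec.value(t) for t in ts]
        assert (np.diff(vals) > 0).all()

    def test_out_of_range_rejected(self):
        spec = PhotoconversionSpec(final_time=10.0)
        with pytest.raises(ValueError):
            spec.value(-1.0)
        with pytest.raises(ValueError):
            spec.value(11.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PhotoconversionSpec(final_time=-1.0)
        with pytest.raises(ValueError):
            PhotoconversionSpec(final_time=10.0, curve_time=0.0)


def _still_flow(mesh):
    return FlowField(
        mesh=mesh,
        velocity=[np.zeros((len(mesh.facets), 3))],
        pressure=[np.zeros(mesh.num_cells)],
        facet_fluxes=[np.zeros(len(mesh.facets))],
        phase_times=np.array([0.0]),
        steady=True,
    )


@pytest.fixture(scope="module")
def slab_with_pc():
    """A 10x2x2-cell slab whose leftmost cell layer is the photoconversion
    region (also tagged as ROI_1 for container invariants)."""
    mesh = box_mesh((10, 2, 2), (100e-6, 20e-6, 20e-6))
    left = np.nonzero(mesh.cell_centroids[:, 0] < 10e-6)[0]
    mesh.cell_sets[PHOTOCONVERSION] = left
    mesh.cell_sets["ROI_1"] = left.copy()
    return mesh


class TestSmoothedInitialConditions:
    @pytest.fixture(scope="class")
    def solver(self, slab_with_pc):
        pc = PhotoconversionSpec(final_time=10.0)
        return TransportSolver(
            slab_with_pc,
            _still_flow(slab_with_pc),
            SoluteSpec("dendra2", 1.15e-10),
            pc,
            TransportDiscretization(degree=2),
        )

    def test_maxima_follow_curve(self, solver):
        c1, c2 = solver.smooth_initial_conditions()
        dt = solver.disc.dt
        assert solver.space.max_over_cells(c1) == pytest.approx(
            solver.pc.value(dt), rel=1e-9
        )
        assert solver.space.max_over_cells(c2) == pytest.approx(
            solver.pc.value(2 * dt), rel=1e-9
        )

    def test_fields_in_unit_interval(self, solver):
        c1, c2 = solver.smooth_initial_conditions()
        for c in (c1, c2):
            assert solver.space.min_over_cells(c) >= -1e-6
            assert solver.space.max_over_cells(c) <= 1.0 + 1e-9

    def test_monotone_decay_away_from_source(self, solver, slab_with_pc):
        """Discrete maximum principle: cell means decrease with distance
        from the photoconversion region along the slab."""
        c1, _ = solver.smooth_initial_conditions()
        means = (solver.w_int * c1).reshape(-1, solver.nb).sum(axis=1)
        means = means / slab_with_pc.cell_volumes
        x = slab_with_pc.cell_centroids[:, 0]
        order = np.argsort(x)
        # average over cells in the same x-layer, then require decay
        layers = np.array_split(order, 10)
        layer_means = [means[l].mean() for l in layers]
        assert all(a >= b - 1e-12 for a, b in zip(layer_means, layer_means[1:]))

    def test_small_multiplier_limit_is_indicator(self, slab_with_pc):
        pc = PhotoconversionSpec(final_time=10.0)
        solver = TransportSolver(
            slab_with_pc,
            _still_flow(slab_with_pc),
            SoluteSpec("dendra2", 1.15e-10),
            pc,
            TransportDiscretization(degree=2, init_diffusion_multiplier=1e-4),
        )
        c1, _ = solver.smooth_initial_conditions()
        means = (solver.w_int * c1).reshape(-1, solver.nb).sum(axis=1)
        means /= slab_with_pc.cell_volumes
        inside = np.asarray(slab_with_pc.cell_sets[PHOTOCONVERSION])
        outside = np.setdiff1d(np.arange(slab_with_pc.num_cells), inside)
        v1 = pc.value(solver.disc.dt)
        assert np.allclose(means[inside], v1, rtol=1e-6)
        assert np.abs(means[outside]).max() < 1e-2 * v1

    def test_empty_region_rejected(self, slab_with_pc):
        mesh = box_mesh((4, 2, 2))
        with pytest.raises((ValueError, KeyError)):
            TransportSolver(
                mesh,
                _still_flow(mesh),
                SoluteSpec("dendra2", 1.15e-10),
                PhotoconversionSpec(final_time=1.0),
                TransportDiscretization(),
            ).smooth_initial_conditions()


class TestStepping:
    def test_uniform_state_stationary_without_flow(self, slab_with_pc):
        solver = TransportSolver(
            slab_with_pc,
            _still_flow(slab_with_pc),
            SoluteSpec("dendra2", 1.15e-10),
            None,
            TransportDiscretization(degree=2),
        )
        c0 = solver.space.constant_field(0.7)
        state = TransportState(c=c0.copy(), c_prev=c0.copy(), time=0.0, step=2)
        for _ in range(3):
            state = solver.advance(state)
        assert np.abs(state.c - c0).max() < 1e-12 * np.abs(c0).max()

    def test_solute_catalog(self):
        assert SoluteSpec.named("dendra2").diffusivity == pytest.approx(1.15e-10)
        assert SoluteSpec.named("ev").diffusivity == pytest.approx(2.17e-12)
        with pytest.raises(KeyError):
            SoluteSpec.named("unobtainium")
        with pytest.raises(ValueError):
            SoluteSpec("x", -1.0)


class TestPeriodicFlux:
    @pytest.fixture(scope="class")
    def cap_solver(self, request):
        mesh = request.getfixturevalue("ventricle_mesh")
        flow = request.getfixturevalue("baseline_flow")
        return TransportSolver(
            mesh, flow, SoluteSpec("dendra2", 1.15e-10), None,
            TransportDiscretization(degree=2),
        )

    def test_zero_previous_outflow_imposes_nothing(self, cap_solver):
        un = cap_solver._phase_un[0][1]
        c_in, new_state = cap_solver.periodic_flux_update(
            PeriodicFluxState(0.0, 0.0), un, 0.023
        )
        assert c_in == 0.0 and new_state.accumulated == 0.0

    def test_accumulates_when_no_inflow(self, cap_solver):
        un = np.abs(cap_solver._phase_un[0][1])  # all outflow
        c_in, new_state = cap_solver.periodic_flux_update(
            PeriodicFluxState(outflow_rate_prev=2.5, accumulated=0.0), un, 0.023
        )
        assert c_in == 0.0
        assert new_state.accumulated == pytest.approx(2.5 * 0.023)

    def test_balance_recovers_uniform_concentration(self, cap_solver):
        """With uniform concentration c* and matched in/out volumetric
        rates, the imposed inflow value equals c*."""
        un = cap_solver._phase_un[3][1]
        assert (un < 0).any() and (un > 0).any()
        c_star = 0.6
        cm = cap_solver.space.constant_field(c_star)
        out_rate, _ = cap_solver.advection.boundary_rates(un, cm)
        c_in, _ = cap_solver.periodic_flux_update(
            PeriodicFluxState(outflow_rate_prev=out_rate, accumulated=0.0), un, 0.023
        )
        vin = -(un[un < 0] * cap_solver.advection.b_areas[un < 0]).sum()
        vout = (un[un > 0] * cap_solver.advection.b_areas[un > 0]).sum()
        assert vin == pytest.approx(vout, rel=1e-10)  # incompressibility
        assert c_in == pytest.approx(c_star, rel=1e-10)

    def test_state_zero_without_pressure_caps(self, slab_with_pc):
        solver = TransportSolver(
            slab_with_pc, _still_flow(slab_with_pc),
            SoluteSpec("dendra2", 1.15e-10), None, TransportDiscretization(),
        )
        assert len(solver.open_facets) == 0


class TestRunTransport:
    def test_zero_cycles_returns_initial_means(self, slab_with_pc):
        pc = PhotoconversionSpec(final_time=1.0)
        _, series, _ = run_transport(
            slab_with_pc, _still_flow(slab_with_pc),
            SoluteSpec("dendra2", 1.15e-10), pc,
            TransportDiscretization(degree=1), n_cycles=0,
        )
        assert len(series.times) == 1
        assert series.times[0] == pytest.approx(2 * 0.023)

    def test_prescribed_region_tracks_curve(self, slab_with_pc):
        pc = PhotoconversionSpec(final_time=(2 + 40) * 0.023)
        _, series, state = run_transport(
            slab_with_pc, _still_flow(slab_with_pc),
            SoluteSpec("dendra2", 1.15e-10), pc,
            TransportDiscretization(degree=1), n_cycles=2, steps_per_cycle=20,
            record_stride=5,
        )
        # ROI_1 is the prescribed region: its mean equals the curve exactly
        for t, mean in zip(series.times[1:], series.means[1:, 0]):
            assert mean == pytest.approx(pc.value(t), rel=1e-9)
        assert series.means[-1].min() >= -1e-3
        assert series.means[-1].max() <= 1.0 + 1e-3
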