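"""Dimensional-analysis formulas, ROI reductions and force integrals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciliaflow.mesh import FacetLabel, box_mesh
from ciliaflow.quantities import (
    NEVER_EXCEEDED,
    PhysicalConstants,
    ROITimeSeries,
    ThresholdSpec,
    force_density,
    mass_scaled_diffusivity,
    peclet,
    reynolds,
    roi_mean_series,
    stokes_einstein_diffusivity,
    tangential_force,
    time_to_threshold,
    timescales,
)
from ciliaflow.stokes import CiliaRegion, CiliaTractionSpec, tangential_projection


class TestClosedForms:
    def test_stokes_einstein_scaling(self):
        d = stokes_einstein_diffusivity(150e-9, 0.7e-3)
        assert d == pytest.approx(2.17e-12, rel=0.01)
        assert stokes_einstein_diffusivity(300e-9, 0.7e-3) == pytest.approx(d / 2)
        assert stokes_einstein_diffusivity(75e-9, 0.7e-3) == pytest.approx(2 * d)

    def test_stokes_einstein_times_radius_constant(self):
        vals = [stokes_einstein_diffusivity(r, 0.7e-3) * r for r in (1e-9, 5e-8, 2e-6)]
        assert np.allclose(vals, vals[0])

    def test_mass_scaling(self):
        d2 = mass_scaled_diffusivity(8.70e-11, 26.9, 66.2 + 26.9)
        assert d2 == pytest.approx(5.75e-11, rel=5e-3)
        assert mass_scaled_diffusivity(1e-10, 30.0, 30.0) == pytest.approx(1e-10)
        assert mass_scaled_diffusivity(1e-10, 10.0, 80.0) == pytest.approx(0.5e-10)

    def test_peclet(self):
        assert round(peclet(600e-6, 2.4e-6, 2.17e-12)) == 664
        assert round(peclet(600e-6, 2.4e-6, 1.15e-10)) == 13
        assert peclet(600e-6, 4.8e-6, 1e-10) == pytest.approx(
            2 * peclet(600e-6, 2.4e-6, 1e-10)
        )
        with pytest.raises(ValueError):
            peclet(600e-6, 2.4e-6, 0.0)

    def test_reynolds(self):
        re = reynolds(1000.0, 27.9e-6, 110e-6, 0.7e-3)
        assert re == pytest.approx(0.004, abs=5e-4)
        assert reynolds(1000.0, 0.0, 110e-6, 0.7e-3) == 0.0
        assert reynolds(1.0, 1.0, 1.0, 1.0) == 1.0

    def test_timescales(self):
        t_a, _ = timescales(200e-6, 2.4e-6, 1e-10)
        assert round(t_a) == 83
        _, t_d = timescales(200e-6, 2.4e-6, 1.15e-10)
        assert round(t_d) == 348
        t_a2, t_d2 = timescales(400e-6, 2.4e-6, 1.15e-10)
        assert t_a2 == pytest.approx(2 * t_a)
        assert t_d2 == pytest.approx(4 * t_d)

    def test_force_density(self):
        assert force_density(2.5e-3, 15e-6) == pytest.approx(166.7, rel=1e-3)
        assert force_density(2.535e-3, 5e-6) == pytest.approx(507.0, rel=1e-3)
        assert force_density(1.0, 2e-6) == pytest.approx(force_density(1.0, 1e-6) / 2)
        with pytest.raises(ValueError):
            force_density(1.0, 0.0)

    @given(
        L=st.floats(1e-6, 1e-2), U=st.floats(1e-8, 1e-3), D=st.floats(1e-13, 1e-9)
    )
    @settings(max_examples=50, deadline=None)
    def test_peclet_round_trip(self, L, U, D):
        assert peclet(L, U, D) * D / (L * U) == pytest.approx(1.0)


class TestTangentialProjection:
    def test_examples(self):
        assert np.allclose(
            tangential_projection((1, 0, 1), (0, 0, 1)), (1, 0, 0)
        )
        assert np.allclose(tangential_projection((0, 0, 2), (0, 0, 1)), 0.0)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            tangential_projection((1, 0, 0), (0, 0, 2))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_pythagoras(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.standard_normal(3)
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        p = tangential_projection(r, n)
        assert abs(np.dot(p, n)) < 1e-12
        assert np.dot(p, p) + np.dot(r, n) ** 2 == pytest.approx(np.dot(r, r))


class TestTangentialForce:
    @pytest.fixture()
    def flat_patch_mesh(self):
        mesh = box_mesh((3, 3, 3))
        # top face (n = +z) becomes a cilia patch
        top = [
            int(f)
            for f in mesh.boundary_facets
            if abs(mesh.facet_midpoints[f][2] - 1.0) < 1e-12
        ]
        for f in top:
            mesh.facet_labels[f] = int(FacetLabel.CILIA_DORSAL_MID)
        return mesh

    def test_constant_traction_on_flat_patch(self, flat_patch_mesh):
        # r = (1, 0, 1) on the flat top: tangential part (1, 0, 0), |tau| = tau0
        cilia = CiliaTractionSpec(amplitude=0.65e-3)
        F = tangential_force(flat_patch_mesh, cilia, FacetLabel.CILIA_DORSAL_MID)
        assert F == pytest.approx(0.65e-3 * 1.0, rel=1e-12)

    def test_additivity_over_disjoint_regions(self, flat_patch_mesh):
        mesh = flat_patch_mesh
        bottom = [
            int(f)
            for f in mesh.boundary_facets
            if abs(mesh.facet_midpoints[f][2]) < 1e-12
        ]
        for f in bottom:
            mesh.facet_labels[f] = int(FacetLabel.CILIA_VENTRAL_MID)
        cilia = CiliaTractionSpec()
        both = tangential_force(
            mesh, cilia, [FacetLabel.CILIA_DORSAL_MID, FacetLabel.CILIA_VENTRAL_MID]
        )
        parts = tangential_force(
            mesh, cilia, FacetLabel.CILIA_DORSAL_MID
        ) + tangential_force(mesh, cilia, FacetLabel.CILIA_VENTRAL_MID)
        assert both == pytest.approx(parts, rel=1e-12)

    def test_quadrature_refinement_agreement(self, flat_patch_mesh):
        # a spatially varying weight exercises the facet quadrature
        cilia = CiliaTractionSpec()
        cilia.regions[int(FacetLabel.CILIA_DORSAL_MID)] = CiliaRegion(
            (1.0, 0.0, 1.0), weight=lambda p: 1.0 + 0.5 * np.sin(3 * p[:, 0])
        )
        coarse = tangential_force(
            flat_patch_mesh, cilia, FacetLabel.CILIA_DORSAL_MID, quad_degree=4
        )
        fine = tangential_force(
            flat_patch_mesh, cilia, FacetLabel.CILIA_DORSAL_MID, quad_degree=10
        )
        assert coarse == pytest.approx(fine, rel=1e-6)

    def test_empty_region_warns_and_returns_zero(self, flat_patch_mesh):
        with pytest.warns(UserWarning):
            F = tangential_force(
                flat_patch_mesh, CiliaTractionSpec(), FacetLabel.CILIA_ANTERIOR
            )
        assert F == 0.0


class TestROISeries:
    def test_constant_field_means(self):
        series = ROITimeSeries(
            times=np.array([0.0, 1.0]),
            means=np.full((2, 6), 0.4),
            roi_volumes=np.ones(6),
        )
        assert np.allclose(series.means, 0.4)

    def test_roi_mean_series_rejects_empty_roi(self):
        with pytest.raises(ValueError, match="ROI_2"):
            roi_mean_series(
                np.array([0.0]), np.zeros((1, 6)), np.array([1, 0, 1, 1, 1, 1.0])
            )

    def test_union_mean_is_volume_weighted_average(self):
        # two ROIs with volumes 1 and 3 and means 0.2 / 0.6
        v = np.array([1.0, 3.0])
        integrals = np.array([[0.2 * 1.0, 0.6 * 3.0]])
        union_mean = integrals.sum() / v.sum()
        assert union_mean == pytest.approx((0.2 * 1 + 0.6 * 3) / 4)

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            ROITimeSeries(
                times=np.array([1.0, 0.5]),
                means=np.zeros((2, 6)),
                roi_volumes=np.ones(6),
            )


class TestTimeToThreshold:
    def _series(self, times, values):
        means = np.tile(np.asarray(values)[:, None], (1, 6))
        return ROITimeSeries(
            times=np.asarray(times), means=means, roi_volumes=np.ones(6)
        )

    def test_first_exceedance(self):
        s = self._series([0.0, 1.0, 2.0], [0.0, 0.2, 0.3])
        t = time_to_threshold(s, ThresholdSpec((0.25,) * 6))
        assert np.allclose(t, 2.0)

    def test_never_exceeded_marker(self):
        s = self._series([0.0, 1.0], [0.0, 0.05])
        t = time_to_threshold(s)
        assert np.all(t == NEVER_EXCEEDED)

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        values = np.sort(rng.uniform(0, 1, size=12))
        times = np.arange(12, dtype=float)
        s = self._series(times, values)
        spec = ThresholdSpec((0.5,) * 6)
        t = time_to_threshold(s, spec)[0]
        brute = next((tt for tt, v in zip(times, values) if v > 0.5), NEVER_EXCEEDED)
        assert t == brute

    def test_monotone_in_threshold(self):
        s = self._series(np.arange(5, dtype=float), [0.0, 0.1, 0.3, 0.5, 0.9])
        lo = time_to_threshold(s, ThresholdSpec((0.05,) * 6))[0]
        hi = time_to_threshold(s, ThresholdSpec((0.8,) * 6))[0]
        assert lo <= hi

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            ThresholdSpec((0.0,) * 6)


def test_physical_constants_defaults():
    consts = PhysicalConstants()
    assert consts.boltzmann == pytest.approx(1.38e-23)
    assert consts.temperature == 310.0
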