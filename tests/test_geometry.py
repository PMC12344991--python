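"""Synthetic ventricle generation, variants and measurement."""

import numpy as np
import pytest

from ciliaflow.geometry import (
    GeometryParameterError,
    GeometryVariant,
    VentricleParams,
    apply_geometry_variant,
    build_synthetic_ventricles,
    cross_section_area,
    measure_geometry,
    min_duct_cross_section,
)
from ciliaflow.mesh import (
    FacetLabel,
    PHOTOCONVERSION,
    ROI_NAMES,
    UM,
    box_mesh,
)


class TestVariants:
    def test_constrict_anterior_middle(self):
        p = apply_geometry_variant(VentricleParams.default(), "constrict_anterior_middle")
        assert p.duct_area_factors == (0.34, 1.0)
        assert p.middle_lateral_factor == 1.0

    def test_constrict_middle_posterior(self):
        p = apply_geometry_variant(
            VentricleParams.default(), GeometryVariant.CONSTRICT_MIDDLE_POSTERIOR
        )
        assert p.duct_area_factors == (1.0, 0.67)

    def test_shrink_middle(self):
        p = apply_geometry_variant(VentricleParams.default(), "shrink_middle")
        assert p.middle_lateral_factor == 0.57

    def test_combined(self):
        p = apply_geometry_variant(VentricleParams.default(), "combined")
        assert p.duct_area_factors == (0.34, 0.67)
        assert p.middle_lateral_factor == 0.57

    def test_idempotent(self):
        p1 = apply_geometry_variant(VentricleParams.default(), "shrink_middle")
        p2 = apply_geometry_variant(p1, "shrink_middle")
        assert p1 == p2

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            apply_geometry_variant(VentricleParams.default(), "squash_everything")

    def test_other_fields_unchanged(self):
        base = VentricleParams.default()
        p = apply_geometry_variant(base, "combined")
        assert p.duct_radii == base.duct_radii
        assert p.roi_centers == base.roi_centers


class TestParameterValidation:
    def test_nonpositive_length_rejected(self):
        with pytest.raises(GeometryParameterError):
            VentricleParams.default(target_edge_length=-1.0).validate()

    def test_factor_out_of_range(self):
        import dataclasses

        p = dataclasses.replace(VentricleParams.default(), duct_area_factors=(1.5, 1.0))
        with pytest.raises(GeometryParameterError):
            p.validate()

    def test_duct_radius_vs_chamber(self):
        import dataclasses

        p = dataclasses.replace(VentricleParams.default(), duct_radii=(80.0, 25.0))
        with pytest.raises(GeometryParameterError):
            p.validate()

    def test_overlapping_rois_rejected(self):
        import dataclasses

        base = VentricleParams.default()
        centers = list(base.roi_centers)
        centers[1] = tuple(np.asarray(centers[0]) + 5.0)
        p = dataclasses.replace(base, roi_centers=tuple(centers))
        with pytest.raises(GeometryParameterError):
            p.validate()


class TestBuiltMesh:
    def test_labels_partition_boundary(self, ventricle_mesh):
        # every boundary facet carries exactly one label; validate() checks
        # the partition and the closed-manifold property
        ventricle_mesh.validate()
        bd = set(ventricle_mesh.boundary_facets.tolist())
        assert set(ventricle_mesh.facet_labels) == bd
        labels = set(ventricle_mesh.facet_labels.values())
        assert labels <= {int(l) for l in FacetLabel}
        # all three cilia patches and both caps exist
        for lab in FacetLabel:
            assert len(ventricle_mesh.facets_with_label(lab)) > 0

    def test_boundary_is_genus_zero(self, ventricle_mesh):
        assert ventricle_mesh.boundary_euler_characteristic() == 2

    def test_photoconversion_cells_are_roi1(self, ventricle_mesh):
        assert np.array_equal(
            np.sort(ventricle_mesh.cell_sets[PHOTOCONVERSION]),
            np.sort(ventricle_mesh.cell_sets["ROI_1"]),
        )

    def test_all_rois_nonempty_and_disjoint(self, ventricle_mesh):
        seen = set()
        for name in ROI_NAMES:
            cells = set(ventricle_mesh.cell_sets[name].tolist())
            assert cells
            assert not cells & seen
            seen |= cells

    def test_min_edge_below_target(self, ventricle_mesh, fixture_params):
        report = measure_geometry(ventricle_mesh, fixture_params)
        assert report.min_edge_length <= fixture_params.target_edge_length

    def test_local_refinement_near_photoconversion(self):
        # full-scale radius (50 um) spans several cells of the 14 um grid,
        # so the graded zone is resolvable
        params = VentricleParams.default(target_edge_length=14.0, refine_factor=2.5)
        mesh = build_synthetic_ventricles(params)
        centroids = mesh.cell_centroids / UM
        sizes = np.cbrt(mesh.cell_volumes / UM ** 3)
        d = np.linalg.norm(centroids - np.asarray(params.pc_center), axis=1)
        # sample the core of the graded zone, where the spacing reduction is
        # fully developed
        near = sizes[d < 0.5 * params.refine_radius].mean()
        far = sizes[d > 3 * params.refine_radius].mean()
        assert near < 0.75 * far


class TestMeasurement:
    def test_unit_cube_volume(self):
        mesh = box_mesh((3, 3, 3))
        # box fixture is in abstract units; measure_geometry reports um^3
        assert mesh.total_volume == pytest.approx(1.0, rel=1e-12)

    def test_cross_section_of_box(self):
        # a 1 um cube stored in metres: any interior plane cuts 1 um^2
        mesh = box_mesh((4, 4, 4), (UM, UM, UM))
        assert cross_section_area(mesh, 0.38) == pytest.approx(1.0, rel=1e-10)

    def test_roi_volumes_sum_below_total(self, ventricle_mesh, fixture_params):
        report = measure_geometry(ventricle_mesh, fixture_params)
        assert sum(report.roi_volumes.values()) < report.total_volume
        assert all(v > 0 for v in report.roi_volumes.values())

    def test_shrink_middle_reduces_volume(self):
        base = VentricleParams.default(scale=0.35, target_edge_length=10.0,
                                       refine_factor=1.5)
        shrunk = apply_geometry_variant(base, "shrink_middle")
        v0 = build_synthetic_ventricles(base).total_volume
        v1 = build_synthetic_ventricles(shrunk).total_volume
        assert v1 < v0

    def test_variant_monotonicity_duct_constriction(self):
        base = VentricleParams.default(scale=0.35, target_edge_length=10.0,
                                       refine_factor=1.5)
        constricted = apply_geometry_variant(base, "constrict_anterior_middle")
        v0 = build_synthetic_ventricles(base).total_volume
        v1 = build_synthetic_ventricles(constricted).total_volume
        assert v1 < v0


class TestDuctConstriction:
    def test_measured_area_ratio_matches_request(self):
        """Requested 66% cross-section reduction is recovered by planar
        slicing of the carved meshes at the default resolution."""
        base = VentricleParams.default()
        constricted = apply_geometry_variant(base, "constrict_anterior_middle")
        m0 = build_synthetic_ventricles(base)
        m1 = build_synthetic_ventricles(constricted)
        a0 = min_duct_cross_section(m0, base.duct_windows()[0])
        a1 = min_duct_cross_section(m1, constricted.duct_windows()[0])
        assert a1 / a0 == pytest.approx(0.34, rel=0.05)

    def test_refinement_cell_count_bound(self):
        coarse = VentricleParams.default(scale=0.4, target_edge_length=16.0,
                                         refine_factor=1.0)
        fine = VentricleParams.default(scale=0.4, target_edge_length=8.0,
                                       refine_factor=1.0)
        n0 = build_synthetic_ventricles(coarse).num_cells
        n1 = build_synthetic_ventricles(fine).num_cells
        assert 4 <= n1 / n0 <= 16
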