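"""Synthetic ventricular geometries.

The embryonic zebrafish ventricular system at 2 dpf is approximated by three
chambers (anterior/telencephalic, middle/di-mesencephalic,
posterior/rhombencephalic) joined by two narrow interventricular ducts,
spanning roughly 600 um rostrocaudally, ~300 um laterally and ~100 um
dorsoventrally.  Chambers are ellipsoids, ducts are x-aligned circular
cylinders, combined by a smooth union of approximate signed distances; the
anterior and posterior tips are truncated by flat planes that become the
pressure end caps.

Meshing carves a structured Freudenthal tetrahedral grid against the implicit
function, with a smooth radial grading map that reduces the local spacing
around the photoconversion centre, followed by Newton projection of boundary
vertices onto the zero level set.  All :class:`VentricleParams` lengths are in
micrometres; the resulting :class:`~ciliaflow.mesh.LabeledMesh` stores metres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .mesh import (
    UM,
    FacetLabel,
    LabeledMesh,
    MeshError,
    PHOTOCONVERSION,
    ROI_NAMES,
)


class GeometryParameterError(ValueError):
    """Infeasible ventricle parameters."""


class MeshGenerationError(RuntimeError):
    """The carving mesher failed to produce a valid labeled mesh."""


class GeometryVariant(str, Enum):
    """Parametric deformations mimicking interindividual morphology variation:
    duct constrictions (66% and 33% cross-sectional area reductions) and a
    lateral shrinkage (43%) of the middle ventricle."""

    CONSTRICT_ANTERIOR_MIDDLE = "constrict_anterior_middle"
    CONSTRICT_MIDDLE_POSTERIOR = "constrict_middle_posterior"
    SHRINK_MIDDLE = "shrink_middle"
    COMBINED = "combined"


_DEFAULT_ROI_CENTERS = (
    (0.0, 0.0, 30.0),     # ROI 1: dorsal middle chamber = photoconversion site
    (60.0, 0.0, 15.0),    # ROI 2: posterior-dorsal middle chamber
    (0.0, 0.0, -30.0),    # ROI 3: ventral middle chamber
    (-60.0, 0.0, 0.0),    # ROI 4: anterior part of the middle chamber
    (-223.75, 0.0, 0.0),  # ROI 5: anterior chamber
    (223.75, 0.0, 0.0),   # ROI 6: posterior chamber
)


@dataclass(frozen=True)
class VentricleParams:
    """Parameters of the synthetic three-chamber ventricle (lengths in um)."""

    anterior_semi_axes: tuple[float, float, float] = (75.0, 70.0, 45.0)
    middle_semi_axes: tuple[float, float, float] = (110.0, 140.0, 55.0)
    posterior_semi_axes: tuple[float, float, float] = (75.0, 80.0, 50.0)
    duct_radii: tuple[float, float] = (22.0, 25.0)
    duct_lengths: tuple[float, float] = (85.0, 85.0)
    duct_area_factors: tuple[float, float] = (1.0, 1.0)
    middle_lateral_factor: float = 1.0
    target_edge_length: float = 12.0
    refine_radius: float = 50.0
    refine_factor: float = 2.0  # local spacing reduction near the pc centre
    pc_center: tuple[float, float, float] = (0.0, 0.0, 30.0)
    pc_radius: float = 15.0
    roi_centers: tuple[tuple[float, float, float], ...] = _DEFAULT_ROI_CENTERS
    roi_radii: tuple[float, ...] = (15.0,) * 6
    cap_inset_frac: float = 0.7     # cap plane at centre -+ frac * semi-axis
    blend_width: float = 15.0       # smooth-union width
    # cilia patch extents, as fractions of the relevant semi-axes
    cilia_mid_z_frac: float = 0.5
    cilia_mid_x_frac: float = 0.7
    cilia_ant_x_frac: float = 0.7
    cilia_ant_z_frac: float = 0.25

    # -- derived placement ---------------------------------------------------

    @property
    def anterior_center_x(self) -> float:
        return -(0.75 * self.middle_semi_axes[0] + self.duct_lengths[0]
                 + 0.75 * self.anterior_semi_axes[0])

    @property
    def posterior_center_x(self) -> float:
        return (0.75 * self.middle_semi_axes[0] + self.duct_lengths[1]
                + 0.75 * self.posterior_semi_axes[0])

    @property
    def cap_anterior_x(self) -> float:
        return self.anterior_center_x - self.cap_inset_frac * self.anterior_semi_axes[0]

    @property
    def cap_posterior_x(self) -> float:
        return self.posterior_center_x + self.cap_inset_frac * self.posterior_semi_axes[0]

    def duct_windows(self) -> list[tuple[float, float]]:
        """x-ranges where each duct is the only structure (for cross-section
        measurements), slightly inset from the chamber surfaces."""
        inset = max(1.5 * self.blend_width, self.target_edge_length)
        w1 = (self.anterior_center_x + self.anterior_semi_axes[0] + inset,
              -self.middle_semi_axes[0] - inset)
        w2 = (self.middle_semi_axes[0] + inset,
              self.posterior_center_x - self.posterior_semi_axes[0] - inset)
        return [w1, w2]

    def effective_duct_radii(self) -> tuple[float, float]:
        # cross-sectional area scales with radius squared
        return tuple(
            r * np.sqrt(f) for r, f in zip(self.duct_radii, self.duct_area_factors)
        )

    def validate(self) -> None:
        lengths = (
            list(self.anterior_semi_axes) + list(self.middle_semi_axes)
            + list(self.posterior_semi_axes) + list(self.duct_radii)
            + list(self.duct_lengths)
            + [self.target_edge_length, self.refine_radius, self.pc_radius]
            + list(self.roi_radii)
        )
        if any(not np.isfinite(v) or v <= 0 for v in lengths):
            raise GeometryParameterError("all lengths must be positive and finite")
        for f in (*self.duct_area_factors, self.middle_lateral_factor):
            if not 0.0 < f <= 1.0:
                raise GeometryParameterError("scale factors must lie in (0, 1]")
        semis = [self.anterior_semi_axes, self.middle_semi_axes, self.posterior_semi_axes]
        if any(r >= min(min(s[1], s[2]) for s in semis) for r in self.duct_radii):
            raise GeometryParameterError(
                "duct radius must be smaller than the adjacent chamber semi-axes"
            )
        centers = np.asarray(self.roi_centers, dtype=float)
        radii = np.asarray(self.roi_radii, dtype=float)
        if len(centers) != 6 or len(radii) != 6:
            raise GeometryParameterError("exactly six ROIs are required")
        for i in range(6):
            for j in range(i + 1, 6):
                if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                    raise GeometryParameterError(
                        f"ROI balls {i + 1} and {j + 1} overlap"
                    )
        if self.implicit(centers).max() >= 0:
            raise GeometryParameterError("every ROI centre must lie inside the domain")

    @classmethod
    def default(cls, scale: float = 1.0, target_edge_length: float | None = None,
                **overrides) -> "VentricleParams":
        """Default geometry, optionally scaled uniformly (scale < 1 yields the
        reduced-scale fixtures used for desk-size runs)."""
        base = cls()

        def s3(t):
            return tuple(scale * v for v in t)

        params = dict(
            anterior_semi_axes=s3(base.anterior_semi_axes),
            middle_semi_axes=s3(base.middle_semi_axes),
            posterior_semi_axes=s3(base.posterior_semi_axes),
            duct_radii=tuple(scale * v for v in base.duct_radii),
            duct_lengths=tuple(scale * v for v in base.duct_lengths),
            refine_radius=scale * base.refine_radius,
            pc_center=s3(base.pc_center),
            pc_radius=scale * base.pc_radius,
            roi_centers=tuple(s3(c) for c in base.roi_centers),
            roi_radii=tuple(scale * v for v in base.roi_radii),
            blend_width=scale * base.blend_width,
            target_edge_length=(
                target_edge_length if target_edge_length is not None
                else scale * base.target_edge_length
            ),
        )
        params.update(overrides)
        return cls(**params)

    # -- implicit geometry ---------------------------------------------------

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """Approximate signed distance (um); negative inside the domain."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

        def ellipsoid(cx, semi, lateral=1.0):
            ax, ay, az = semi[0], semi[1] * lateral, semi[2]
            q = np.sqrt(((x - cx) / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)
            return (q - 1.0) * min(ax, ay, az)

        def duct(radius, x_lo, x_hi):
            d = np.sqrt(y ** 2 + z ** 2) - radius
            return np.maximum(d, np.maximum(x_lo - x, x - x_hi))

        r1, r2 = self.effective_duct_radii()
        parts = [
            ellipsoid(self.anterior_center_x, self.anterior_semi_axes),
            ellipsoid(0.0, self.middle_semi_axes, self.middle_lateral_factor),
            ellipsoid(self.posterior_center_x, self.posterior_semi_axes),
            duct(r1, self.anterior_center_x + 0.4 * self.anterior_semi_axes[0],
                 -0.4 * self.middle_semi_axes[0]),
            duct(r2, 0.4 * self.middle_semi_axes[0],
                 self.posterior_center_x - 0.4 * self.posterior_semi_axes[0]),
        ]
        phi = parts[0]
        for p in parts[1:]:
            phi = _smooth_min(phi, p, self.blend_width)
        # flat truncation planes -> pressure end caps
        phi = np.maximum(phi, self.cap_anterior_x - x)
        phi = np.maximum(phi, x - self.cap_posterior_x)
        return phi


def _smooth_min(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


def apply_geometry_variant(
    params: VentricleParams, variant: GeometryVariant | str
) -> VentricleParams:
    """Return a copy of ``params`` with the deformation factors of the named
    variant applied (66% / 33% cross-section reduction of the anterior-middle /
    middle-posterior duct; 43% lateral reduction of the middle chamber).
    Idempotent: factors are set absolutely, not compounded."""
    variant = GeometryVariant(variant)
    if variant is GeometryVariant.CONSTRICT_ANTERIOR_MIDDLE:
        changes = dict(duct_area_factors=(0.34, 1.0), middle_lateral_factor=1.0)
    elif variant is GeometryVariant.CONSTRICT_MIDDLE_POSTERIOR:
        changes = dict(duct_area_factors=(1.0, 0.67), middle_lateral_factor=1.0)
    elif variant is GeometryVariant.SHRINK_MIDDLE:
        changes = dict(duct_area_factors=(1.0, 1.0), middle_lateral_factor=0.57)
    else:  # combined
        changes = dict(duct_area_factors=(0.34, 0.67), middle_lateral_factor=0.57)
    return dataclasses.replace(params, **changes)


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------


def build_synthetic_ventricles(params: VentricleParams) -> LabeledMesh:
    """Carve, label and validate a synthetic ventricle mesh."""
    params.validate()
    h = params.target_edge_length
    margin = 2.0 * h + (1.0 - 1.0 / params.refine_factor) * params.refine_radius

    lo = np.array([
        params.cap_anterior_x,
        -max(params.anterior_semi_axes[1], params.middle_semi_axes[1],
             params.posterior_semi_axes[1]),
        -max(params.anterior_semi_axes[2], params.middle_semi_axes[2],
             params.posterior_semi_axes[2]),
    ]) - margin
    hi = np.array([
        params.cap_posterior_x,
        -lo[1] - 2 * margin,
        -lo[2] - 2 * margin,
    ]) + margin
    hi[1] = -lo[1]
    hi[2] = -lo[2]

    points, cells = _structured_grid(lo, hi, h)
    points = _refinement_warp(points, params)

    phi_centroid = params.implicit(points[cells].mean(axis=1))
    keep = phi_centroid < 0.0
    if not keep.any():
        raise MeshGenerationError("no cells inside the implicit domain")
    cells = cells[keep]
    cells = _largest_component(cells)
    cells = _strip_spikes(points, cells)
    points, cells = _compact(points, cells)
    points = _project_boundary(points, cells, params, h)

    mesh = LabeledMesh(points=points * UM, cells=cells)
    _label_facets(mesh, params)
    _label_cells(mesh, params)
    try:
        mesh.validate()
    except MeshError as exc:
        raise MeshGenerationError(
            f"carved mesh failed validation: {exc}; "
            "try a smaller target edge length relative to the duct radii"
        ) from exc
    return mesh


def _structured_grid(lo, hi, h):
    n = np.maximum(np.ceil((hi - lo) / h).astype(int), 2)
    from .mesh import box_mesh

    box = box_mesh(tuple(n), tuple(hi - lo), tuple(lo))
    return box.points, box.cells


def _refinement_warp(points: np.ndarray, params: VentricleParams) -> np.ndarray:
    """Radial grading: spacing near the photoconversion centre is reduced by
    ``refine_factor``, smoothly recovering the background spacing outside
    ``refine_radius``."""
    s = 1.0 / params.refine_factor
    w = params.refine_radius
    c = np.asarray(params.pc_center, dtype=float)
    d = points - c
    rho = np.linalg.norm(d, axis=1)
    g = s * rho + (1.0 - s) * w * np.log(np.cosh(rho / w))
    scale = np.ones_like(rho)
    nz = rho > 1e-12
    scale[nz] = g[nz] / rho[nz]
    return c + d * scale[:, None]


def _largest_component(cells: np.ndarray) -> np.ndarray:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    tri = np.sort(
        np.concatenate([cells[:, [1, 2, 3]], cells[:, [0, 2, 3]],
                        cells[:, [0, 1, 3]], cells[:, [0, 1, 2]]]), axis=1
    )
    _, inv = np.unique(tri, axis=0, return_inverse=True)
    owner = np.tile(np.arange(len(cells)), 4)
    order = np.argsort(inv, kind="stable")
    inv_s, own_s = inv[order], owner[order]
    same = inv_s[1:] == inv_s[:-1]
    a, b = own_s[:-1][same], own_s[1:][same]
    graph = coo_matrix(
        (np.ones(len(a)), (a, b)), shape=(len(cells), len(cells))
    )
    ncomp, labels = connected_components(graph, directed=False)
    if ncomp == 1:
        return cells
    best = np.bincount(labels).argmax()
    return cells[labels == best]


def _strip_spikes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Iteratively remove cells with three or more boundary facets; such
    spikes degrade the carved surface and can pinch the boundary."""
    for _ in range(20):
        tri = np.sort(
            np.concatenate([cells[:, [1, 2, 3]], cells[:, [0, 2, 3]],
                            cells[:, [0, 1, 3]], cells[:, [0, 1, 2]]]), axis=1
        )
        _, inv, counts = np.unique(tri, axis=0, return_inverse=True, return_counts=True)
        n_bnd = (counts[inv] == 1).reshape(4, -1).sum(axis=0)
        spikes = n_bnd >= 3
        if not spikes.any():
            return cells
        cells = cells[~spikes]
        if len(cells) == 0:
            raise MeshGenerationError("carving removed every cell (domain too thin)")
    return cells


def _compact(points, cells):
    used, inv = np.unique(cells, return_inverse=True)
    return points[used], inv.reshape(cells.shape)


def _project_boundary(points, cells, params, h):
    """Newton-project boundary vertices onto the zero level set, backing off
    where a projection would invert an adjacent tetrahedron."""
    tri = np.sort(
        np.concatenate([cells[:, [1, 2, 3]], cells[:, [0, 2, 3]],
                        cells[:, [0, 1, 3]], cells[:, [0, 1, 2]]]), axis=1
    )
    uniq, counts = np.unique(tri, axis=0, return_counts=True)
    bverts = np.unique(uniq[counts == 1])

    target = points.copy()
    x = points[bverts].copy()
    delta = 0.05 * h
    for _ in range(6):
        phi = params.implicit(x)
        grad = np.empty_like(x)
        for d in range(3):
            step = np.zeros(3)
            step[d] = delta
            grad[:, d] = (params.implicit(x + step) - params.implicit(x - step)) / (2 * delta)
        norm2 = np.einsum("ij,ij->i", grad, grad)
        norm2 = np.where(norm2 < 1e-12, 1.0, norm2)
        x = x - (phi / norm2)[:, None] * grad
    disp = x - points[bverts]
    dist = np.linalg.norm(disp, axis=1)
    cap = 0.87 * h  # max stairstep distance of a carved vertex to the surface
    over = dist > cap
    disp[over] *= (cap / dist[over])[:, None]
    target[bverts] = points[bverts] + disp

    # back off wherever a cell would invert or collapse: a cell may lose at
    # most 4/5 of its unprojected volume.  Strongly degenerate slivers would
    # otherwise poison the conditioning of every solver downstream
    v0 = points[cells]
    vol0 = np.einsum(
        "ij,ij->i",
        np.cross(v0[:, 1] - v0[:, 0], v0[:, 2] - v0[:, 0]), v0[:, 3] - v0[:, 0],
    )
    scale = np.ones(len(points))
    for _ in range(10):
        trial = points + (target - points) * scale[:, None]
        v = trial[cells]
        vol = np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), v[:, 3] - v[:, 0],
        )
        bad = vol <= 0.2 * vol0
        if not bad.any():
            return trial
        scale[np.unique(cells[bad])] *= 0.5
    scale_final = np.where(scale < 0.4, 0.0, scale)
    return points + (target - points) * scale_final[:, None]


def _label_facets(mesh: LabeledMesh, params: VentricleParams) -> None:
    bf = mesh.boundary_facets
    mid = mesh.facet_midpoints[bf] / UM  # um
    x, y, z = mid[:, 0], mid[:, 1], mid[:, 2]
    h = params.target_edge_length
    labels = np.full(len(bf), int(FacetLabel.SLIP_WALL))

    cap_tol = 0.35 * h
    labels[np.abs(x - params.cap_anterior_x) < cap_tol] = int(FacetLabel.PRESSURE_ANTERIOR)
    labels[np.abs(x - params.cap_posterior_x) < cap_tol] = int(FacetLabel.PRESSURE_POSTERIOR)

    msx, _, msz = params.middle_semi_axes
    free = labels == int(FacetLabel.SLIP_WALL)
    in_mid_x = np.abs(x) < params.cilia_mid_x_frac * msx
    dorsal = free & in_mid_x & (z > params.cilia_mid_z_frac * msz)
    ventral = free & in_mid_x & (z < -params.cilia_mid_z_frac * msz)
    labels[dorsal] = int(FacetLabel.CILIA_DORSAL_MID)
    labels[ventral] = int(FacetLabel.CILIA_VENTRAL_MID)

    asx, _, asz = params.anterior_semi_axes
    free = labels == int(FacetLabel.SLIP_WALL)
    anterior = (
        free
        & (np.abs(x - params.anterior_center_x) < params.cilia_ant_x_frac * asx)
        & (z > params.cilia_ant_z_frac * asz)
    )
    labels[anterior] = int(FacetLabel.CILIA_ANTERIOR)

    mesh.facet_labels = {int(f): int(l) for f, l in zip(bf, labels)}


def _label_cells(mesh: LabeledMesh, params: VentricleParams) -> None:
    centroids = mesh.cell_centroids / UM
    sets: dict[str, np.ndarray] = {}
    for name, center, radius in zip(ROI_NAMES, params.roi_centers, params.roi_radii):
        d = np.linalg.norm(centroids - np.asarray(center), axis=1)
        idx = np.nonzero(d < radius)[0]
        if len(idx) == 0:
            # guarantee a nonempty ROI: take the nearest cell
            idx = np.array([int(np.argmin(d))])
        sets[name] = idx
    sets[PHOTOCONVERSION] = sets["ROI_1"].copy()
    mesh.cell_sets = sets


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


@dataclass
class GeometryReport:
    """Volumes in um^3, areas in um^2, lengths in um."""

    total_volume: float
    roi_volumes: dict[str, float]
    min_duct_areas: tuple[float, ...]
    cell_count: int
    max_edge_length: float
    min_edge_length: float

    def to_dict(self) -> dict:
        return {
            "total_volume_um3": self.total_volume,
            "roi_volumes_um3": self.roi_volumes,
            "min_duct_areas_um2": list(self.min_duct_areas),
            "cell_count": self.cell_count,
            "max_edge_length_um": self.max_edge_length,
            "min_edge_length_um": self.min_edge_length,
        }


def cross_section_area(mesh: LabeledMesh, x_plane_um: float) -> float:
    """Area (um^2) of the mesh cross-section with the plane x = const."""
    pts = mesh.points / UM
    v = pts[mesh.cells]  # (nc, 4, 3)
    d = v[:, :, 0] - x_plane_um
    crossing = (d.min(axis=1) < 0) & (d.max(axis=1) > 0)
    area = 0.0
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for cell in np.nonzero(crossing)[0]:
        dv, vv = d[cell], v[cell]
        poly = []
        for i, j in pairs:
            if dv[i] * dv[j] < 0:
                t = dv[i] / (dv[i] - dv[j])
                poly.append(vv[i] + t * (vv[j] - vv[i]))
        for i in range(4):  # vertices exactly on the plane
            if dv[i] == 0.0:
                poly.append(vv[i])
        if len(poly) < 3:
            continue
        q = np.asarray(poly)[:, 1:]  # (y, z)
        centroid = q.mean(axis=0)
        ang = np.arctan2(q[:, 1] - centroid[1], q[:, 0] - centroid[0])
        q = q[np.argsort(ang)]
        x0, y0 = q[:, 0], q[:, 1]
        area += 0.5 * abs(np.dot(x0, np.roll(y0, -1)) - np.dot(y0, np.roll(x0, -1)))
    return float(area)


def min_duct_cross_section(
    mesh: LabeledMesh, window: tuple[float, float], n_planes: int = 9
) -> float:
    xs = np.linspace(window[0], window[1], n_planes)
    return min(cross_section_area(mesh, x) for x in xs)


def measure_geometry(
    mesh: LabeledMesh, params: VentricleParams | None = None
) -> GeometryReport:
    """Exact tetrahedral volumes; duct cross-sections via planar slicing
    when the generating parameters are available."""
    vols = mesh.cell_volumes / UM ** 3
    roi_volumes = {
        name: float(vols[idx].sum())
        for name, idx in mesh.cell_sets.items()
        if name.startswith("ROI")
    }
    duct_areas: tuple[float, ...] = ()
    if params is not None:
        duct_areas = tuple(
            min_duct_cross_section(mesh, w) for w in params.duct_windows()
        )
    edges = mesh.edge_lengths / UM
    return GeometryReport(
        total_volume=float(vols.sum()),
        roi_volumes=roi_volumes,
        min_duct_areas=duct_areas,
        cell_count=mesh.num_cells,
        max_edge_length=float(edges.max()),
        min_edge_length=float(edges.min()),
    )
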