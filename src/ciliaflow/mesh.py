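"""Labeled tetrahedral meshes and their topology.

A :class:`LabeledMesh` is the container every solver in this package consumes:
vertex coordinates (metres, SI internally; user-facing I/O is in micrometres),
tetrahedral connectivity, one label per boundary facet (walls, cilia patches,
pressure end caps) and named cell sets (regions of interest and the
photoconversion region, which may overlap).

The coordinate convention is recorded on the mesh: x increases
anterior -> posterior (rostrocaudal), y is lateral, z ventral -> dorsal, so
that cilia drive directions +-(1, 0, 1) are interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from functools import cached_property

import numpy as np

UM = 1e-6  # micrometre in metres

COORDINATE_CONVENTION = (
    "x: anterior->posterior (rostrocaudal); y: lateral; z: ventral->dorsal; units: m"
)


class FacetLabel(IntEnum):
    SLIP_WALL = 1
    CILIA_ANTERIOR = 2
    CILIA_DORSAL_MID = 3
    CILIA_VENTRAL_MID = 4
    PRESSURE_ANTERIOR = 5
    PRESSURE_POSTERIOR = 6


CILIA_LABELS = (
    FacetLabel.CILIA_ANTERIOR,
    FacetLabel.CILIA_DORSAL_MID,
    FacetLabel.CILIA_VENTRAL_MID,
)
PRESSURE_LABELS = (FacetLabel.PRESSURE_ANTERIOR, FacetLabel.PRESSURE_POSTERIOR)

ROI_NAMES = tuple(f"ROI_{i}" for i in range(1, 7))
PHOTOCONVERSION = "PHOTOCONVERSION"


class MeshError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class LabeledMesh:
    points: np.ndarray                 # (npoints, 3), metres
    cells: np.ndarray                  # (ncells, 4) int
    facet_labels: dict[int, int] = field(default_factory=dict)  # boundary facet -> FacetLabel
    cell_sets: dict[str, np.ndarray] = field(default_factory=dict)
    coordinate_convention: str = COORDINATE_CONVENTION

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self._orient_cells()

    # -- construction helpers ------------------------------------------------

    def _orient_cells(self) -> None:
        """Reorder vertices so every tetrahedron has positive volume."""
        v = self.points[self.cells]
        vol6 = np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        )
        flip = vol6 < 0
        if flip.any():
            self.cells[flip] = self.cells[flip][:, [0, 2, 1, 3]]

    # -- topology ------------------------------------------------------------

    @cached_property
    def num_cells(self) -> int:
        return len(self.cells)

    @cached_property
    def facets(self) -> np.ndarray:
        """Unique facets as sorted vertex triples, shape (nfacets, 3)."""
        return self._facet_data[0]

    @cached_property
    def cell_facets(self) -> np.ndarray:
        """Global facet index of each cell's four facets (local facet i is
        opposite local vertex i); shape (ncells, 4)."""
        return self._facet_data[1]

    @cached_property
    def facet_cells(self) -> np.ndarray:
        """(nfacets, 2): adjacent cells; second entry -1 on the boundary."""
        return self._facet_data[2]

    @cached_property
    def _facet_data(self):
        c = self.cells
        # local facet i = vertices of the cell without local vertex i
        local = np.stack(
            [c[:, [1, 2, 3]], c[:, [0, 2, 3]], c[:, [0, 1, 3]], c[:, [0, 1, 2]]],
            axis=1,
        )  # (ncells, 4, 3)
        tri = np.sort(local.reshape(-1, 3), axis=1)
        uniq, inv, counts = np.unique(
            tri, axis=0, return_inverse=True, return_counts=True
        )
        if counts.max() > 2:
            raise MeshError("non-manifold facet shared by more than two cells")
        cell_facets = inv.reshape(-1, 4)
        nfac = len(uniq)
        facet_cells = np.full((nfac, 2), -1, dtype=np.int64)
        owner = np.repeat(np.arange(len(c)), 4)
        order = np.argsort(inv, kind="stable")
        f_sorted = inv[order]
        o_sorted = owner[order]
        first = np.searchsorted(f_sorted, np.arange(nfac), side="left")
        facet_cells[:, 0] = o_sorted[first]
        second = counts == 2
        facet_cells[second, 1] = o_sorted[first[second] + 1]
        return uniq, cell_facets, facet_cells

    @cached_property
    def boundary_facets(self) -> np.ndarray:
        return np.nonzero(self.facet_cells[:, 1] < 0)[0]

    @cached_property
    def cell_volumes(self) -> np.ndarray:
        v = self.points[self.cells]
        vol = np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        ) / 6.0
        if (vol <= 0).any():
            bad = int(np.argmin(vol))
            raise MeshError(f"degenerate or inverted cell {bad} (volume {vol[bad]:.3e})")
        return vol

    @cached_property
    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    @cached_property
    def facet_areas(self) -> np.ndarray:
        p = self.points[self.facets]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    @cached_property
    def facet_midpoints(self) -> np.ndarray:
        return self.points[self.facets].mean(axis=1)

    @cached_property
    def facet_normals(self) -> np.ndarray:
        """Unit normals; oriented outward from facet_cells[:, 0] (hence
        outward from the domain on boundary facets)."""
        p = self.points[self.facets]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        n /= np.linalg.norm(n, axis=1)[:, None]
        toward = self.facet_midpoints - self.cell_centroids[self.facet_cells[:, 0]]
        sign = np.sign(np.einsum("ij,ij->i", n, toward))
        return n * sign[:, None]

    @cached_property
    def facet_diameters(self) -> np.ndarray:
        p = self.points[self.facets]
        e = np.stack(
            [p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 2] - p[:, 1]], axis=1
        )
        return np.linalg.norm(e, axis=2).max(axis=1)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        c = self.cells
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        edges = np.sort(
            np.concatenate([c[:, [i, j]] for i, j in pairs]), axis=1
        )
        edges = np.unique(edges, axis=0)
        d = self.points[edges[:, 0]] - self.points[edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @cached_property
    def barycentric_gradients(self) -> np.ndarray:
        """(ncells, 4, 3): constant gradient of each barycentric coordinate."""
        v = self.points[self.cells]
        T = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=1)
        Tinv = np.linalg.inv(T)  # rows of Tinv.T are grads of lam1..3
        g = np.transpose(Tinv, (0, 2, 1))  # (ncells, 3 lam, 3 xyz)
        g0 = -g.sum(axis=1, keepdims=True)
        return np.concatenate([g0, g], axis=1)

    # -- labels and validation ----------------------------------------------

    @cached_property
    def facet_label_array(self) -> np.ndarray:
        """(nfacets,) int; 0 on interior facets."""
        arr = np.zeros(len(self.facets), dtype=np.int64)
        for f, lab in self.facet_labels.items():
            arr[f] = int(lab)
        return arr

    def facets_with_label(self, label) -> np.ndarray:
        labels = (
            [int(label)] if np.isscalar(label) or isinstance(label, IntEnum)
            else [int(l) for l in label]
        )
        arr = self.facet_label_array
        return np.nonzero(np.isin(arr, labels))[0]

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`MeshError` on failure."""
        self.cell_volumes  # raises on degenerate cells
        bd = set(self.boundary_facets.tolist())
        labeled = set(self.facet_labels)
        unlabeled = bd - labeled
        if unlabeled:
            raise MeshError(
                f"unlabeled boundary: {len(unlabeled)} boundary facet(s) carry no label"
            )
        stray = labeled - bd
        if stray:
            raise MeshError(f"{len(stray)} labeled facet(s) are not on the boundary")
        bad = {f for f, l in self.facet_labels.items() if int(l) not in set(FacetLabel)}
        if bad:
            raise MeshError(f"unknown facet label values on {len(bad)} facet(s)")
        # closed, edge-manifold boundary surface
        tris = self.facets[self.boundary_facets]
        edges = np.sort(
            np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if (counts != 2).any():
            raise MeshError(
                f"boundary surface is not closed/manifold: "
                f"{(counts != 2).sum()} edge(s) not shared by exactly two facets"
            )
        for name, idx in self.cell_sets.items():
            idx = np.asarray(idx)
            if (idx < 0).any() or (idx >= self.num_cells).any():
                raise MeshError(f"cell set {name!r} references nonexistent cells")
        if PHOTOCONVERSION in self.cell_sets and "ROI_1" in self.cell_sets:
            if not np.array_equal(
                np.sort(self.cell_sets[PHOTOCONVERSION]), np.sort(self.cell_sets["ROI_1"])
            ):
                raise MeshError("PHOTOCONVERSION cells must coincide with ROI_1 cells")

    def boundary_euler_characteristic(self) -> int:
        tris = self.facets[self.boundary_facets]
        verts = np.unique(tris)
        edges = np.unique(
            np.sort(
                np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [0, 2]]]),
                axis=1,
            ),
            axis=0,
        )
        return len(verts) - len(edges) + len(tris)

    @property
    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())


def box_mesh(
    n: tuple[int, int, int],
    lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    label: int = FacetLabel.SLIP_WALL,
) -> LabeledMesh:
    """Structured box mesh from the Freudenthal (Kuhn) 6-tet subdivision.

    Used as the unit-cube / slab fixture for verification; every boundary
    facet carries ``label``.
    """
    nx, ny, nz = n
    xs = [np.linspace(o, o + L, m + 1) for o, L, m in zip(origin, lengths, n)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = {
        (di, dj, dk): vid(I + di, J + dj, K + dk)
        for di in (0, 1) for dj in (0, 1) for dk in (0, 1)
    }
    import itertools

    cells = []
    for perm in itertools.permutations(range(3)):
        path = [(0, 0, 0)]
        for axis in perm:
            step = list(path[-1])
            step[axis] += 1
            path.append(tuple(step))
        cells.append(np.stack([corner[p] for p in path], axis=1))
    cells = np.concatenate(cells)
    mesh = LabeledMesh(points=points, cells=cells)
    mesh.facet_labels = {int(f): int(label) for f in mesh.boundary_facets}
    return mesh
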