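"""Discontinuous Galerkin scaffolding for the solute transport solver.

Scalar fields are represented in a modal basis of shifted, scaled monomials
per cell (degree 2 by default, ten modes per tetrahedron; the first mode is
the constant, so prescribing a cellwise-constant value touches one
coefficient).  Diffusion uses the symmetric interior penalty (SIPG) form with
penalty sigma_F = alpha D k^2 / h_F per facet; advection uses upwind fluxes.
Velocities arrive either as H(div) facet fluxes (from the flow solver; the
facet normal velocity is then single-valued and facetwise constant, making
the upwind choice unambiguous) or as an analytic callable (verification).

The advection operator is applied matrix-free from precomputed cell and
facet-trace blocks, because one operator per cardiac phase would otherwise
be stored; the phase-independent diffusion+mass part is a sparse matrix and
doubles as the core of the preconditioner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import LabeledMesh
from .quadrature import map_to_cells, map_to_facets, tetrahedron_rule, triangle_rule


def _monomial_exponents(degree: int) -> np.ndarray:
    out = []
    for total in range(degree + 1):
        for a in range(total, -1, -1):
            for b in range(total - a, -1, -1):
                out.append((a, b, total - a - b))
    return np.asarray(out, dtype=int)


class DGSpace:
    """Cellwise polynomial space of the given total degree."""

    def __init__(self, mesh: LabeledMesh, degree: int = 2):
        if degree < 1:
            raise ValueError("degree must be >= 1")
        self.mesh = mesh
        self.degree = degree
        self.exponents = _monomial_exponents(degree)
        self.nb = len(self.exponents)
        self.ndof = self.nb * mesh.num_cells
        self.centers = mesh.cell_centroids
        v = mesh.points[mesh.cells]
        self.scales = np.linalg.norm(
            v[:, :, None, :] - v[:, None, :, :], axis=3
        ).max(axis=(1, 2))
        # L2-orthonormalize the monomials per cell (Cholesky of the local
        # mass block): keeps the basis well conditioned on the sliver cells
        # that boundary projection inevitably produces, and makes the first
        # mode a multiple of the constant (Cholesky is triangular)
        rp, rw = tetrahedron_rule(2 * degree)
        pts = map_to_cells(rp, v)
        wts = 6.0 * mesh.cell_volumes[:, None] * rw[None, :]
        raw = self._eval_raw(np.arange(mesh.num_cells), pts)
        Mloc = np.einsum("cq,cqa,cqb->cab", wts, raw, raw)
        L = np.linalg.cholesky(Mloc)
        self._transform = np.linalg.inv(L)      # basis = transform @ monomials
        self.L00 = L[:, 0, 0]                   # = sqrt(cell volume)

    # -- basis evaluation ----------------------------------------------------

    def _eval_raw(self, cells: np.ndarray, pts: np.ndarray) -> np.ndarray:
        xi = (pts - self.centers[cells][:, None, :]) / self.scales[cells][:, None, None]
        powx = xi[..., 0][..., None] ** self.exponents[:, 0]
        powy = xi[..., 1][..., None] ** self.exponents[:, 1]
        powz = xi[..., 2][..., None] ** self.exponents[:, 2]
        return powx * powy * powz

    def eval_basis(self, cells: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """(n, nq, nb) orthonormal-basis values at physical points (n, nq, 3)."""
        raw = self._eval_raw(cells, pts)
        return np.einsum("cab,cqb->cqa", self._transform[cells], raw)

    def eval_grad(self, cells: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """(n, nq, nb, 3) basis gradients at physical points."""
        xi = (pts - self.centers[cells][:, None, :]) / self.scales[cells][:, None, None]
        e = self.exponents
        out = np.empty(xi.shape[:2] + (self.nb, 3))
        for d in range(3):
            ed = e.copy()
            ed[:, d] = np.maximum(ed[:, d] - 1, 0)
            powx = xi[..., 0][..., None] ** ed[:, 0]
            powy = xi[..., 1][..., None] ** ed[:, 1]
            powz = xi[..., 2][..., None] ** ed[:, 2]
            out[..., d] = e[:, d] * powx * powy * powz
        out /= self.scales[cells][:, None, None, None]
        return np.einsum("cab,cqbd->cqad", self._transform[cells], out)

    def constant_field(self, value: float) -> np.ndarray:
        """Coefficients of the globally constant function ``value``."""
        c = np.zeros(self.ndof)
        c.reshape(-1, self.nb)[:, 0] = value * self.L00
        return c

    def eval_function(self, coeffs: np.ndarray, cells: np.ndarray, pts: np.ndarray):
        phi = self.eval_basis(cells, pts)
        return np.einsum("nqb,nb->nq", phi, coeffs.reshape(-1, self.nb)[cells])

    # -- elementary integrals ------------------------------------------------

    def _volume_quad(self, extra_degree: int = 0):
        rp, rw = tetrahedron_rule(2 * self.degree + extra_degree)
        pts = map_to_cells(rp, self.mesh.points[self.mesh.cells])
        wts = 6.0 * self.mesh.cell_volumes[:, None] * rw[None, :]
        return pts, wts

    def mass_matrix(self) -> sp.csr_matrix:
        pts, wts = self._volume_quad()
        cells = np.arange(self.mesh.num_cells)
        phi = self.eval_basis(cells, pts)
        blocks = np.einsum("cq,cqa,cqb->cab", wts, phi, phi)
        return self._block_diag(blocks)

    def integration_vector(self) -> np.ndarray:
        """w with w . c = int_Omega c dx."""
        pts, wts = self._volume_quad()
        cells = np.arange(self.mesh.num_cells)
        phi = self.eval_basis(cells, pts)
        return np.einsum("cq,cqb->cb", wts, phi).ravel()

    def project(self, f) -> np.ndarray:
        """L2 projection of a callable f(points (n,3)) -> (n,)."""
        pts, wts = self._volume_quad(extra_degree=2)
        cells = np.arange(self.mesh.num_cells)
        phi = self.eval_basis(cells, pts)
        rhs = np.einsum(
            "cq,cqb->cb", wts * np.asarray(f(pts.reshape(-1, 3))).reshape(pts.shape[:2]), phi
        )
        blocks = np.einsum("cq,cqa,cqb->cab", wts, phi, phi)
        return np.linalg.solve(blocks, rhs[..., None])[..., 0].ravel()

    def source_vector(self, f) -> np.ndarray:
        pts, wts = self._volume_quad(extra_degree=2)
        cells = np.arange(self.mesh.num_cells)
        phi = self.eval_basis(cells, pts)
        fv = np.asarray(f(pts.reshape(-1, 3))).reshape(pts.shape[:2])
        return np.einsum("cq,cq,cqb->cb", wts, fv, phi).ravel()

    def _block_diag(self, blocks: np.ndarray) -> sp.csr_matrix:
        nc, nb = self.mesh.num_cells, self.nb
        idx = nb * np.arange(nc)[:, None, None]
        rows = np.broadcast_to(idx + np.arange(nb)[None, :, None], blocks.shape)
        cols = np.broadcast_to(idx + np.arange(nb)[None, None, :], blocks.shape)
        return sp.coo_matrix(
            (blocks.ravel(), (rows.ravel(), cols.ravel())),
            shape=(self.ndof, self.ndof),
        ).tocsr()

    def cell_dof_slice(self, cells: np.ndarray) -> np.ndarray:
        return (self.nb * np.asarray(cells)[:, None] + np.arange(self.nb)).ravel()

    _SAMPLE_REF = np.array(
        [
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
            [0.5, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, 0.0, 0.5],
            [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5],
            [0.25, 0.25, 0.25],
        ]
    )  # vertices, edge midpoints, centroid: a cheap bound sample

    def minmax_over_cells(self, coeffs: np.ndarray) -> tuple[float, float]:
        """(min, max) of the represented function over a nodal sample."""
        cells = np.arange(self.mesh.num_cells)
        pts = map_to_cells(self._SAMPLE_REF, self.mesh.points[self.mesh.cells])
        vals = self.eval_function(coeffs, cells, pts)
        return float(vals.min()), float(vals.max())

    def max_over_cells(self, coeffs: np.ndarray) -> float:
        return self.minmax_over_cells(coeffs)[1]

    def min_over_cells(self, coeffs: np.ndarray) -> float:
        return self.minmax_over_cells(coeffs)[0]


@dataclass
class FacetTraces:
    """Precomputed basis traces at facet quadrature points.

    ``phi[side]``: (nfacets, nq, nb); ``dphin[side]``: normal derivatives;
    weights already include the physical facet measure.
    """

    facets: np.ndarray
    phi: list[np.ndarray]
    dphin: list[np.ndarray]
    weights: np.ndarray
    normals: np.ndarray
    diameters: np.ndarray
    points: np.ndarray


def facet_traces(space: DGSpace, facets: np.ndarray, sides: int) -> FacetTraces:
    mesh = space.mesh
    rp, rw = triangle_rule(2 * space.degree + 1)
    pts = map_to_facets(rp, mesh.points[mesh.facets[facets]])
    n = mesh.facet_normals[facets]
    phi, dphin = [], []
    for side in range(sides):
        cells = mesh.facet_cells[facets, side]
        phi.append(space.eval_basis(cells, pts))
        grad = space.eval_grad(cells, pts)
        dphin.append(np.einsum("fqbd,fd->fqb", grad, n))
    wts = 2.0 * mesh.facet_areas[facets][:, None] * rw[None, :]
    return FacetTraces(
        facets=facets,
        phi=phi,
        dphin=dphin,
        weights=wts,
        normals=n,
        diameters=mesh.facet_diameters[facets],
        points=pts,
    )


class SIPGDiffusion:
    """Sparse SIPG diffusion operator for unit diffusivity (scale by D)."""

    def __init__(self, space: DGSpace, alpha: float = 50.0,
                 dirichlet_facets: np.ndarray | None = None):
        self.space = space
        self.alpha = alpha
        mesh = space.mesh
        self.interior = np.nonzero(mesh.facet_cells[:, 1] >= 0)[0]
        self.dirichlet_facets = (
            np.asarray(dirichlet_facets, dtype=int)
            if dirichlet_facets is not None
            else np.empty(0, dtype=int)
        )
        self.matrix = self._assemble()

    def _assemble(self) -> sp.csr_matrix:
        space, mesh = self.space, self.space.mesh
        nb, nc = space.nb, mesh.num_cells
        pts, wts = space._volume_quad()
        cells = np.arange(nc)
        grad = space.eval_grad(cells, pts)
        vol_blocks = np.einsum("cq,cqad,cqbd->cab", wts, grad, grad)
        mat = space._block_diag(vol_blocks)

        k2 = float(space.degree ** 2)
        tr = facet_traces(space, self.interior, 2)
        sigma = self.alpha * k2 / tr.diameters
        entries, rows, cols = [], [], []
        cell_ids = mesh.facet_cells[self.interior]
        for i in range(2):
            si = 1.0 if i == 0 else -1.0
            for j in range(2):
                sj = 1.0 if j == 0 else -1.0
                block = (
                    -0.5 * si * np.einsum("fq,fqa,fqb->fab", tr.weights, tr.phi[i], tr.dphin[j])
                    - 0.5 * sj * np.einsum("fq,fqa,fqb->fab", tr.weights, tr.dphin[i], tr.phi[j])
                    + (sigma[:, None, None] * si * sj)
                    * np.einsum("fq,fqa,fqb->fab", tr.weights, tr.phi[i], tr.phi[j])
                )
                r = nb * cell_ids[:, i][:, None, None] + np.arange(nb)[None, :, None]
                c = nb * cell_ids[:, j][:, None, None] + np.arange(nb)[None, None, :]
                entries.append(block.ravel())
                rows.append(np.broadcast_to(r, block.shape).ravel())
                cols.append(np.broadcast_to(c, block.shape).ravel())
        if len(self.dirichlet_facets):
            tr = facet_traces(space, self.dirichlet_facets, 1)
            self._dir_traces = tr
            sigma = self.alpha * k2 / tr.diameters
            block = (
                -np.einsum("fq,fqa,fqb->fab", tr.weights, tr.phi[0], tr.dphin[0])
                - np.einsum("fq,fqa,fqb->fab", tr.weights, tr.dphin[0], tr.phi[0])
                + sigma[:, None, None]
                * np.einsum("fq,fqa,fqb->fab", tr.weights, tr.phi[0], tr.phi[0])
            )
            own = mesh.facet_cells[self.dirichlet_facets, 0]
            r = nb * own[:, None, None] + np.arange(nb)[None, :, None]
            c = nb * own[:, None, None] + np.arange(nb)[None, None, :]
            entries.append(block.ravel())
            rows.append(np.broadcast_to(r, block.shape).ravel())
            cols.append(np.broadcast_to(c, block.shape).ravel())
        mat = mat + sp.coo_matrix(
            (np.concatenate(entries), (np.concatenate(rows), np.concatenate(cols))),
            shape=(space.ndof, space.ndof),
        ).tocsr()
        return mat

    def dirichlet_rhs(self, g) -> np.ndarray:
        """RHS terms for weak Dirichlet data g(points)->(n,) (unit D)."""
        rhs = np.zeros(self.space.ndof)
        if not len(self.dirichlet_facets):
            return rhs
        tr = self._dir_traces
        gv = np.asarray(g(tr.points.reshape(-1, 3))).reshape(tr.points.shape[:2])
        sigma = self.alpha * float(self.space.degree ** 2) / tr.diameters
        loc = (
            -np.einsum("fq,fq,fqa->fa", tr.weights, gv, tr.dphin[0])
            + sigma[:, None] * np.einsum("fq,fq,fqa->fa", tr.weights, gv, tr.phi[0])
        )
        own = self.space.mesh.facet_cells[self.dirichlet_facets, 0]
        idx = self.space.nb * own[:, None] + np.arange(self.space.nb)
        np.add.at(rhs, idx.ravel(), loc.ravel())
        return rhs


class UpwindAdvection:
    """Matrix-free upwind advection for a velocity given as H(div) facet
    fluxes.  ``apply(fluxes, c)`` returns the action of the advection
    operator; boundary behaviour: zero-flux facets drop out exactly, and
    facets listed in ``open_facets`` get outflow upwinding (the inflow value
    is supplied separately through :meth:`inflow_vector`)."""

    def __init__(self, space: DGSpace, open_facets: np.ndarray | None = None):
        self.space = space
        mesh = space.mesh
        self.interior = np.nonzero(mesh.facet_cells[:, 1] >= 0)[0]
        self.open_facets = (
            np.asarray(open_facets, dtype=int)
            if open_facets is not None
            else np.empty(0, dtype=int)
        )
        self.tr = facet_traces(space, self.interior, 2)
        # P[i][j] = int_F phi_a^i phi_b^j ds / |F| (normalized by area so a
        # facet-constant normal velocity multiplies back in)
        # P[i][j]_{ab} = int_F phi_a^i phi_b^j ds; the (facet-constant) normal
        # velocity u.n = q_F / |F| multiplies these blocks directly
        self.P = [
            [
                np.einsum("fq,fqa,fqb->fab", self.tr.weights, self.tr.phi[i], self.tr.phi[j])
                for j in range(2)
            ]
            for i in range(2)
        ]
        self.cell_ids = mesh.facet_cells[self.interior]
        if len(self.open_facets):
            self.btr = facet_traces(space, self.open_facets, 1)
            self.Pb = np.einsum(
                "fq,fqa,fqb->fab", self.btr.weights, self.btr.phi[0], self.btr.phi[0]
            )
            self.b_int_phi = np.einsum("fq,fqa->fa", self.btr.weights, self.btr.phi[0])
            self.b_areas = mesh.facet_areas[self.open_facets]
            self.b_own = mesh.facet_cells[self.open_facets, 0]

    def cell_blocks(self, velocity_at) -> np.ndarray:
        """Volume term -int_K c u . grad v for a callable velocity evaluator
        ``velocity_at(cells, pts) -> (nc, nq, 3)``; returns (nc, nb, nb)."""
        space = self.space
        pts, wts = space._volume_quad(extra_degree=1)
        cells = np.arange(space.mesh.num_cells)
        grad = space.eval_grad(cells, pts)
        phi = space.eval_basis(cells, pts)
        u = velocity_at(cells, pts)
        return -np.einsum("cq,cqd,cqad,cqb->cab", wts, u, grad, phi)

    def rt0_cell_tensor(self) -> np.ndarray:
        """Precomputed tensor G with G[c, i, a, b] = -int_K (x - p_i) .
        grad(phi_a) phi_b dx, where p_i is the vertex opposite local facet i.
        The volume advection block of an H(div) flux field q is then the
        flux-linear contraction sum_i sigma_i q_i / (3 |K|) G[c, i]."""
        space = self.space
        mesh = space.mesh
        pts, wts = space._volume_quad(extra_degree=1)
        cells = np.arange(mesh.num_cells)
        grad = space.eval_grad(cells, pts)
        phi = space.eval_basis(cells, pts)
        verts = mesh.points[mesh.cells]                       # (nc, 4, 3)
        diff = pts[:, :, None, :] - verts[:, None, :, :]      # (nc, nq, 4, 3)
        return -np.einsum("cq,cqix,cqax,cqb->ciab", wts, diff, grad, phi)

    def cell_blocks_from_fluxes(self, tensor: np.ndarray, fluxes: np.ndarray) -> np.ndarray:
        mesh = self.space.mesh
        cf = mesh.cell_facets
        sign = np.where(
            mesh.facet_cells[cf][:, :, 0] == np.arange(mesh.num_cells)[:, None],
            1.0,
            -1.0,
        )
        coef = sign * fluxes[cf] / (3.0 * mesh.cell_volumes)[:, None]
        return np.einsum("ci,ciab->cab", coef, tensor)

    def normal_velocities(self, fluxes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Facet-mean normal velocity on interior and open boundary facets."""
        mesh = self.space.mesh
        un_int = fluxes[self.interior] / mesh.facet_areas[self.interior]
        un_open = (
            fluxes[self.open_facets] / mesh.facet_areas[self.open_facets]
            if len(self.open_facets)
            else np.empty(0)
        )
        return un_int, un_open

    def apply_facets(self, un_int, un_open, c: np.ndarray) -> np.ndarray:
        """Facet (upwind flux) part of A c."""
        space = self.space
        nb = space.nb
        cm = c.reshape(-1, nb)
        y = np.zeros_like(cm)
        up = (un_int >= 0.0).astype(int)      # upwind side: 0 if flow 0->1
        s = 1 - up                            # index of upwind cell column
        c_up = cm[self.cell_ids[np.arange(len(s)), s]]
        # pick trace products against the upwind side
        P0s = np.where(s[:, None, None] == 0, self.P[0][0], self.P[0][1])
        P1s = np.where(s[:, None, None] == 0, self.P[1][0], self.P[1][1])
        flux0 = un_int[:, None] * np.einsum("fab,fb->fa", P0s, c_up)
        flux1 = un_int[:, None] * np.einsum("fab,fb->fa", P1s, c_up)
        np.add.at(y, self.cell_ids[:, 0], flux0)
        np.add.at(y, self.cell_ids[:, 1], -flux1)
        if len(self.open_facets):
            out = un_open > 0.0
            if out.any():
                fluxb = un_open[out, None] * np.einsum(
                    "fab,fb->fa", self.Pb[out], cm[self.b_own[out]]
                )
                np.add.at(y, self.b_own[out], fluxb)
        return y.ravel()

    def inflow_vector(self, un_open: np.ndarray, c_in: float) -> np.ndarray:
        """RHS contribution -int_{inflow} c_in (u.n) v of the open boundary."""
        rhs = np.zeros(self.space.ndof)
        if not len(self.open_facets) or c_in == 0.0:
            return rhs
        infl = un_open < 0.0
        if not infl.any():
            return rhs
        loc = -c_in * un_open[infl, None] * self.b_int_phi[infl]
        idx = self.space.nb * self.b_own[infl][:, None] + np.arange(self.space.nb)
        np.add.at(rhs, idx.ravel(), loc.ravel())
        return rhs

    def matrix_from_fluxes(self, fluxes: np.ndarray, tensor: np.ndarray | None = None) -> sp.csr_matrix:
        """Sparse upwind advection operator for an H(div) flux field (same
        action as the matrix-free path; used to build preconditioners)."""
        space = self.space
        mesh = space.mesh
        nb = space.nb
        if tensor is None:
            tensor = self.rt0_cell_tensor()
        mat = space._block_diag(self.cell_blocks_from_fluxes(tensor, fluxes))

        un_int, un_open = self.normal_velocities(fluxes)
        up = (un_int >= 0.0).astype(int)
        s = 1 - up  # upwind side index (0 when flow crosses 0 -> 1)
        entries, rows, cols = [], [], []
        for i in range(2):
            sign = 1.0 if i == 0 else -1.0
            Ps = np.where(s[:, None, None] == 0, self.P[i][0], self.P[i][1])
            block = sign * un_int[:, None, None] * Ps
            trial_cells = self.cell_ids[np.arange(len(s)), s]
            r = nb * self.cell_ids[:, i][:, None, None] + np.arange(nb)[None, :, None]
            c = nb * trial_cells[:, None, None] + np.arange(nb)[None, None, :]
            entries.append(block.ravel())
            rows.append(np.broadcast_to(r, block.shape).ravel())
            cols.append(np.broadcast_to(c, block.shape).ravel())
        if len(self.open_facets):
            out = un_open > 0.0
            if out.any():
                block = un_open[out, None, None] * self.Pb[out]
                own = self.b_own[out]
                r = nb * own[:, None, None] + np.arange(nb)[None, :, None]
                c = nb * own[:, None, None] + np.arange(nb)[None, None, :]
                entries.append(block.ravel())
                rows.append(np.broadcast_to(r, block.shape).ravel())
                cols.append(np.broadcast_to(c, block.shape).ravel())
        return mat + sp.coo_matrix(
            (np.concatenate(entries), (np.concatenate(rows), np.concatenate(cols))),
            shape=(space.ndof, space.ndof),
        ).tocsr()

    def matrix_from_callable(
        self, u_fn, dirichlet_facets: np.ndarray | None = None
    ) -> sp.csr_matrix:
        """Sparse upwind advection operator for an analytic velocity
        ``u_fn(points (n,3)) -> (n,3)`` with pointwise upwinding (used by the
        manufactured-solution studies; physical runs use the matrix-free
        H(div) path)."""
        space = self.space
        mesh = space.mesh
        nb = space.nb
        cells = np.arange(mesh.num_cells)
        pts, wts = space._volume_quad(extra_degree=2)
        grad = space.eval_grad(cells, pts)
        phi = space.eval_basis(cells, pts)
        u = np.asarray(u_fn(pts.reshape(-1, 3))).reshape(pts.shape)
        vol_blocks = -np.einsum("cq,cqd,cqad,cqb->cab", wts, u, grad, phi)
        mat = space._block_diag(vol_blocks)

        tr = self.tr
        un = np.einsum(
            "fqd,fd->fq",
            np.asarray(u_fn(tr.points.reshape(-1, 3))).reshape(tr.points.shape),
            tr.normals,
        )
        un_pos, un_neg = np.maximum(un, 0.0), np.minimum(un, 0.0)
        entries, rows, cols = [], [], []
        for i in range(2):
            s_i = 1.0 if i == 0 else -1.0
            for j, unpart in ((0, un_pos), (1, un_neg)):
                block = s_i * np.einsum(
                    "fq,fq,fqa,fqb->fab", tr.weights, unpart, tr.phi[i], tr.phi[j]
                )
                r = nb * self.cell_ids[:, i][:, None, None] + np.arange(nb)[None, :, None]
                c = nb * self.cell_ids[:, j][:, None, None] + np.arange(nb)[None, None, :]
                entries.append(block.ravel())
                rows.append(np.broadcast_to(r, block.shape).ravel())
                cols.append(np.broadcast_to(c, block.shape).ravel())
        if dirichlet_facets is not None and len(dirichlet_facets):
            btr = facet_traces(space, np.asarray(dirichlet_facets, int), 1)
            self._mms_btr = btr
            un_b = np.einsum(
                "fqd,fd->fq",
                np.asarray(u_fn(btr.points.reshape(-1, 3))).reshape(btr.points.shape),
                btr.normals,
            )
            self._mms_un_b = un_b
            block = np.einsum(
                "fq,fq,fqa,fqb->fab", btr.weights, np.maximum(un_b, 0.0),
                btr.phi[0], btr.phi[0],
            )
            own = mesh.facet_cells[np.asarray(dirichlet_facets, int), 0]
            r = nb * own[:, None, None] + np.arange(nb)[None, :, None]
            c = nb * own[:, None, None] + np.arange(nb)[None, None, :]
            entries.append(block.ravel())
            rows.append(np.broadcast_to(r, block.shape).ravel())
            cols.append(np.broadcast_to(c, block.shape).ravel())
        return mat + sp.coo_matrix(
            (np.concatenate(entries), (np.concatenate(rows), np.concatenate(cols))),
            shape=(space.ndof, space.ndof),
        ).tocsr()

    def dirichlet_inflow_rhs(self, g) -> np.ndarray:
        """RHS term -int_{u.n<0} g (u.n) v ds for the analytic-velocity path
        (call after :meth:`matrix_from_callable` with Dirichlet facets)."""
        rhs = np.zeros(self.space.ndof)
        btr = self._mms_btr
        gv = np.asarray(g(btr.points.reshape(-1, 3))).reshape(btr.points.shape[:2])
        loc = -np.einsum(
            "fq,fq,fq,fqa->fa", btr.weights, np.minimum(self._mms_un_b, 0.0), gv, btr.phi[0]
        )
        own = self.space.mesh.facet_cells[btr.facets, 0]
        idx = self.space.nb * own[:, None] + np.arange(self.space.nb)
        np.add.at(rhs, idx.ravel(), loc.ravel())
        return rhs

    def boundary_rates(self, un_open: np.ndarray, c: np.ndarray) -> tuple[float, float]:
        """(outflow rate, inflow volumetric rate): int c u.n over outflow
        facets, and -int u.n over inflow facets (amount / time, m^3/s)."""
        if not len(self.open_facets):
            return 0.0, 0.0
        cm = c.reshape(-1, self.space.nb)
        out = un_open > 0.0
        rate = 0.0
        if out.any():
            rate = float(
                np.einsum(
                    "f,fa,fa->",
                    un_open[out],
                    self.b_int_phi[out],
                    cm[self.b_own[out]],
                )
            )
        infl = un_open < 0.0
        vin = float(-(un_open[infl] * self.b_areas[infl]).sum()) if infl.any() else 0.0
        return rate, vin
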