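"""Incompressible Stokes flow driven by cilia traction and cardiac pressure.

The CSF in the embryonic ventricles is modeled as a Newtonian fluid at
vanishing Reynolds number: find velocity u and pressure p with

    rho du/dt - div( 2 mu eps(u) - p I ) = 0,    div u = 0,

subject to (i) tangential traction on the ciliated wall patches
(u.n = 0 strongly, sigma_parallel = tau weakly), (ii) free slip on the
remaining walls, and (iii) a normal pressure on the anterior/posterior end
caps (p_tilde = 0 anteriorly, -A sin(omega t) posteriorly).

Discretization: facet-based nonconforming P1 vector elements
(Crouzeix-Raviart) for the velocity and cellwise-constant pressure, with the
tangential inter-element jump penalized (dimensionless penalty gamma).  The
velocity degrees of freedom are facet(-mean) values, so impermeability is
imposed strongly by rotating wall DOFs into a normal/tangential frame and
eliminating the normal component, and the cellwise divergence vanishes to
solver precision.  A lowest-order Raviart-Thomas flux reconstruction (exact,
from the single-valued facet normal fluxes) provides the pointwise
H(div)-conforming velocity consumed by the transport solver.  Time stepping
is implicit Euler; one cardiac cycle is stored after a configurable number of
startup cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import (
    CILIA_LABELS,
    FacetLabel,
    LabeledMesh,
    PRESSURE_LABELS,
)
from .quadrature import map_to_cells, map_to_facets, tetrahedron_rule, triangle_rule

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """CSF density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1000.0
    viscosity: float = 0.7e-3

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class CiliaRegion:
    direction: tuple[float, float, float]     # r, projected tangentially per facet
    weight: object | None = None              # lambda(x) >= 0; None means 1


def _default_regions() -> dict[int, CiliaRegion]:
    # dorsal-middle cilia drive rostrocaudally (+x) along the dorsal wall;
    # ventral-middle and anterior cilia drive the return flow
    return {
        int(FacetLabel.CILIA_DORSAL_MID): CiliaRegion((1.0, 0.0, 1.0)),
        int(FacetLabel.CILIA_VENTRAL_MID): CiliaRegion((-1.0, 0.0, -1.0)),
        int(FacetLabel.CILIA_ANTERIOR): CiliaRegion((-1.0, 0.0, -1.0)),
    }


@dataclass
class CiliaTractionSpec:
    """Steady tangential traction tau * lambda(x) * P_n(r) on cilia patches."""

    amplitude: float = 0.65e-3  # Pa
    regions: dict[int, CiliaRegion] = dc_field(default_factory=_default_regions)
    active: frozenset[int] = dc_field(
        default_factory=lambda: frozenset(int(l) for l in CILIA_LABELS)
    )

    def paralyze(self, labels) -> "CiliaTractionSpec":
        off = {int(l) for l in labels}
        return CiliaTractionSpec(
            amplitude=self.amplitude,
            regions=dict(self.regions),
            active=frozenset(self.active - off),
        )


@dataclass(frozen=True)
class CardiacForcing:
    """Sinusoidal normal pressure on the posterior cap; anterior cap at 0."""

    amplitude: float = 1.5e-3  # Pa
    frequency: float = 2.22    # Hz

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    def anterior_pressure(self, t: float) -> float:
        return 0.0

    def posterior_pressure(self, t: float, omega: float | None = None) -> float:
        w = self.omega if omega is None else omega
        return -self.amplitude * np.sin(w * t)


@dataclass(frozen=True)
class StokesDiscretization:
    dt: float = 0.023
    steps_per_cycle: int = 20
    gamma: float = 10.0          # tangential-jump penalty (dimensionless)
    startup_cycles: int = 3
    cycle_tolerance: float = 1e-6

    def __post_init__(self):
        if self.gamma <= 0 or self.dt <= 0 or self.steps_per_cycle < 1:
            raise ValueError("invalid Stokes discretization parameters")

    def check_period(self, cardiac: CardiacForcing) -> None:
        period = self.dt * self.steps_per_cycle
        if abs(period * cardiac.frequency - 1.0) > 0.05:
            raise ValueError(
                f"dt * steps_per_cycle = {period:.4g} s is inconsistent with the "
                f"cardiac period 1/f = {1 / cardiac.frequency:.4g} s"
            )

    def effective_omega(self) -> float:
        """Angular frequency making the forcing exactly periodic over the
        discrete cycle (the printed dt=0.023 s x 20 steps and f=2.22 Hz agree
        only to ~2%; the discrete cycle length wins internally)."""
        return 2.0 * np.pi / (self.dt * self.steps_per_cycle)


@dataclass(frozen=True)
class FlowScenario:
    selector: str = "baseline"  # baseline | cilia_only | cardiac_only | paralysis
    paralyzed: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.selector not in {"baseline", "cilia_only", "cardiac_only", "paralysis"}:
            raise ValueError(f"unknown flow scenario {self.selector!r}")

    def resolve(
        self, cilia: CiliaTractionSpec, cardiac: CardiacForcing | None
    ) -> tuple[CiliaTractionSpec, CardiacForcing | None]:
        if self.selector == "cilia_only":
            return cilia, None
        if self.selector == "cardiac_only":
            return cilia.paralyze(cilia.active), cardiac
        if self.selector == "paralysis":
            return cilia.paralyze(self.paralyzed), cardiac
        return cilia, cardiac


@dataclass
class FlowField:
    """Velocity/pressure snapshots: one for steady flow, one cardiac cycle
    (phase-indexed) for pulsatile scenarios.

    ``velocity`` holds facet-midpoint values (nfacets, 3) in m/s; ``pressure``
    cellwise constants in Pa; ``facet_fluxes`` the single-valued normal fluxes
    int_F u.n dS (m^3/s) orienting each facet by the mesh's global normal.
    """

    mesh: LabeledMesh
    velocity: list[np.ndarray]
    pressure: list[np.ndarray]
    facet_fluxes: list[np.ndarray]
    phase_times: np.ndarray
    steady: bool = False

    @property
    def num_snapshots(self) -> int:
        return len(self.velocity)

    def snapshot_velocity(self, phase: int) -> np.ndarray:
        return self.velocity[phase % self.num_snapshots]

    def snapshot_fluxes(self, phase: int) -> np.ndarray:
        return self.facet_fluxes[phase % self.num_snapshots]


def tangential_projection(r, n):
    """(I - n x n) r for a unit normal n."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-10:
        raise ValueError("normal vector must have unit length")
    return r - np.dot(r, n) * n


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class _SaddleFactor:
    """Sparse LU of the saddle matrix, kept together with the matrix so the
    solve can run a couple of iterative-refinement sweeps."""

    def __init__(self, matrix: sp.csc_matrix):
        self.matrix = matrix
        self.lu = spla.splu(matrix)

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self.lu.solve(b)


class StokesSystem:
    """Assembled Crouzeix-Raviart / P0 Stokes operator on a labeled mesh.

    ``dirichlet`` optionally maps boundary facet indices to prescribed
    velocity values (used by the manufactured-solution verification); facets
    labeled as walls or cilia otherwise get the strong impermeability
    constraint, and pressure-cap facets remain fully natural.
    """

    def __init__(
        self,
        mesh: LabeledMesh,
        props: FluidProperties,
        disc: StokesDiscretization,
        dirichlet: dict[int, np.ndarray] | None = None,
        closed_caps: bool = False,
    ):
        self.mesh = mesh
        self.props = props
        self.disc = disc
        self.nf = len(mesh.facets)
        self.nc = mesh.num_cells
        self.nu = 3 * self.nf

        labels = mesh.facet_label_array
        self.cap_facets = np.nonzero(np.isin(labels, [int(l) for l in PRESSURE_LABELS]))[0]
        if closed_caps:
            # the cilia-only scenario has no pressure boundary: the caps
            # revert to free-slip walls and the domain is closed
            self.cap_facets = np.empty(0, dtype=int)
        self.dirichlet = dict(dirichlet or {})
        wall_mask = np.zeros(self.nf, dtype=bool)
        wall_mask[mesh.boundary_facets] = True
        wall_mask[self.cap_facets] = False
        for f in self.dirichlet:
            wall_mask[f] = False
        self.wall_facets = np.nonzero(wall_mask)[0]
        # pressure is only fixed through a natural boundary condition
        self.needs_gauge = len(self.cap_facets) == 0

        self._build_rotation()
        self._assemble()

    # -- geometry-frame handling --------------------------------------------

    def _build_rotation(self):
        mesh = self.mesh
        n = mesh.facet_normals
        t1 = np.cross(n, np.array([1.0, 0.0, 0.0]))
        small = np.linalg.norm(t1, axis=1) < 1e-6
        t1[small] = np.cross(n[small], np.array([0.0, 1.0, 0.0]))
        t1 /= np.linalg.norm(t1, axis=1)[:, None]
        t2 = np.cross(n, t1)
        # columns of each 3x3 block map (t1, t2, n) coefficients to xyz
        blocks = np.stack([t1, t2, n], axis=2)  # (nf, 3, 3)
        eye = np.broadcast_to(np.eye(3), (self.nf, 3, 3)).copy()
        rotated = np.zeros(self.nf, dtype=bool)
        rotated[self.wall_facets] = True
        T = np.where(rotated[:, None, None], blocks, eye)
        rows = (3 * np.arange(self.nf)[:, None, None] + np.arange(3)[:, None]).repeat(3, axis=2)
        cols = (3 * np.arange(self.nf)[:, None, None] + np.arange(3)[None, None, :]).repeat(3, axis=1)
        self.T = sp.csr_matrix(
            (T.ravel(), (rows.ravel(), cols.ravel())), shape=(self.nu, self.nu)
        )
        fixed = [3 * f + 2 for f in self.wall_facets]  # normal components
        fixed_vals = [0.0] * len(fixed)
        for f, g in self.dirichlet.items():
            fixed += [3 * f, 3 * f + 1, 3 * f + 2]
            fixed_vals += list(np.asarray(g, dtype=float))
        self.fixed_idx = np.asarray(fixed, dtype=int)
        self.fixed_vals = np.asarray(fixed_vals, dtype=float)
        mask = np.ones(self.nu, dtype=bool)
        mask[self.fixed_idx] = False
        self.free_idx = np.nonzero(mask)[0]

    # -- matrices ------------------------------------------------------------

    def _assemble(self):
        mesh, mu = self.mesh, self.props.viscosity
        V = mesh.cell_volumes
        g = -3.0 * mesh.barycentric_gradients  # CR gradients, (nc, 4, 3)
        cf = mesh.cell_facets

        gg = np.einsum("cix,cjx->cij", g, g)
        eye = np.eye(3)
        # K[c, i, d, j, e] = mu |K| (delta_de g_i.g_j + g_j[d] g_i[e])
        K = mu * V[:, None, None, None, None] * (
            np.einsum("de,cij->cidje", eye, gg)
            + np.einsum("cjd,cie->cidje", g, g)
        )
        rows = (3 * cf[:, :, None, None, None] + np.arange(3)[None, None, :, None, None])
        rows = np.broadcast_to(rows, K.shape)
        cols = (3 * cf[:, None, None, :, None] + np.arange(3)[None, None, None, None, :])
        cols = np.broadcast_to(cols, K.shape)
        A = sp.coo_matrix(
            (K.ravel(), (rows.ravel(), cols.ravel())), shape=(self.nu, self.nu)
        ).tocsr()
        A = A + self._jump_penalty()
        self.A = A

        Bv = -V[:, None, None] * g  # (nc, 4, 3)
        rows = 3 * cf[:, :, None] + np.arange(3)[None, None, :]
        cols = np.broadcast_to(np.arange(self.nc)[:, None, None], Bv.shape)
        self.B = sp.coo_matrix(
            (Bv.ravel(), (rows.ravel(), cols.ravel())), shape=(self.nu, self.nc)
        ).tocsr()

        mloc = (-np.ones((4, 4)) + 9.0 * np.eye(4)) / 20.0
        Mv = self.props.density * V[:, None, None] * mloc[None, :, :]
        rows = np.broadcast_to(3 * cf[:, :, None], (self.nc, 4, 4))
        cols = np.broadcast_to(3 * cf[:, None, :], (self.nc, 4, 4))
        M1 = sp.coo_matrix(
            (Mv.ravel(), (rows.ravel(), cols.ravel())), shape=(self.nu, self.nu)
        ).tocsr()
        self.M = (
            M1
            + sp.coo_matrix(
                (Mv.ravel(), ((rows + 1).ravel(), (cols + 1).ravel())),
                shape=(self.nu, self.nu),
            ).tocsr()
            + sp.coo_matrix(
                (Mv.ravel(), ((rows + 2).ravel(), (cols + 2).ravel())),
                shape=(self.nu, self.nu),
            ).tocsr()
        )

        self._rotate_all()

    def _cr_traces(self, facets: np.ndarray, side: int, pts: np.ndarray) -> np.ndarray:
        """CR basis traces of the side-th adjacent cell at physical points
        pts (nfacets, nq, 3); returns (nfacets, nq, 4)."""
        mesh = self.mesh
        cells = mesh.facet_cells[facets, side]
        grads = mesh.barycentric_gradients[cells]            # (nf, 4, 3)
        verts = mesh.points[mesh.cells[cells]]               # (nf, 4, 3)
        lam = 1.0 + np.einsum(
            "fix,fqix->fqi", grads, pts[:, :, None, :] - verts[:, None, :, :]
        )
        return 1.0 - 3.0 * lam

    def _jump_penalty(self) -> sp.csr_matrix:
        mesh, mu, gamma = self.mesh, self.props.viscosity, self.disc.gamma
        interior = np.nonzero(mesh.facet_cells[:, 1] >= 0)[0]
        if len(interior) == 0:
            return sp.csr_matrix((self.nu, self.nu))
        ref_pts, ref_w = triangle_rule(2)
        mats = []
        for chunk in np.array_split(interior, max(1, len(interior) // 8000)):
            pts = map_to_facets(ref_pts, mesh.points[mesh.facets[chunk]])
            phi0 = self._cr_traces(chunk, 0, pts)
            phi1 = self._cr_traces(chunk, 1, pts)
            phi = np.concatenate([phi0, -phi1], axis=2)       # jump, (nf, nq, 8)
            area = mesh.facet_areas[chunk]
            h = mesh.facet_diameters[chunk]
            coef = gamma * mu / h * 2.0 * area                # rule weights sum to 1/2
            S = coef[:, None, None] * np.einsum("q,fqa,fqb->fab", ref_w, phi, phi)
            # the full jump is penalized: the facet-mean normal jump already
            # vanishes for this element, but pointwise normal jumps (rotation
            # hinge modes) would otherwise evade Korn's inequality
            P = np.broadcast_to(np.eye(3), (len(chunk), 3, 3))
            block = np.einsum("fab,fde->fadbe", S, P)         # (nf, 8, 3, 8, 3)
            dofmap = np.concatenate(
                [mesh.cell_facets[mesh.facet_cells[chunk, 0]],
                 mesh.cell_facets[mesh.facet_cells[chunk, 1]]], axis=1
            )                                                  # (nf, 8)
            rows = 3 * dofmap[:, :, None, None, None] + np.arange(3)[None, None, :, None, None]
            cols = 3 * dofmap[:, None, None, :, None] + np.arange(3)[None, None, None, None, :]
            rows = np.broadcast_to(rows, block.shape)
            cols = np.broadcast_to(cols, block.shape)
            mats.append(
                sp.coo_matrix(
                    (block.ravel(), (rows.ravel(), cols.ravel())),
                    shape=(self.nu, self.nu),
                ).tocsr()
            )
        out = mats[0]
        for m in mats[1:]:
            out = out + m
        return out

    def _rotate_all(self):
        T = self.T
        self.A_r = (T.T @ self.A @ T).tocsr()
        self.M_r = (T.T @ self.M @ T).tocsr()
        self.B_r = (T.T @ self.B).tocsr()

    # -- right-hand sides ----------------------------------------------------

    def traction_rhs(self, cilia: CiliaTractionSpec) -> np.ndarray:
        """Weak cilia forcing int_Gc tau . v ds."""
        mesh = self.mesh
        rhs = np.zeros(self.nu)
        ref_pts, ref_w = triangle_rule(3)
        for label in sorted(cilia.active):
            region = cilia.regions.get(int(label))
            if region is None:
                continue
            facets = mesh.facets_with_label(label)
            if len(facets) == 0:
                continue
            pts = map_to_facets(ref_pts, mesh.points[mesh.facets[facets]])
            n = mesh.facet_normals[facets]
            r = np.asarray(region.direction, dtype=float)
            tang = r[None, :] - np.einsum("fd,d->f", n, r)[:, None] * n
            w = (
                region.weight(pts.reshape(-1, 3)).reshape(pts.shape[:2])
                if region.weight is not None
                else np.ones(pts.shape[:2])
            )
            phi = self._cr_traces(facets, 0, pts)              # (nf, nq, 4)
            coef = 2.0 * mesh.facet_areas[facets]
            loc = cilia.amplitude * coef[:, None, None] * np.einsum(
                "q,fq,fqj,fd->fjd", ref_w, w, phi, tang
            )
            dof = 3 * mesh.cell_facets[mesh.facet_cells[facets, 0]]
            np.add.at(rhs, (dof[:, :, None] + np.arange(3)[None, None, :]).ravel(), loc.ravel())
        return rhs

    def pressure_rhs(self, p_ant: float, p_post: float) -> np.ndarray:
        """Weak normal-pressure forcing int_Gp p_tilde n . v ds."""
        mesh = self.mesh
        rhs = np.zeros(self.nu)
        ref_pts, ref_w = triangle_rule(2)
        for label, val in (
            (FacetLabel.PRESSURE_ANTERIOR, p_ant),
            (FacetLabel.PRESSURE_POSTERIOR, p_post),
        ):
            if val == 0.0:
                continue
            facets = mesh.facets_with_label(label)
            if len(facets) == 0:
                continue
            pts = map_to_facets(ref_pts, mesh.points[mesh.facets[facets]])
            phi = self._cr_traces(facets, 0, pts)
            n = mesh.facet_normals[facets]
            coef = 2.0 * mesh.facet_areas[facets] * val
            loc = coef[:, None, None] * np.einsum("q,fqj,fd->fjd", ref_w, phi, n)
            dof = 3 * mesh.cell_facets[mesh.facet_cells[facets, 0]]
            np.add.at(rhs, (dof[:, :, None] + np.arange(3)[None, None, :]).ravel(), loc.ravel())
        return rhs

    def body_force_rhs(self, f) -> np.ndarray:
        """int_Omega f . v dx for a callable f(points)->(n,3) (verification)."""
        mesh = self.mesh
        ref_pts, ref_w = tetrahedron_rule(4)
        pts = map_to_cells(ref_pts, mesh.points[mesh.cells])   # (nc, nq, 3)
        fv = np.asarray(f(pts.reshape(-1, 3))).reshape(pts.shape)
        grads = mesh.barycentric_gradients
        verts = mesh.points[mesh.cells]
        lam = 1.0 + np.einsum(
            "cix,cqix->cqi", grads, pts[:, :, None, :] - verts[:, None, :, :]
        )
        phi = 1.0 - 3.0 * lam                                   # (nc, nq, 4)
        loc = 6.0 * mesh.cell_volumes[:, None, None] * np.einsum(
            "q,cqj,cqd->cjd", ref_w, phi, fv
        )
        rhs = np.zeros(self.nu)
        dof = 3 * mesh.cell_facets
        np.add.at(rhs, (dof[:, :, None] + np.arange(3)[None, None, :]).ravel(), loc.ravel())
        return rhs

    # -- solvers -------------------------------------------------------------

    def _saddle(self, Auu: sp.csr_matrix):
        free = self.free_idx
        Aff = Auu[free][:, free]
        Bf = self.B_r[free]
        Bt = Bf.T.tocsr()
        C = None
        if self.needs_gauge:
            # sparsity-preserving gauge: replace the first continuity row by
            # p_0 = 0 (that row is implied by the others plus compatibility);
            # the returned pressure is shifted to zero volume-mean afterwards
            keep = np.ones(self.nc)
            keep[0] = 0.0
            Bt = sp.diags(keep) @ Bt
            C = sp.coo_matrix(([1.0], ([0], [0])), shape=(self.nc, self.nc)).tocsr()
        blocks = [[Aff, Bf], [Bt, C]]
        return sp.bmat(blocks, format="csc")

    def _solve(self, lu, Auu, rhs_u, rhs_p=None):
        free = self.free_idx
        b_u = rhs_u[free] - Auu[free][:, self.fixed_idx] @ self.fixed_vals
        b_p = -(self.B_r[self.fixed_idx].T @ self.fixed_vals)
        if rhs_p is not None:
            b_p = b_p + rhs_p
        if self.needs_gauge:
            b_p[0] = 0.0
        b = np.concatenate([b_u, b_p])
        x = lu.solve(b)
        for _ in range(2):  # iterative refinement: keeps the cellwise
            r = b - lu.matrix @ x          # divergence at machine level
            if np.linalg.norm(r) <= 1e-14 * np.linalg.norm(b):
                break
            x = x + lu.lu.solve(r)
        w = np.zeros(self.nu)
        w[free] = x[: len(free)]
        w[self.fixed_idx] = self.fixed_vals
        u = (self.T @ w).reshape(self.nf, 3)
        p = x[len(free): len(free) + self.nc]
        if self.needs_gauge:
            p = p - np.average(p, weights=self.mesh.cell_volumes)
        return u, p

    def factor(self, Auu: sp.csr_matrix):
        return _SaddleFactor(self._saddle(Auu))

    # -- post-processing -----------------------------------------------------

    def facet_fluxes(self, u: np.ndarray) -> np.ndarray:
        """Single-valued normal fluxes int_F u.n dS (exact for facetwise-linear
        velocity; the facet midpoint value is the facet mean)."""
        return self.mesh.facet_areas * np.einsum(
            "fd,fd->f", u, self.mesh.facet_normals
        )


def _make_field(system: StokesSystem, snaps, times, steady) -> FlowField:
    return FlowField(
        mesh=system.mesh,
        velocity=[u for u, _ in snaps],
        pressure=[p for _, p in snaps],
        facet_fluxes=[system.facet_fluxes(u) for u, _ in snaps],
        phase_times=np.asarray(times),
        steady=steady,
    )


def solve_steady_stokes(
    mesh: LabeledMesh,
    props: FluidProperties = FluidProperties(),
    cilia: CiliaTractionSpec | None = None,
    disc: StokesDiscretization = StokesDiscretization(),
    mms_source=None,
    dirichlet: dict[int, np.ndarray] | None = None,
    system: StokesSystem | None = None,
    closed_caps: bool = False,
) -> FlowField:
    """Steady Stokes flow (the cilia-driven/no-cardiac scenario, or a
    manufactured problem when ``mms_source``/``dirichlet`` are given)."""
    if system is None:
        system = StokesSystem(
            mesh, props, disc, dirichlet=dirichlet, closed_caps=closed_caps
        )
    rhs = np.zeros(system.nu)
    if cilia is not None:
        rhs += system.traction_rhs(cilia)
    if mms_source is not None:
        rhs += system.body_force_rhs(mms_source)
    if system.needs_gauge:
        logger.info("pressure gauge fixed by zero-mean constraint (no pressure caps)")
    lu = system.factor(system.A_r)
    u, p = system._solve(lu, system.A_r, system.T.T @ rhs)
    return _make_field(system, [(u, p)], [0.0], steady=True)


def solve_transient_cycle(
    mesh: LabeledMesh,
    props: FluidProperties = FluidProperties(),
    cilia: CiliaTractionSpec | None = None,
    cardiac: CardiacForcing | None = CardiacForcing(),
    disc: StokesDiscretization = StokesDiscretization(),
    scenario: FlowScenario = FlowScenario("baseline"),
    system: StokesSystem | None = None,
) -> FlowField:
    """Implicit-Euler time stepping from rest; returns the velocity/pressure
    snapshots of one cardiac cycle stored after the startup cycles, checking
    that consecutive cycles have converged to a periodic state."""
    cilia = cilia if cilia is not None else CiliaTractionSpec()
    cilia, cardiac = scenario.resolve(cilia, cardiac)
    if scenario.selector == "cilia_only" or cardiac is None:
        return solve_steady_stokes(
            mesh, props, cilia=cilia, disc=disc, system=system,
            closed_caps=(scenario.selector == "cilia_only"),
        )
    disc.check_period(cardiac)
    omega = disc.effective_omega()

    if system is None:
        system = StokesSystem(mesh, props, disc)
    dt = disc.dt
    Auu = system.M_r / dt + system.A_r
    lu = system.factor(Auu)
    rhs_cilia = system.T.T @ system.traction_rhs(cilia)

    u = np.zeros((system.nf, 3))
    prev_cycle: list[np.ndarray] | None = None
    snaps, times = [], []
    n_cycles = disc.startup_cycles + 1
    for cycle in range(n_cycles):
        this_cycle = []
        for k in range(disc.steps_per_cycle):
            t = (cycle * disc.steps_per_cycle + k + 1) * dt
            rhs = rhs_cilia + system.T.T @ system.pressure_rhs(
                cardiac.anterior_pressure(t),
                cardiac.posterior_pressure(t, omega=omega),
            )
            rhs_t = rhs + (system.M_r / dt) @ (system.T.T @ u.ravel())
            u, p = system._solve(lu, Auu, rhs_t)
            this_cycle.append((u.copy(), p.copy()))
            if cycle == n_cycles - 1:
                snaps.append((u, p))
                times.append(t)
        if prev_cycle is not None:
            num = max(
                np.abs(a[0] - b).max() for a, b in zip(this_cycle, prev_cycle)
            )
            den = max(np.abs(a[0]).max() for a in this_cycle) or 1.0
            if num / den > disc.cycle_tolerance and cycle == n_cycles - 1:
                logger.warning(
                    "cardiac cycle not periodic to %.1e (got %.1e); "
                    "increase startup_cycles", disc.cycle_tolerance, num / den
                )
        prev_cycle = [a[0] for a in this_cycle]
    return _make_field(system, snaps, times, steady=False)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def velocity_at_cell_points(
    mesh: LabeledMesh, u: np.ndarray, ref_pts: np.ndarray
) -> np.ndarray:
    """Evaluate the facet-based velocity inside every cell at reference
    points; returns (ncells, nq, 3)."""
    pts = map_to_cells(ref_pts, mesh.points[mesh.cells])
    grads = mesh.barycentric_gradients
    verts = mesh.points[mesh.cells]
    lam = 1.0 + np.einsum(
        "cix,cqix->cqi", grads, pts[:, :, None, :] - verts[:, None, :, :]
    )
    phi = 1.0 - 3.0 * lam
    coeffs = u[mesh.cell_facets]  # (nc, 4, 3)
    return np.einsum("cqi,cid->cqd", phi, coeffs)


def rt0_velocity_at_points(
    mesh: LabeledMesh, fluxes: np.ndarray, cells: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    """Evaluate the Raviart-Thomas reconstruction u(x) = sum_F sigma_F q_F
    (x - p_F) / (3 |K|) at points (n, nq, 3) inside the given cells."""
    q = fluxes[mesh.cell_facets[cells]]                       # (n, 4)
    sign = np.where(mesh.facet_cells[mesh.cell_facets[cells], 0] == cells[:, None], 1.0, -1.0)
    verts = mesh.points[mesh.cells[cells]]                    # (n, 4, 3)
    vol = mesh.cell_volumes[cells]
    diff = pts[:, :, None, :] - verts[:, None, :, :]          # (n, nq, 4, 3)
    return np.einsum("ni,nqix->nqx", q * sign / (3.0 * vol)[:, None], diff)


def flow_statistics(field: FlowField, disc_degree: int = 2) -> dict:
    """Max speed, spatial RMS speed per snapshot, and its cycle average."""
    if field.num_snapshots == 0:
        raise ValueError("flow field holds no snapshots")
    mesh = field.mesh
    ref_pts, ref_w = tetrahedron_rule(max(2, disc_degree))
    vol = mesh.total_volume
    max_speed = 0.0
    rms = []
    for u in field.velocity:
        uq = velocity_at_cell_points(mesh, u, ref_pts)
        speed2 = np.einsum("cqd,cqd->cq", uq, uq)
        max_speed = max(max_speed, float(np.sqrt(speed2.max())))
        integral = float(
            np.einsum("q,cq,c->", ref_w, speed2, 6.0 * mesh.cell_volumes)
        )
        rms.append(np.sqrt(integral / vol))
    rms = np.asarray(rms)
    return {
        "max_speed": max_speed,
        "rms_speed": rms,
        "mean_speed": float(rms.mean()),
    }


def divergence_residual(field: FlowField) -> float:
    """Max over cells and snapshots of the cellwise-average divergence."""
    mesh = field.mesh
    sign = np.where(
        mesh.facet_cells[mesh.cell_facets][:, :, 0] == np.arange(mesh.num_cells)[:, None],
        1.0,
        -1.0,
    )
    worst = 0.0
    for q in field.facet_fluxes:
        div = np.abs((sign * q[mesh.cell_facets]).sum(axis=1)) / mesh.cell_volumes
        worst = max(worst, float(div.max()))
    return worst
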