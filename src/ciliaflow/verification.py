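"""Analytic and manufactured-solution oracles for the PDE solvers.

Everything here runs on fixtures (unit cube, slab) with closed-form exact
solutions, so the flow and transport discretizations are testable without
external data:

* :func:`manufactured_stokes_case` -- steady Stokes with a smooth
  divergence-free exact velocity and trigonometric pressure, Dirichlet data
  on the whole boundary; reports L2 errors and observed orders (the velocity
  scheme is a first-order method; second order is typically observed in L2).
* :func:`manufactured_transport_case` -- space-time advection-diffusion with
  an analytic rotating velocity, weak Dirichlet boundaries and a manufactured
  source; h and dt refined together (quadratic elements + BDF2: order 2).
* :func:`diffusion_decay_case` -- slab eigenmode cos(pi x / L) decaying at
  exp(-D pi^2 t / L^2) under no-flux walls.
* :func:`superposition_check` -- linearity of Stokes: the baseline flow
  equals the cilia-driven plus the cardiac-driven solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .dg import DGSpace, SIPGDiffusion, UpwindAdvection
from .mesh import LabeledMesh, box_mesh
from .quadrature import map_to_cells, tetrahedron_rule
from .stokes import (
    CardiacForcing,
    CiliaTractionSpec,
    FluidProperties,
    FlowScenario,
    StokesDiscretization,
    divergence_residual,
    solve_steady_stokes,
    solve_transient_cycle,
    velocity_at_cell_points,
)


@dataclass
class ConvergenceReport:
    mesh_sizes: list[float]
    errors: list[float]
    orders: list[float]

    @property
    def fitted_order(self) -> float:
        """Least-squares slope of log(error) against log(h)."""
        return float(
            np.polyfit(np.log(self.mesh_sizes), np.log(self.errors), 1)[0]
        )

    def to_dict(self) -> dict:
        return {
            "mesh_sizes": self.mesh_sizes,
            "errors": self.errors,
            "orders": self.orders,
            "fitted_order": self.fitted_order,
        }


def _stepwise_orders(hs, errs) -> list[float]:
    return [
        float(np.log(e0 / e1) / np.log(h0 / h1))
        for (h0, e0), (h1, e1) in zip(zip(hs, errs), zip(hs[1:], errs[1:]))
    ]


def _l2_error(mesh: LabeledMesh, values_at, exact_at, degree: int = 4) -> float:
    rp, rw = tetrahedron_rule(degree)
    pts = map_to_cells(rp, mesh.points[mesh.cells])
    approx = values_at(pts)
    diff = approx - exact_at(pts.reshape(-1, 3)).reshape(approx.shape)
    if diff.ndim == 3:
        sq = np.einsum("cqd,cqd->cq", diff, diff)
    else:
        sq = diff ** 2
    return float(np.sqrt(np.einsum("q,cq,c->", rw, sq, 6.0 * mesh.cell_volumes)))


# ---------------------------------------------------------------------------
# Stokes
# ---------------------------------------------------------------------------

_PI = np.pi


def _stokes_exact_u(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack(
        [
            _PI * np.sin(_PI * x) * np.cos(_PI * y),
            -_PI * np.cos(_PI * x) * np.sin(_PI * y),
            np.zeros_like(x),
        ]
    )


def _stokes_exact_p(pts: np.ndarray) -> np.ndarray:
    return np.cos(_PI * pts[:, 0]) * np.cos(_PI * pts[:, 2])


def _stokes_source(mu: float):
    def f(pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        lap_u = np.column_stack(
            [
                -2 * _PI ** 3 * np.sin(_PI * x) * np.cos(_PI * y),
                2 * _PI ** 3 * np.cos(_PI * x) * np.sin(_PI * y),
                np.zeros_like(x),
            ]
        )
        grad_p = np.column_stack(
            [
                -_PI * np.sin(_PI * x) * np.cos(_PI * z),
                np.zeros_like(x),
                -_PI * np.cos(_PI * x) * np.sin(_PI * z),
            ]
        )
        return -mu * lap_u + grad_p

    return f


def manufactured_stokes_case(
    levels: tuple[int, ...] = (2, 4, 6), viscosity: float = 0.7e-3
) -> tuple[ConvergenceReport, ConvergenceReport]:
    """Velocity and pressure L2 convergence on the unit cube."""
    if len(levels) < 2:
        raise ValueError("at least two refinement levels are required")
    u_errs, p_errs, hs = [], [], []
    for n in levels:
        mesh = box_mesh((n, n, n))
        mids = mesh.facet_midpoints
        dirichlet = {
            int(f): _stokes_exact_u(mids[f][None])[0] for f in mesh.boundary_facets
        }
        field = solve_steady_stokes(
            mesh,
            FluidProperties(viscosity=viscosity),
            mms_source=_stokes_source(viscosity),
            dirichlet=dirichlet,
        )
        u, p = field.velocity[0], field.pressure[0]
        rp, _ = tetrahedron_rule(4)
        u_errs.append(
            _l2_error(
                mesh,
                lambda pts, u=u, m=mesh: velocity_at_cell_points(m, u, rp),
                _stokes_exact_u,
            )
        )
        pe = _stokes_exact_p(mesh.cell_centroids)
        pe -= np.average(pe, weights=mesh.cell_volumes)
        ph = p - np.average(p, weights=mesh.cell_volumes)
        p_errs.append(float(np.sqrt(np.sum((ph - pe) ** 2 * mesh.cell_volumes))))
        hs.append(1.0 / n)
    return (
        ConvergenceReport(hs, u_errs, _stepwise_orders(hs, u_errs)),
        ConvergenceReport(hs, p_errs, _stepwise_orders(hs, p_errs)),
    )


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------


def _transport_exact(t: float):
    def c(pts):
        return (
            np.exp(-t)
            * np.cos(_PI * pts[:, 0])
            * np.cos(_PI * pts[:, 1])
            * np.cos(_PI * pts[:, 2])
        )

    return c


def _transport_velocity(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return 0.3 * np.column_stack(
        [
            _PI * np.sin(_PI * x) * np.cos(_PI * y),
            -_PI * np.cos(_PI * x) * np.sin(_PI * y),
            np.zeros_like(x),
        ]
    )


def _transport_source(D: float, t: float):
    def f(pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        c = (
            np.exp(-t)
            * np.cos(_PI * x)
            * np.cos(_PI * y)
            * np.cos(_PI * z)
        )
        dcdt = -c
        lap = -3 * _PI ** 2 * c
        adv = (
            0.3
            * _PI ** 2
            * np.exp(-t)
            * np.cos(_PI * z)
            * (
                np.cos(_PI * x) ** 2 * np.sin(_PI * y) ** 2
                - np.sin(_PI * x) ** 2 * np.cos(_PI * y) ** 2
            )
        )
        return dcdt + adv - D * lap

    return f


def manufactured_transport_case(
    levels: tuple[int, ...] = (2, 4, 8),
    diffusivity: float = 0.05,
    degree: int = 2,
    alpha: float = 50.0,
    final_time: float = 0.2,
    base_steps: int = 2,
) -> ConvergenceReport:
    """Space-time L2 convergence of the SIPG/upwind/BDF2 transport solver
    under simultaneous h and dt refinement."""
    errs, hs = [], []
    for lvl, n in enumerate(levels):
        mesh = box_mesh((n, n, n))
        space = DGSpace(mesh, degree)
        bfacets = mesh.boundary_facets
        diff = SIPGDiffusion(space, alpha=alpha, dirichlet_facets=bfacets)
        adv = UpwindAdvection(space)
        A = adv.matrix_from_callable(_transport_velocity, dirichlet_facets=bfacets)
        M = space.mass_matrix()

        steps = base_steps * 2 ** lvl
        dt = final_time / steps
        op = (1.5 / dt) * M + diffusivity * diff.matrix + A
        lu = spla.splu(op.tocsc())

        c_prev = space.project(_transport_exact(0.0))
        c_cur = space.project(_transport_exact(dt))
        for k in range(2, steps + 1):
            t = k * dt
            rhs = M @ ((2.0 / dt) * c_cur - (0.5 / dt) * c_prev)
            rhs += diffusivity * diff.dirichlet_rhs(_transport_exact(t))
            rhs += adv.dirichlet_inflow_rhs(_transport_exact(t))
            rhs += space.source_vector(_transport_source(diffusivity, t))
            c_prev, c_cur = c_cur, lu.solve(rhs)

        cells = np.arange(mesh.num_cells)
        rp, _ = tetrahedron_rule(2 * degree + 2)
        errs.append(
            _l2_error(
                mesh,
                lambda pts: space.eval_function(c_cur, cells, pts),
                _transport_exact(final_time),
                degree=2 * degree + 2,
            )
        )
        hs.append(1.0 / n)
    return ConvergenceReport(hs, errs, _stepwise_orders(hs, errs))


def diffusion_decay_case(
    diffusivity: float = 1.15e-10,
    steps: int = 100,
    dt: float = 0.023,
    length: float = 100e-6,
    resolution: tuple[int, int, int] = (20, 3, 3),
    degree: int = 2,
) -> dict:
    """Decay of the first Neumann eigenmode cos(pi x / L) on a slab against
    the closed form exp(-D pi^2 t / L^2).  The first BDF2 level is taken from
    one implicit-Euler step."""
    mesh = box_mesh(resolution, (length, 0.2 * length, 0.2 * length))
    space = DGSpace(mesh, degree)
    diff = SIPGDiffusion(space)
    M = space.mass_matrix()

    def mode(pts):
        return np.cos(_PI * pts[:, 0] / length)

    c0 = space.project(mode)
    # implicit Euler startup step
    op1 = (1.0 / dt) * M + diffusivity * diff.matrix
    c1 = spla.splu(op1.tocsc()).solve(M @ c0 / dt)
    op = (1.5 / dt) * M + diffusivity * diff.matrix
    lu = spla.splu(op.tocsc())
    c_prev, c_cur = c0, c1
    for _ in range(steps - 1):
        c_prev, c_cur = c_cur, lu.solve(M @ ((2.0 / dt) * c_cur - (0.5 / dt) * c_prev))
    t_end = steps * dt
    w = space.project(mode)
    Mw = M @ w
    amplitude = float((Mw @ c_cur) / (Mw @ w))
    exact = float(np.exp(-diffusivity * _PI ** 2 * t_end / length ** 2))
    return {
        "amplitude": amplitude,
        "exact": exact,
        "relative_error": abs(amplitude / exact - 1.0),
        "time": t_end,
    }


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def superposition_check(
    mesh: LabeledMesh,
    props: FluidProperties = FluidProperties(),
    cilia: CiliaTractionSpec | None = None,
    cardiac: CardiacForcing = CardiacForcing(),
    disc: StokesDiscretization = StokesDiscretization(),
) -> float:
    """Max relative pointwise defect between the baseline flow and the sum
    of the cilia-driven (caps open, zero cap pressure) and cardiac-driven
    solutions; linearity of Stokes makes this machine-small."""
    cilia = cilia if cilia is not None else CiliaTractionSpec()
    base = solve_transient_cycle(
        mesh, props, cilia=cilia, cardiac=cardiac, disc=disc,
        scenario=FlowScenario("baseline"),
    )
    cardiac_only = solve_transient_cycle(
        mesh, props, cilia=cilia, cardiac=cardiac, disc=disc,
        scenario=FlowScenario("cardiac_only"),
    )
    cilia_steady = solve_steady_stokes(mesh, props, cilia=cilia, disc=disc)
    scale = max(np.abs(u).max() for u in base.velocity)
    defect = max(
        np.abs(ub - (uc + cilia_steady.velocity[0])).max()
        for ub, uc in zip(base.velocity, cardiac_only.velocity)
    )
    return defect / scale


def verify_all(levels: int = 3) -> dict:
    """Run the whole oracle battery; returns a JSON-serializable report."""
    ns = tuple(2 * 2 ** k for k in range(levels)) if levels <= 3 else (2, 4, 8)
    u_rep, p_rep = manufactured_stokes_case(levels=ns[:3])
    t_rep = manufactured_transport_case(levels=ns[:3])
    decay = diffusion_decay_case()
    return {
        "stokes_velocity": u_rep.to_dict(),
        "stokes_pressure": p_rep.to_dict(),
        "transport": t_rep.to_dict(),
        "diffusion_decay": decay,
    }
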