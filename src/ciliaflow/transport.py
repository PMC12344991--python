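"""Solute transport after photoconversion.

The concentration c of a photoconverted solute obeys the conservation law

    dc/dt + div J = 0,      J = c u - D grad c,

one-way coupled to the stored CSF flow cycle (reused periodically, one
snapshot per step).  Walls are impermeable (J.n = 0); on the anterior /
posterior pressure caps the diffusive flux is zero and the advective inflow
re-injects the previous step's total outflow (approximate periodicity: the
embryonic ventricular system is closed, so solute leaving with the cardiac
pulse must come back).  Inside the photoconversion region the concentration
follows the logarithmic experimental curve

    c(t) = log(1 + t/a) / log(1 + T/a),

prescribed strongly on every degree of freedom of the tagged cells.

Discretization: modal DG (quadratic by default) with SIPG diffusion
(penalty alpha), upwind advective fluxes, and BDF2 in time; the two starting
levels come from heavily smoothed diffusion solves (D multiplied by 1e5),
each normalized to unit maximum and rescaled by the photoconversion curve.
Linear systems are solved by preconditioned flexible GMRES with the
diffusion-only operator (prefactored) as preconditioner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import scipy.sparse.linalg as spla

from .dg import DGSpace, SIPGDiffusion, UpwindAdvection
from .mesh import LabeledMesh, PHOTOCONVERSION, PRESSURE_LABELS, ROI_NAMES
from .quantities import ROITimeSeries, SOLUTE_DIFFUSIVITIES, roi_mean_series
from .stokes import FlowField, rt0_velocity_at_points

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SoluteSpec:
    label: str
    diffusivity: float  # m^2/s

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")

    @classmethod
    def named(cls, label: str) -> "SoluteSpec":
        try:
            return cls(label, SOLUTE_DIFFUSIVITIES[label])
        except KeyError:
            raise KeyError(
                f"unknown solute {label!r}; catalog: {sorted(SOLUTE_DIFFUSIVITIES)}"
            ) from None


@dataclass(frozen=True)
class PhotoconversionSpec:
    """Logarithmic photoconversion curve; ``curve_time`` (a) and the final
    time T share units (seconds)."""

    final_time: float
    curve_time: float = 65.0

    def __post_init__(self):
        if self.curve_time <= 0 or self.final_time <= 0:
            raise ValueError("photoconversion times must be positive")

    def value(self, t: float) -> float:
        if t < -1e-12 or t > self.final_time * (1 + 1e-12):
            raise ValueError(f"time {t} outside [0, T={self.final_time}]")
        return math.log1p(max(t, 0.0) / self.curve_time) / math.log1p(
            self.final_time / self.curve_time
        )


def photoconversion_value(t: float, spec: PhotoconversionSpec) -> float:
    return spec.value(t)


@dataclass(frozen=True)
class TransportDiscretization:
    degree: int = 2
    alpha: float = 50.0
    dt: float = 0.023
    init_diffusion_multiplier: float = 1e5
    gmres_tol: float = 1e-10
    max_gmres_iter: int = 200
    inflow_cap: float = 2.0  # ceiling on the imposed cap inflow concentration

    def __post_init__(self):
        if self.alpha <= 0 or self.dt <= 0:
            raise ValueError("alpha and dt must be positive")


@dataclass
class PeriodicFluxState:
    """Bookkeeping for the approximate-periodic cap condition: the previous
    step's total advective outflow (amount/time) plus any amount that could
    not be discharged during phases with negligible inflow."""

    outflow_rate_prev: float = 0.0
    accumulated: float = 0.0


@dataclass
class TransportState:
    c: np.ndarray           # current concentration coefficients
    c_prev: np.ndarray      # previous level (BDF2 history)
    time: float
    step: int
    flux_state: PeriodicFluxState = dc_field(default_factory=PeriodicFluxState)


class ConcentrationHistory:
    """Recorded diagnostics of a transport run."""

    def __init__(self):
        self.times: list[float] = []
        self.mass: list[float] = []
        self.reservoir: list[float] = []
        self.min_c: list[float] = []
        self.max_c: list[float] = []
        self.snapshots: dict[float, np.ndarray] = {}


class _ScaledIdentity:
    def __init__(self, scale: float):
        self.scale = scale

    def solve(self, x: np.ndarray) -> np.ndarray:
        return self.scale * x


class TransportSolver:
    """Assembled transport operators for one mesh/solute/flow combination."""

    def __init__(
        self,
        mesh: LabeledMesh,
        flow: FlowField,
        solute: SoluteSpec,
        pc: PhotoconversionSpec | None,
        disc: TransportDiscretization = TransportDiscretization(),
    ):
        self.mesh = mesh
        self.flow = flow
        self.solute = solute
        self.pc = pc
        self.disc = disc
        self.space = DGSpace(mesh, disc.degree)
        self.nb = self.space.nb

        caps = mesh.facets_with_label([int(l) for l in PRESSURE_LABELS])
        # caps with identically zero flux (steady cilia flow with closed
        # caps) are treated as walls
        if flow is not None and len(caps):
            qmax = max(np.abs(q[caps]).max() for q in flow.facet_fluxes)
            if qmax == 0.0:
                caps = np.empty(0, dtype=int)
        self.open_facets = caps

        self.mass = self.space.mass_matrix()
        self.w_int = self.space.integration_vector()
        self.diffusion = SIPGDiffusion(self.space, alpha=disc.alpha)
        self.advection = UpwindAdvection(self.space, open_facets=caps)

        if pc is not None:
            pc_cells = np.asarray(mesh.cell_sets[PHOTOCONVERSION], dtype=int)
            if len(pc_cells) == 0:
                raise ValueError("photoconversion region is empty")
        else:
            pc_cells = np.empty(0, dtype=int)
        self.pc_cells = pc_cells
        self.pc_dofs = self.space.cell_dof_slice(pc_cells)
        self.free_mask = np.ones(self.space.ndof, dtype=bool)
        self.free_mask[self.pc_dofs] = False

        self._phase_blocks: list[np.ndarray] = []
        self._phase_un: list[tuple[np.ndarray, np.ndarray]] = []
        tensor = None
        if flow is not None:
            tensor = self.advection.rt0_cell_tensor()
            for q in flow.facet_fluxes:
                self._phase_blocks.append(
                    self.advection.cell_blocks_from_fluxes(tensor, q)
                )
                self._phase_un.append(self.advection.normal_velocities(q))

        D = solute.diffusivity
        self.bdf2_lhs_diffusion = (1.5 / disc.dt) * self.mass + D * self.diffusion.matrix
        # preconditioner: the full operator at the cycle-averaged fluxes.
        # Only the oscillating cardiac part of the advection is left for the
        # Krylov iteration, which then converges in a handful of steps
        pre_mat = self.bdf2_lhs_diffusion
        if flow is not None and len(flow.facet_fluxes):
            q_mean = np.mean(flow.facet_fluxes, axis=0)
            pre_mat = pre_mat + self.advection.matrix_from_fluxes(q_mean, tensor)
        free = np.nonzero(self.free_mask)[0]
        self._pre = spla.splu(pre_mat[free][:, free].tocsc())

        # ROI integration vectors: use whichever ROI sets the mesh carries;
        # fixture meshes without any fall back to the whole domain
        self.roi_names = tuple(n for n in ROI_NAMES if n in mesh.cell_sets)
        if self.roi_names:
            self.roi_volumes = np.array(
                [mesh.cell_volumes[np.asarray(mesh.cell_sets[n], int)].sum()
                 for n in self.roi_names]
            )
            w_cells = self.w_int.reshape(-1, self.nb)
            self.roi_w = np.zeros((len(self.roi_names), self.space.ndof))
            for j, name in enumerate(self.roi_names):
                idx = np.asarray(mesh.cell_sets[name], dtype=int)
                self.roi_w[j].reshape(-1, self.nb)[idx] = w_cells[idx]
        else:
            self.roi_names = ("DOMAIN",)
            self.roi_w = self.w_int[None, :]
            self.roi_volumes = np.array([mesh.total_volume])

    # -- operator application -------------------------------------------------

    def n_phases(self) -> int:
        return max(1, len(self._phase_blocks))

    def _apply_operator(self, phase: int, x: np.ndarray) -> np.ndarray:
        y = self.bdf2_lhs_diffusion @ x
        if self._phase_blocks:
            blocks = self._phase_blocks[phase]
            xm = x.reshape(-1, self.nb)
            y += np.einsum("cab,cb->ca", blocks, xm).ravel()
            un_int, un_open = self._phase_un[phase]
            y += self.advection.apply_facets(un_int, un_open, x)
        return y

    def _solve_constrained(self, phase: int, rhs: np.ndarray, pc_value: float) -> np.ndarray:
        """Solve the BDF2 system with the photoconversion cells pinned to
        ``pc_value`` (constant mode only; higher modes zero)."""
        full_fix = np.zeros(self.space.ndof)
        if len(self.pc_dofs):
            full_fix.reshape(-1, self.nb)[self.pc_cells, 0] = (
                pc_value * self.space.L00[self.pc_cells]
            )
            rhs = rhs - self._apply_operator(phase, full_fix)
        free = self.free_mask
        nfree = int(free.sum())

        def mv(xf):
            x = np.zeros(self.space.ndof)
            x[free] = xf
            return self._apply_operator(phase, x)[free]

        def pre(xf):
            return self._pre.solve(xf)

        A = spla.LinearOperator((nfree, nfree), matvec=mv)
        M = spla.LinearOperator((nfree, nfree), matvec=pre)
        b = rhs[free]
        bnorm = np.linalg.norm(b)
        if bnorm == 0.0:
            xf = np.zeros(nfree)
        else:
            xf, info = spla.lgmres(
                A, b, M=M, rtol=self.disc.gmres_tol, atol=0.0,
                maxiter=self.disc.max_gmres_iter,
            )
            if info != 0:
                res = np.linalg.norm(A @ xf - b) / bnorm
                raise RuntimeError(
                    f"transport GMRES failed to converge (info={info}, "
                    f"relative residual {res:.2e})"
                )
        out = full_fix
        out[free] = xf
        return out

    # -- initial conditions ---------------------------------------------------

    def smooth_initial_conditions(self) -> tuple[np.ndarray, np.ndarray]:
        """Two heavily-diffused fields for the BDF2 startup: implicit Euler
        diffusion steps with D~ = D * multiplier from c = 0, the tagged cells
        held at 1, each normalized to unit max and scaled by the
        photoconversion curve at dt and 2 dt."""
        if self.pc is None or len(self.pc_cells) == 0:
            raise ValueError("photoconversion region is empty")
        disc, D = self.disc, self.solute.diffusivity
        Dt = D * disc.init_diffusion_multiplier
        op = (1.0 / disc.dt) * self.mass + Dt * self.diffusion.matrix
        lu = spla.splu(op.tocsc())
        free = self.free_mask

        def smooth_step(c0):
            fix = np.zeros(self.space.ndof)
            fix.reshape(-1, self.nb)[self.pc_cells, 0] = self.space.L00[self.pc_cells]
            rhs = (self.mass @ c0) / disc.dt - op @ fix
            x = np.zeros(self.space.ndof)
            # one direct solve on the constrained system via the full
            # factorization and a projected correction is overkill here: the
            # operator is SPD and diffusion-only, so a few preconditioned CG
            # refinements on the free block suffice
            xf, info = spla.cg(
                spla.LinearOperator(
                    (int(free.sum()),) * 2,
                    matvec=lambda v: self._embed_apply(op, v),
                ),
                rhs[free],
                M=spla.LinearOperator(
                    (int(free.sum()),) * 2,
                    matvec=lambda v: self._embed_solve(lu, v),
                ),
                rtol=1e-12, atol=0.0, maxiter=500,
            )
            if info != 0:
                raise RuntimeError("initial smoothing solve failed")
            x[free] = xf
            x += fix
            return x

        c1 = smooth_step(np.zeros(self.space.ndof))
        c2 = smooth_step(c1)
        v1, v2 = self.pc.value(disc.dt), self.pc.value(2 * disc.dt)
        c1 = c1 / self.space.max_over_cells(c1) * v1
        c2 = c2 / self.space.max_over_cells(c2) * v2
        return c1, c2

    def _embed_apply(self, op, v):
        x = np.zeros(self.space.ndof)
        x[self.free_mask] = v
        return (op @ x)[self.free_mask]

    def _embed_solve(self, lu, v):
        x = np.zeros(self.space.ndof)
        x[self.free_mask] = v
        return lu.solve(x)[self.free_mask]

    # -- stepping --------------------------------------------------------------

    def initial_state(self) -> TransportState:
        c1, c2 = self.smooth_initial_conditions()
        return TransportState(c=c2, c_prev=c1, time=2 * self.disc.dt, step=2)

    def periodic_flux_update(
        self, state: PeriodicFluxState, un_open: np.ndarray, dt: float
    ) -> tuple[float, PeriodicFluxState]:
        """Choose the uniform inflow concentration that discharges the
        previous outflow (plus any backlog).  The imposed value is capped at
        ``inflow_cap``: near flow reversal the available inflow rate passes
        through zero, and an uncapped value would inject arbitrarily high
        boundary concentrations (an unstable feedback loop); any amount that
        cannot be discharged this step accumulates instead."""
        target_rate = state.outflow_rate_prev + state.accumulated / dt
        if len(un_open) == 0 or target_rate == 0.0:
            return 0.0, PeriodicFluxState(state.outflow_rate_prev, state.accumulated)
        infl = un_open < 0.0
        vin = float(-(un_open[infl] * self.advection.b_areas[infl]).sum()) if infl.any() else 0.0
        scale = np.abs(un_open).max() * self.advection.b_areas.max()
        if vin <= 1e-9 * max(scale, 1e-300):
            return 0.0, PeriodicFluxState(
                state.outflow_rate_prev, state.accumulated + state.outflow_rate_prev * dt
            )
        c_in = min(target_rate / vin, self.disc.inflow_cap)
        leftover = (target_rate - c_in * vin) * dt
        return c_in, PeriodicFluxState(state.outflow_rate_prev, max(leftover, 0.0))

    def advance(self, state: TransportState) -> TransportState:
        """One BDF2 step."""
        disc = self.disc
        n = state.step + 1
        t = n * disc.dt
        phase = (n - 1) % self.n_phases() if self._phase_blocks else 0
        un_open = self._phase_un[phase][1] if self._phase_blocks else np.empty(0)

        c_in, flux_state = self.periodic_flux_update(state.flux_state, un_open, disc.dt)
        rhs = self.mass @ (2.0 / disc.dt * state.c - 0.5 / disc.dt * state.c_prev)
        if c_in != 0.0:
            rhs += self.advection.inflow_vector(un_open, c_in)

        pc_val = self.pc.value(t) if self.pc is not None else 0.0
        c_new = self._solve_constrained(phase, rhs, pc_val)

        out_rate, _ = (
            self.advection.boundary_rates(un_open, c_new)
            if len(self.open_facets)
            else (0.0, 0.0)
        )
        # the discharged inflow amount re-enters the domain; the fresh
        # outflow is parked for the next step
        new_flux = PeriodicFluxState(
            outflow_rate_prev=out_rate, accumulated=flux_state.accumulated
        )
        return TransportState(
            c=c_new, c_prev=state.c, time=t, step=n, flux_state=new_flux
        )

    def total_mass(self, c: np.ndarray) -> float:
        return float(self.w_int @ c)

    def roi_integrals(self, c: np.ndarray) -> np.ndarray:
        return self.roi_w @ c


def run_transport(
    mesh: LabeledMesh,
    flow: FlowField,
    solute: SoluteSpec,
    pc: PhotoconversionSpec | None,
    disc: TransportDiscretization = TransportDiscretization(),
    n_cycles: int = 100,
    steps_per_cycle: int | None = None,
    record_stride: int = 1,
    snapshot_times: tuple[float, ...] = (),
    initial_state: TransportState | None = None,
) -> tuple[ConcentrationHistory, ROITimeSeries, TransportState]:
    """Initialize (smoothed photoconversion fields) and advance the solute
    for ``n_cycles`` cardiac cycles, recording ROI means every
    ``record_stride`` steps plus a mass audit per step."""
    solver = TransportSolver(mesh, flow, solute, pc, disc)
    P = steps_per_cycle or (flow.num_snapshots if not flow.steady else 20)
    n_steps = n_cycles * P

    if initial_state is not None:
        state = initial_state
    elif pc is not None:
        state = solver.initial_state()
    else:
        state = TransportState(
            c=np.zeros(solver.space.ndof),
            c_prev=np.zeros(solver.space.ndof),
            time=2 * disc.dt,
            step=2,
        )

    history = ConcentrationHistory()
    times = [state.time]
    integrals = [solver.roi_integrals(state.c)]
    history.times.append(state.time)
    history.mass.append(solver.total_mass(state.c))
    history.reservoir.append(0.0)
    lo, hi = solver.space.minmax_over_cells(state.c)
    history.min_c.append(lo)
    history.max_c.append(hi)

    last_step = state.step + n_steps
    while state.step < last_step:
        state = solver.advance(state)
        if (state.step % record_stride == 0) or state.step == last_step:
            times.append(state.time)
            integrals.append(solver.roi_integrals(state.c))
            history.times.append(state.time)
            history.mass.append(solver.total_mass(state.c))
            history.reservoir.append(
                state.flux_state.outflow_rate_prev * disc.dt
                + state.flux_state.accumulated
            )
            lo, hi = solver.space.minmax_over_cells(state.c)
            history.min_c.append(lo)
            history.max_c.append(hi)
        for ts in snapshot_times:
            if abs(state.time - ts) < 0.5 * disc.dt and ts not in history.snapshots:
                history.snapshots[ts] = state.c.copy()

    eps = max(history.max_c[-1] - 1.0, -min(history.min_c))
    if eps > 1e-3:
        logger.info("DG over/undershoot beyond tolerance: %.2e", eps)

    series = roi_mean_series(
        np.asarray(times), np.asarray(integrals), solver.roi_volumes,
        roi_names=solver.roi_names,
    )
    return history, series, state
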