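"""End-to-end scenario orchestration.

A :class:`ScenarioConfig` describes one in-silico experiment: which geometry
(synthetic parameters or a mesh file, optionally deformed by a named
variant), which flow scenario (baseline, cilia-only, cardiac-only, regional
paralysis), which solute, and how long to simulate.  :func:`run_scenario`
executes geometry -> flow -> transport -> quantities and writes a
self-describing run directory; :func:`compare_runs` produces the per-ROI
difference report used for paralysis / mutant / geometry-variant comparisons.

The pipeline is deterministic for a fixed configuration (direct solvers,
fixed iteration tolerances, no sampling), which :func:`run_scenario` records
in the provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    GeometryVariant,
    VentricleParams,
    apply_geometry_variant,
    build_synthetic_ventricles,
    measure_geometry,
)
from .mesh import UM, FacetLabel, LabeledMesh
from .meshfile import load_labeled_mesh, save_labeled_mesh
from .quantities import (
    ROITimeSeries,
    ScaleSet,
    ThresholdSpec,
    dimensionless_report,
    tangential_force,
    time_to_threshold,
)
from .stokes import (
    CardiacForcing,
    CiliaTractionSpec,
    FlowScenario,
    FluidProperties,
    StokesDiscretization,
    divergence_residual,
    flow_statistics,
    solve_transient_cycle,
)
from .transport import (
    PhotoconversionSpec,
    SoluteSpec,
    TransportDiscretization,
    run_transport,
)

logger = logging.getLogger(__name__)

_PARALYSIS_NAMES = {
    "anterior": FacetLabel.CILIA_ANTERIOR,
    "dorsal_mid": FacetLabel.CILIA_DORSAL_MID,
    "ventral_mid": FacetLabel.CILIA_VENTRAL_MID,
}


@dataclass
class ScenarioConfig:
    # geometry
    mesh_path: str | None = None
    geometry_scale: float = 1.0
    target_edge_length: float | None = None
    variant: str | None = None
    geometry_overrides: dict = field(default_factory=dict)
    # flow
    flow_scenario: str = "baseline"
    paralyzed: tuple[str, ...] = ()
    fluid: FluidProperties = field(default_factory=FluidProperties)
    cilia_amplitude: float = 0.65e-3
    cardiac: CardiacForcing = field(default_factory=CardiacForcing)
    stokes: StokesDiscretization = field(default_factory=StokesDiscretization)
    # transport
    solute: str = "dendra2"
    diffusivity: float | None = None
    curve_time: float = 65.0
    n_cycles: int = 100
    record_stride: int = 4
    transport: TransportDiscretization = field(default_factory=TransportDiscretization)
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    # bookkeeping
    seed: int = 0  # recorded for provenance; the PDE pipeline is deterministic

    def resolve_params(self) -> VentricleParams | None:
        if self.mesh_path is not None:
            return None
        params = VentricleParams.default(
            scale=self.geometry_scale,
            target_edge_length=self.target_edge_length,
            **self.geometry_overrides,
        )
        if self.variant:
            params = apply_geometry_variant(params, GeometryVariant(self.variant))
        return params

    def resolve_solute(self) -> SoluteSpec:
        if self.diffusivity is not None:
            return SoluteSpec(self.solute, self.diffusivity)
        return SoluteSpec.named(self.solute)

    def resolve_scenario(self) -> FlowScenario:
        paralyzed = frozenset(int(_PARALYSIS_NAMES[n]) for n in self.paralyzed)
        selector = self.flow_scenario
        if paralyzed and selector == "baseline":
            selector = "paralysis"
        return FlowScenario(selector, paralyzed)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        kwargs = dict(raw)
        for key, typ in (
            ("fluid", FluidProperties),
            ("cardiac", CardiacForcing),
            ("stokes", StokesDiscretization),
            ("transport", TransportDiscretization),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if "thresholds" in kwargs and isinstance(kwargs["thresholds"], (list, tuple)):
            kwargs["thresholds"] = ThresholdSpec(tuple(kwargs["thresholds"]))
        if "paralyzed" in kwargs:
            kwargs["paralyzed"] = tuple(kwargs["paralyzed"])
        return cls(**kwargs)


def _config_hash(config: ScenarioConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class ScenarioResult:
    directory: Path | None
    mesh: LabeledMesh
    flow_stats: dict
    series: ROITimeSeries
    thresholds: np.ndarray
    report: dict


def run_scenario(config: ScenarioConfig, outdir: str | Path | None = None) -> ScenarioResult:
    """Execute the full pipeline for one configuration; write artifacts when
    ``outdir`` is given (mesh, ROI CSV, JSON reports, provenance manifest)."""
    t_start = time.time()
    stage = "geometry"
    try:
        params = config.resolve_params()
        if params is not None:
            mesh = build_synthetic_ventricles(params)
        else:
            mesh = load_labeled_mesh(config.mesh_path)
        geo_report = measure_geometry(mesh, params)

        stage = "flow"
        cilia = CiliaTractionSpec(amplitude=config.cilia_amplitude)
        scenario = config.resolve_scenario()
        flow = solve_transient_cycle(
            mesh,
            config.fluid,
            cilia=cilia,
            cardiac=config.cardiac,
            disc=config.stokes,
            scenario=scenario,
        )
        stats = flow_statistics(flow)
        stats["divergence_residual"] = divergence_residual(flow)

        stage = "transport"
        solute = config.resolve_solute()
        steps = config.stokes.steps_per_cycle
        final_time = (2 + config.n_cycles * steps) * config.transport.dt
        pc = PhotoconversionSpec(final_time=final_time, curve_time=config.curve_time)
        history, series, _ = run_transport(
            mesh,
            flow,
            solute,
            pc,
            config.transport,
            n_cycles=config.n_cycles,
            steps_per_cycle=steps,
            record_stride=config.record_stride,
        )

        stage = "quantities"
        tth = time_to_threshold(series, config.thresholds)
        forces = {
            name: tangential_force(mesh, scenario.resolve(cilia, config.cardiac)[0], label)
            for name, label in _PARALYSIS_NAMES.items()
        }
        forces["total"] = sum(forces.values())
        scales = ScaleSet(
            transport_speed=max(stats["mean_speed"], 1e-12),
            reynolds_speed=max(stats["max_speed"], 1e-12),
        )
        report = {
            "geometry": geo_report.to_dict(),
            "flow": {
                "max_speed_um_per_s": stats["max_speed"] / UM,
                "mean_speed_um_per_s": stats["mean_speed"] / UM,
                "divergence_residual": stats["divergence_residual"],
            },
            "forces_N": forces,
            "time_to_threshold_s": {
                name: (None if not np.isfinite(v) else float(v))
                for name, v in zip(series.roi_names, tth)
            },
            "dimensionless": dimensionless_report(
                scales, config.fluid.viscosity, config.fluid.density
            ),
            "mass_audit": {
                "initial": history.mass[0],
                "final": history.mass[-1],
                "min_c": min(history.min_c),
                "max_c": max(history.max_c),
            },
        }
    except Exception as exc:
        raise RuntimeError(f"scenario failed in stage {stage!r}: {exc}") from exc

    directory = None
    if outdir is not None:
        directory = Path(outdir)
        directory.mkdir(parents=True, exist_ok=True)
        save_labeled_mesh(mesh, directory / "mesh.xdmf")
        series.to_frame().to_csv(directory / "roi_series.csv", index=False)
        (directory / "report.json").write_text(json.dumps(report, indent=2, default=str))
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "elapsed_s": time.time() - t_start,
            "versions": _versions(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ScenarioResult(
        directory=directory,
        mesh=mesh,
        flow_stats=stats,
        series=series,
        thresholds=tth,
        report=report,
    )


def _versions() -> dict:
    import numpy
    import scipy

    from . import __version__

    return {
        "ciliaflow": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }


def compare_runs(
    a: ScenarioResult | ROITimeSeries,
    b: ScenarioResult | ROITimeSeries,
    thresholds: ThresholdSpec = ThresholdSpec(),
) -> dict:
    """Per-ROI curve differences and time-to-threshold changes between two
    runs sharing ROI definitions and sample times."""
    sa = a.series if isinstance(a, ScenarioResult) else a
    sb = b.series if isinstance(b, ScenarioResult) else b
    if sa.means.shape[1] != sb.means.shape[1]:
        raise ValueError("runs disagree in ROI count")
    if len(sa.times) != len(sb.times) or not np.allclose(sa.times, sb.times):
        raise ValueError(
            "runs were sampled at different times; resample one onto the "
            "other's time grid before comparing"
        )
    ta = time_to_threshold(sa, thresholds)
    tb = time_to_threshold(sb, thresholds)
    with np.errstate(invalid="ignore"):
        ratio = tb / ta
    return {
        "max_abs_mean_difference": np.abs(sa.means - sb.means).max(axis=0).tolist(),
        "final_mean_difference": (sb.means[-1] - sa.means[-1]).tolist(),
        "time_to_threshold_a": ta.tolist(),
        "time_to_threshold_b": tb.tolist(),
        "time_to_threshold_ratio": ratio.tolist(),
        "percent_higher_time_to_threshold": (100.0 * (ratio - 1.0)).tolist(),
    }
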