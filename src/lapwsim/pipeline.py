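"""Configuration-driven orchestration of the whole pipeline.

A single YAML config drives: fixture generation (or loading a PCD from
disk) → mesh construction → fiber/conductivity assignment → optional
fibrosis tagging → monodomain simulation → virtual electrograms → feature
extraction → recorded-vs-simulated comparison. Every stage writes its
artifact under the output directory, and a manifest records the config
hash, derived seeds, and package version so identical configs reproduce
identical artifacts.

One global seed fans out to per-stage seeds as
``SeedSequence([global_seed, stage_ordinal]) % 2**31`` — deterministic,
independent streams per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, io
from .comparison import compare_sets
from .egm import forward_egm_set, postprocess
from .ep import SimulationConfig, StimulusProtocol, select_stimulus_nodes, simulate
from .features import EGMFeatures, characterize, detect_lat
from .fibers import ConductivitySet, conductivity_tensor, template_field
from .fibrosis import FibrosisSpec, apply_percolation, generate_pattern
from .geometry import (
    PointCloud,
    clean_surface,
    downsample_pcd,
    extrude_surface,
    reconstruct_surface,
    refine_uniform,
    tetrahedralize,
)
from .synthetic_data import (
    PseudoRecordingSpec,
    SheetSpec,
    make_electrode_grid,
    make_recorded_egm_set,
    make_sheet_pcd,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

STAGE_ORDER = (
    "fixtures",
    "geometry",
    "fibers",
    "fibrosis",
    "simulation",
    "egm",
    "features",
    "comparison",
)


def stage_seed(global_seed: int, stage: str) -> int:
    ordinal = STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([global_seed, ordinal]).generate_state(1)[0]) % (
        2**31
    )


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixturesBlock(_Strict):
    extent_x: float = Field(20.0, gt=0)
    extent_y: float = Field(20.0, gt=0)
    curvature_radius: float = Field(float("inf"), gt=0)
    point_spacing: float = Field(1.0, gt=0)
    positional_noise_sd: float = Field(0.0, ge=0)
    electrode_spacing: float = Field(4.0, gt=0)
    electrode_standoff: float = Field(1.0, gt=0)
    cv: float = Field(70.0, gt=0)
    amplitude_mean: float = Field(2.0, gt=0)
    amplitude_sd: float = Field(0.5, ge=0)
    fractionation_probability: float = Field(0.0, ge=0, le=1)
    jitter_sd: float = Field(0.0, ge=0)


class GeometryBlock(_Strict):
    pcd_path: str | None = None  # XYZ text; None = use the fixtures stage
    downsample_spacing: float = Field(3.5, gt=0)
    thickness: float = Field(2.3, gt=0)
    max_normal_angle: float = Field(60.0, gt=0, le=180.0)
    refine_levels: int = Field(0, ge=0)


class FibersBlock(_Strict):
    theta_endo: float = -60.0
    theta_epi: float = 60.0
    sigma_li: float = Field(1.74, gt=0)
    sigma_le: float = Field(6.25, gt=0)
    sigma_ti: float = Field(0.193, gt=0)
    sigma_te: float = Field(2.36, gt=0)
    K: float = Field(1.0, gt=0)


class FibrosisBlock(_Strict):
    enabled: bool = False
    type: Literal["compact", "diffuse", "interstitial", "patchy"] = "diffuse"
    density: float = Field(0.35, ge=0, le=1)
    feature_size: float | None = Field(None, gt=0)
    octaves: int | None = Field(None, ge=1)
    fiber_anisotropy: float | None = Field(None, ge=1)


class SimulationBlock(_Strict):
    Cm: float = Field(1.0, gt=0)
    chi: float = Field(1500.0, gt=0)
    dt: float = Field(0.01, gt=0)
    duration: float = Field(140.0, gt=0)
    output_rate: float = Field(1000.0, gt=0)
    stimulus_amplitude: float = Field(25.0, gt=0)
    stimulus_duration: float = Field(2.5, gt=0)
    stimulus_start: float = Field(0.0, ge=0)
    lat_window: float = Field(2.0, gt=0)


class EGMBlock(_Strict):
    sigma_b: float = Field(6.67, gt=0)
    band_low: float = Field(2.0, gt=0)
    band_high: float = Field(220.0, gt=0)
    fs_out: float = Field(1000.0, gt=0)


class ComparisonBlock(_Strict):
    enabled: bool = True
    k_clusters: int = Field(3, ge=1)
    variance_target: float = Field(0.90, gt=0, le=1)


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "lapwsim_out"
    fixtures: FixturesBlock | None = FixturesBlock()
    geometry: GeometryBlock = GeometryBlock()
    fibers: FibersBlock = FibersBlock()
    fibrosis: FibrosisBlock = FibrosisBlock()
    simulation: SimulationBlock = SimulationBlock()
    egm: EGMBlock = EGMBlock()
    comparison: ComparisonBlock = ComparisonBlock()
    recorded_csv: str | None = None  # recorded EGM set (overrides fixtures)

    @model_validator(mode="after")
    def _cross_checks(self):
        if self.fixtures is None and self.geometry.pcd_path is None:
            raise ValueError("either a fixtures block or geometry.pcd_path is required")
        if self.geometry.pcd_path is not None and not Path(self.geometry.pcd_path).exists():
            raise ValueError(f"geometry.pcd_path does not exist: {self.geometry.pcd_path}")
        if self.recorded_csv is not None and not Path(self.recorded_csv).exists():
            raise ValueError(f"recorded_csv does not exist: {self.recorded_csv}")
        if self.comparison.enabled and self.fixtures is None and self.recorded_csv is None:
            raise ValueError(
                "comparison requires recorded traces: provide a fixtures block "
                "or recorded_csv"
            )
        return self


def validate_config(path) -> RunConfig:
    """Load + type-check a YAML config; unknown keys are rejected and all
    defaults filled in."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seeds": {},
        "artifacts": {},
        "timings_s": {},
    }

    def _stage(name):
        manifest["seeds"][name] = stage_seed(config.seed, name)
        logger.info("stage %s (seed %d)", name, manifest["seeds"][name])
        return time.perf_counter()

    # ---- fixtures -------------------------------------------------------
    recorded = None
    electrodes = None
    rec_lats = None
    if config.fixtures is not None:
        t0 = _stage("fixtures")
        fx = config.fixtures
        sheet = SheetSpec(
            extent_x=fx.extent_x,
            extent_y=fx.extent_y,
            curvature_radius=fx.curvature_radius,
            point_spacing=fx.point_spacing,
            positional_noise_sd=fx.positional_noise_sd,
            seed=manifest["seeds"]["fixtures"],
        )
        cloud = make_sheet_pcd(sheet)
        io.write_xyz(out / "pcd.xyz", cloud.points)
        manifest["artifacts"]["pcd"] = "pcd.xyz"
        surface0 = reconstruct_surface(cloud)
        electrodes = make_electrode_grid(
            surface0, fx.electrode_spacing, fx.electrode_standoff
        )
        rec_spec = PseudoRecordingSpec(
            cv=fx.cv,
            amplitude_mean=fx.amplitude_mean,
            amplitude_sd=fx.amplitude_sd,
            fractionation_probability=fx.fractionation_probability,
            jitter_sd=fx.jitter_sd,
            duration=config.simulation.duration,
            seed=manifest["seeds"]["fixtures"],
        )
        pseudo = make_recorded_egm_set(electrodes, rec_spec)
        io.write_egm_csv(
            out / "recorded.csv",
            pseudo.time,
            pseudo.traces,
            electrodes,
            sidecar={"provenance": "synthetic-recorded"},
        )
        manifest["artifacts"]["recorded"] = "recorded.csv"
        recorded = pseudo
        manifest["timings_s"]["fixtures"] = round(time.perf_counter() - t0, 3)
        src_points = cloud.points
    else:
        src_points = io.read_xyz(config.geometry.pcd_path)

    if config.recorded_csv is not None:
        time_ms, traces, elec, _ = io.read_egm_csv(config.recorded_csv)
        electrodes = elec
        recorded = None
        recorded_traces = (time_ms, traces)
    elif recorded is not None:
        recorded_traces = (recorded.time, recorded.traces)
    else:
        recorded_traces = None

    # ---- geometry -------------------------------------------------------
    t0 = _stage("geometry")
    g = config.geometry
    cloud = downsample_pcd(PointCloud(src_points), g.downsample_spacing)
    surface = reconstruct_surface(cloud)
    surface, n_removed = clean_surface(surface, g.max_normal_angle)
    shell = extrude_surface(surface, g.thickness)
    mesh = refine_uniform(tetrahedralize(shell), g.refine_levels)
    io.write_stl(out / "surface.stl", surface.vertices, surface.triangles)
    manifest["artifacts"]["surface"] = "surface.stl"
    manifest["cleaned_vertices"] = n_removed
    manifest["timings_s"]["geometry"] = round(time.perf_counter() - t0, 3)

    # ---- fibers ---------------------------------------------------------
    t0 = _stage("fibers")
    fb = config.fibers
    field = template_field(mesh, fb.theta_endo, fb.theta_epi)
    sigma = ConductivitySet(
        sigma_li=fb.sigma_li,
        sigma_le=fb.sigma_le,
        sigma_ti=fb.sigma_ti,
        sigma_te=fb.sigma_te,
        sigma_b=config.egm.sigma_b,
        K=fb.K,
    )
    manifest["timings_s"]["fibers"] = round(time.perf_counter() - t0, 3)

    # ---- fibrosis -------------------------------------------------------
    if config.fibrosis.enabled:
        t0 = _stage("fibrosis")
        spec = FibrosisSpec(
            type=config.fibrosis.type,
            density=config.fibrosis.density,
            seed=manifest["seeds"]["fibrosis"],
            feature_size=config.fibrosis.feature_size,
            octaves=config.fibrosis.octaves,
            fiber_anisotropy=config.fibrosis.fiber_anisotropy,
        )
        pattern = generate_pattern(mesh, field, spec)
        mesh = apply_percolation(mesh, pattern)
        manifest["achieved_fibrosis_density"] = pattern.achieved_density
        manifest["timings_s"]["fibrosis"] = round(time.perf_counter() - t0, 3)
    tensors = conductivity_tensor(field, sigma)
    io.write_vtk_unstructured(
        out / "mesh.vtk",
        mesh.vertices,
        mesh.tets,
        cell_data={
            "subdomain": mesh.element_subdomain,
            "fiber": field.f,
            "sheet": field.s,
            "sheet_normal": field.n,
        },
    )
    manifest["artifacts"]["mesh"] = "mesh.vtk"

    # ---- simulation -----------------------------------------------------
    t0 = _stage("simulation")
    sim = config.simulation
    if recorded_traces is not None and electrodes is not None:
        time_ms, traces = recorded_traces
        from .egm import EGMTrace

        rec_lats = np.array(
            [
                detect_lat(EGMTrace(time_ms, traces[:, k], electrodes[k], "recorded"))
                for k in range(traces.shape[1])
            ]
        )
        stim_nodes = select_stimulus_nodes(mesh, electrodes, rec_lats, sim.lat_window)
        stim = StimulusProtocol(
            amplitude=sim.stimulus_amplitude,
            duration=sim.stimulus_duration,
            start=sim.stimulus_start,
            nodes=stim_nodes,
        )
    else:
        lo = mesh.vertices.min(axis=0) - 1.0
        hi = mesh.vertices.max(axis=0) + 1.0
        hi[0] = lo[0] + 2.0  # stimulate the low-x edge by default
        stim = StimulusProtocol(
            box_min=tuple(lo),
            box_max=tuple(hi),
            amplitude=sim.stimulus_amplitude,
            duration=sim.stimulus_duration,
            start=sim.stimulus_start,
        )
    sim_cfg = SimulationConfig(
        Cm=sim.Cm,
        chi=sim.chi,
        dt=sim.dt,
        duration=sim.duration,
        output_rate=sim.output_rate,
        stimuli=[stim],
    )
    result = simulate(mesh, tensors, sim_cfg)
    _write_im_h5(out / "im_history.h5", result)
    manifest["artifacts"]["im_history"] = "im_history.h5"
    manifest["timings_s"]["simulation"] = round(time.perf_counter() - t0, 3)

    # ---- egm ------------------------------------------------------------
    t0 = _stage("egm")
    if electrodes is None:
        surface_top = mesh.vertices[:, 2].max()
        gx = np.linspace(mesh.vertices[:, 0].min() + 2, mesh.vertices[:, 0].max() - 2, 4)
        gy = np.linspace(mesh.vertices[:, 1].min() + 2, mesh.vertices[:, 1].max() - 2, 4)
        electrodes = np.array(
            [[x, y, surface_top + 1.0] for x in gx for y in gy]
        )
    raw = forward_egm_set(result, electrodes, sigma_b=config.egm.sigma_b)
    band = (config.egm.band_low, config.egm.band_high)
    sim_traces = [postprocess(t, config.egm.fs_out, band) for t in raw]
    io.write_egm_csv(
        out / "simulated.csv",
        sim_traces[0].time,
        np.column_stack([t.phi_e for t in sim_traces]),
        electrodes,
        sidecar={"sigma_b": config.egm.sigma_b, "band_hz": list(band)},
    )
    manifest["artifacts"]["simulated"] = "simulated.csv"
    manifest["timings_s"]["egm"] = round(time.perf_counter() - t0, 3)

    # ---- features -------------------------------------------------------
    t0 = _stage("features")
    feats = [characterize(t) for t in sim_traces]
    _write_features_csv(out / "features.csv", feats)
    manifest["artifacts"]["features"] = "features.csv"
    manifest["timings_s"]["features"] = round(time.perf_counter() - t0, 3)

    # ---- comparison -----------------------------------------------------
    if config.comparison.enabled and recorded_traces is not None:
        t0 = _stage("comparison")
        from .egm import EGMTrace

        time_ms, traces = recorded_traces
        # recorded and simulated windows can differ by one trailing sample
        n_t = min(len(time_ms), len(sim_traces[0].time))
        rec_list = [
            EGMTrace(time_ms[:n_t], traces[:n_t, k], electrodes[k], "recorded")
            for k in range(traces.shape[1])
        ]
        sim_traces = [
            EGMTrace(t.time[:n_t], t.phi_e[:n_t], t.electrode_position) for t in sim_traces
        ]
        n = min(len(rec_list), len(sim_traces))
        report = compare_sets(
            rec_list[:n],
            sim_traces[:n],
            k_clusters=config.comparison.k_clusters,
            seed=manifest["seeds"]["comparison"],
            variance_target=config.comparison.variance_target,
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        manifest["artifacts"]["report"] = "report.json"
        manifest["timings_s"]["comparison"] = round(time.perf_counter() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_features_csv(path, feats: list[EGMFeatures]) -> None:
    header = "electrode," + ",".join(EGMFeatures.FIELD_ORDER)
    rows = [
        f"{k}," + ",".join(f"{v:.9g}" for v in f.as_array())
        for k, f in enumerate(feats)
    ]
    Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")


def _write_im_h5(path, result) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times_ms", data=result.times)
        f.create_dataset("im_uA_per_cm2", data=result.im, compression="gzip")
        f.create_dataset("vm_mV", data=result.vm, compression="gzip")
        f.create_dataset("lat_ms", data=result.lat)
        f.create_dataset("active_nodes", data=result.active_nodes)
        f.create_dataset("node_volumes_cm3", data=result.node_volumes_cm3)
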