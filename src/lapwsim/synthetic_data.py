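"""Desk-scale synthetic fixtures: sheet point clouds, electrode grids, and
pseudo-"recorded" unipolar electrograms.

The generators emulate the statistical structure the pipeline assumes of
clinical electroanatomical data — a curved sheet point cloud at ~1 mm spacing,
a grid of electrodes floating in the blood pool above the wall, and 1 kHz /
140 ms unipolar traces whose local activation times (LATs) follow a planar
wave — without reproducing any particular patient. The pseudo-recording noise
model (normal amplitude and jitter laws, template-copy fractionation) is a
stand-in chosen for testability, not an estimate of clinical statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import PointCloud, SurfaceMesh, _principal_frame

__all__ = [
    "SheetSpec",
    "PseudoRecordingSpec",
    "PseudoRecordingSet",
    "make_sheet_pcd",
    "make_electrode_grid",
    "make_recorded_egm_set",
    "biphasic_template",
]


@dataclass
class SheetSpec:
    """A rectangular (optionally cylinder-curved) sheet of points.

    ``point_spacing`` is the target mean nearest-neighbour distance (1 mm
    matches the raw clinical clouds); ``curvature_radius`` bends the sheet
    onto a cylinder of that radius (``inf`` = flat); ``positional_noise_sd``
    adds isotropic Gaussian jitter.
    """

    extent_x: float = 20.0
    extent_y: float = 20.0
    curvature_radius: float = math.inf
    point_spacing: float = 1.0
    positional_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ValueError("sheet extents must be positive")
        if self.point_spacing <= 0:
            raise ValueError("point_spacing must be positive")
        if self.positional_noise_sd < 0:
            raise ValueError("positional_noise_sd must be >= 0")


@dataclass
class PseudoRecordingSpec:
    """Planar-wave pseudo-recordings at 1 kHz over 140 ms.

    cv is the planar conduction speed (cm/s) used to assign LATs from the
    distance to the earliest-activated sheet edge; amplitudes are drawn from a
    normal law truncated at zero; fractionated traces receive extra
    deflections after the main complex.
    """

    cv: float = 70.0
    amplitude_mean: float = 2.0
    amplitude_sd: float = 0.5
    fractionation_probability: float = 0.0
    extra_deflection_count_range: tuple[int, int] = (1, 3)
    jitter_sd: float = 0.0
    sample_rate: float = 1000.0
    duration: float = 140.0
    template_width_ms: float = 5.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)  # propagation axis
    seed: int = 0

    def __post_init__(self):
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 <= self.fractionation_probability <= 1.0:
            raise ValueError("fractionation_probability must be in [0, 1]")


@dataclass
class PseudoRecordingSet:
    """Pseudo-recorded traces plus their construction ground truth."""

    time: np.ndarray  # ms
    traces: np.ndarray  # (n_samples, n_electrodes) mV
    electrode_positions: np.ndarray  # (n_electrodes, 3) mm
    lats: np.ndarray  # construction LATs, ms
    amplitudes: np.ndarray  # peak-to-peak, mV
    deflection_counts: np.ndarray  # constructed deflections per trace
    spec: PseudoRecordingSpec = field(repr=False, default=None)  # type: ignore


def make_sheet_pcd(spec: SheetSpec) -> PointCloud:
    """Regular-grid sheet cloud, optionally wrapped onto a cylinder.

    The y coordinate is treated as arc length along the cylinder (axis along
    x, radius ``curvature_radius``), so nearest-neighbour spacing is preserved
    under bending. Deterministic for a fixed seed.
    """
    nx = int(math.floor(spec.extent_x / spec.point_spacing)) + 1
    ny = int(math.floor(spec.extent_y / spec.point_spacing)) + 1
    xs = np.arange(nx) * spec.point_spacing
    ys = np.arange(ny) * spec.point_spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    if math.isinf(spec.curvature_radius):
        pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    else:
        R = spec.curvature_radius
        theta = Y.ravel() / R
        pts = np.column_stack([X.ravel(), R * np.sin(theta), R * (1.0 - np.cos(theta))])
    if spec.positional_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.positional_noise_sd, size=pts.shape)
    return PointCloud(pts)


def make_electrode_grid(
    surface: SurfaceMesh, grid_spacing: float, standoff: float
) -> np.ndarray:
    """Electrodes on a regular grid ``standoff`` mm above the sheet.

    Grid points are laid out in the surface's principal plane; each is snapped
    to its nearest surface vertex and lifted along that vertex's outward
    normal. Electrodes sit strictly off-tissue (in the blood pool), hence
    standoff must be positive.
    """
    if standoff <= 0:
        raise ValueError("standoff must be positive: electrodes sit off-tissue")
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    pts = surface.vertices
    e1, e2, _ = _principal_frame(pts)
    c = pts.mean(axis=0)
    u = (pts - c) @ e1
    v = (pts - c) @ e2
    if grid_spacing > (u.max() - u.min()) and grid_spacing > (v.max() - v.min()):
        raise ValueError("grid_spacing exceeds the surface extent: no electrodes")
    nu = int(math.floor((u.max() - u.min()) / grid_spacing + 1e-9)) + 1
    nv = int(math.floor((v.max() - v.min()) / grid_spacing + 1e-9)) + 1
    electrodes = []
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([u, v]))
    for iu in range(nu):
        for iv in range(nv):
            gu = u.min() + iu * grid_spacing
            gv = v.min() + iv * grid_spacing
            _, idx = tree.query([gu, gv])
            electrodes.append(pts[idx] + standoff * surface.vertex_normals[idx])
    return np.asarray(electrodes)


def biphasic_template(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-peak-to-peak biphasic (RS) deflection: positive lobe then negative.

    Derivative-of-Gaussian shape; the steepest downslope — i.e. the detected
    LAT — is exactly at ``center``, and the two extrema sit ``width`` ms on
    either side of it.
    """
    x = (t - center) / width
    w = -x * np.exp(-0.5 * x * x)
    return w / (2.0 * np.exp(-0.5))  # peak-to-peak of -x e^{-x²/2} is 2 e^{-1/2}


def make_recorded_egm_set(
    electrodes: np.ndarray, spec: PseudoRecordingSpec
) -> PseudoRecordingSet:
    """Pseudo-recorded unipolar EGMs for a planar wave across the electrodes.

    Per-electrode LAT = distance from the earliest-activated edge / cv
    (+ normal jitter); amplitude ~ N(mean, sd) truncated positive; with
    probability ``fractionation_probability`` extra late deflections are
    appended (scaled single-lobe copies of the template), each adding exactly
    one counted deflection.
    """
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    if len(electrodes) < 1:
        raise ValueError("need at least one electrode")
    rng = np.random.default_rng(spec.seed)
    axis = np.asarray(spec.direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    s = electrodes @ axis
    dist_mm = s - s.min()
    lat0 = 4.0 * spec.template_width_ms  # head room before the first complex
    lats = lat0 + dist_mm * 100.0 / spec.cv  # mm → cm (÷10), s → ms (×1000)
    if spec.jitter_sd > 0:
        lats = lats + rng.normal(0.0, spec.jitter_sd, size=len(lats))
    lo, hi = spec.extra_deflection_count_range
    tail = 4.0 * spec.template_width_ms
    if spec.fractionation_probability > 0:
        tail += (3.0 * hi + 2.0) * spec.template_width_ms
    if np.max(lats) + tail > spec.duration:
        raise ValueError(
            f"duration {spec.duration} ms too short for latest LAT "
            f"{np.max(lats):.1f} ms (+{tail:.0f} ms waveform tail)"
        )
    n_samples = int(round(spec.duration * spec.sample_rate / 1000.0))
    time = np.arange(n_samples) * (1000.0 / spec.sample_rate)
    traces = np.zeros((n_samples, len(electrodes)))
    amplitudes = np.empty(len(electrodes))
    counts = np.full(len(electrodes), 2, dtype=int)
    for i, lat in enumerate(lats):
        amp = spec.amplitude_mean
        if spec.amplitude_sd > 0:
            for _ in range(100):  # truncated-normal draw (amplitude > 0)
                amp = rng.normal(spec.amplitude_mean, spec.amplitude_sd)
                if amp > 0:
                    break
            else:
                amp = max(spec.amplitude_mean, 1e-3)
        amplitudes[i] = amp
        tr = amp * biphasic_template(time, lat, spec.template_width_ms)
        fractionated = rng.uniform() < spec.fractionation_probability
        if fractionated and hi >= 1:
            k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            gap = 3.0 * spec.template_width_ms
            for j in range(k):
                t_extra = lat + spec.template_width_ms + (j + 1) * gap
                sign = 1.0 if j % 2 == 0 else -1.0
                bump = 0.3 * amp * np.exp(
                    -0.5 * ((time - t_extra) / (0.6 * spec.template_width_ms)) ** 2
                )
                tr = tr + sign * bump
            counts[i] = 2 + k
        traces[:, i] = tr
    return PseudoRecordingSet(
        time=time,
        traces=traces,
        electrode_positions=electrodes,
        lats=np.asarray(lats),
        amplitudes=amplitudes,
        deflection_counts=counts,
        spec=spec,
    )
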