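"""Fiber architecture and electrical anisotropy.

Atrial posterior-wall muscle fibers rotate modestly across the wall; here a
rule-based template assigns each element an orthonormal (fiber, sheet,
sheet-normal) triad whose in-plane angle interpolates linearly from the
endocardial to the epicardial angle with transmural depth. Template fields
can be mapped onto another mesh by translation + per-axis scaling alignment
(an atlas-style mapping), mirroring the observation that posterior-wall fiber
patterns are consistent across hearts.

Conductivities follow the bidomain values of Henriquez (fiber direction:
σ_i = 1.74, σ_e = 6.25 mS/cm; sheet and sheet-normal: σ_i = 0.193,
σ_e = 2.36 mS/cm); the monodomain conductivity in each direction is
σ_i·σ_e/(σ_i+σ_e) — half the harmonic mean. A single multiplicative factor K
on all four bidomain values calibrates the simulated conduction velocity (CV)
to a measured target, iterated with the cable-theory law CV ∝ √σ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VolumeMesh

__all__ = [
    "FiberField",
    "ConductivitySet",
    "CVMeasurement",
    "template_field",
    "map_fibers",
    "monodomain_sigma",
    "conductivity_tensor",
    "measure_cv",
    "calibrate_conductivity",
]


@dataclass
class FiberField:
    """Per-element orthonormal triads: fiber f, sheet s, sheet-normal n."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.f = np.atleast_2d(np.asarray(self.f, float))
        self.s = np.atleast_2d(np.asarray(self.s, float))
        self.n = np.atleast_2d(np.asarray(self.n, float))

    def __len__(self) -> int:
        return len(self.f)

    def validate(self, tol: float = 1e-8) -> None:
        for a, b in [(self.f, self.s), (self.f, self.n), (self.s, self.n)]:
            if np.max(np.abs(np.einsum("ij,ij->i", a, b))) > tol:
                raise ValueError("triads not orthogonal")
        for a in (self.f, self.s, self.n):
            if np.max(np.abs(np.linalg.norm(a, axis=1) - 1.0)) > tol:
                raise ValueError("triad vectors not unit length")
        if np.min(np.einsum("ij,ij->i", np.cross(self.f, self.s), self.n)) < 1.0 - 1e-6:
            raise ValueError("triads not right-handed")


@dataclass
class ConductivitySet:
    """Bidomain inputs, derived monodomain values, and the calibration factor.

    All conductivities in mS/cm. ``sigma_l``/``sigma_t`` are recomputed from
    the (K-scaled) bidomain values via the half-harmonic-mean rule whenever K
    changes. ``sigma_b`` is the blood-pool conductivity used in the forward
    electrogram integral (never stated in the source conventions; 6.67 mS/cm
    ≈ 0.667 S/m blood is the configurable default).
    """

    sigma_li: float = 1.74
    sigma_le: float = 6.25
    sigma_ti: float = 0.193
    sigma_te: float = 2.36
    sigma_b: float = 6.67
    K: float = 1.0

    def __post_init__(self):
        for name in ("sigma_li", "sigma_le", "sigma_ti", "sigma_te", "sigma_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")

    @property
    def sigma_l(self) -> float:
        return monodomain_sigma(self.K * self.sigma_li, self.K * self.sigma_le)

    @property
    def sigma_t(self) -> float:
        return monodomain_sigma(self.K * self.sigma_ti, self.K * self.sigma_te)

    def scaled(self, K: float) -> "ConductivitySet":
        return replace(self, K=K)


@dataclass
class CVMeasurement:
    cv: float  # cm/s
    start_points: np.ndarray
    end_points: np.ndarray
    lat_start: float  # ms (mean over start set)
    lat_end: float  # ms (mean over end set)


def monodomain_sigma(sigma_i: float, sigma_e: float) -> float:
    """Monodomain conductivity σ_iσ_e/(σ_i+σ_e) (half the harmonic mean)."""
    if sigma_i <= 0 or sigma_e <= 0:
        raise ValueError("conductivities must be positive")
    return sigma_i * sigma_e / (sigma_i + sigma_e)


def _element_depth_and_normal(mesh: VolumeMesh):
    if mesh.vertex_depth is None or mesh.vertex_normal is None:
        raise ValueError(
            "mesh lacks transmural structure (vertex_depth / vertex_normal); "
            "build it through the extrusion pipeline"
        )
    d = mesh.vertex_depth[mesh.tets].mean(axis=1)
    n = mesh.vertex_normal[mesh.tets].mean(axis=1)
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    return d, n


def template_field(
    mesh: VolumeMesh, theta_endo: float = -60.0, theta_epi: float = 60.0
) -> FiberField:
    """Rule-based transmural fiber rotation.

    At transmural depth d ∈ [0, 1] the in-plane fiber angle is
    θ(d) = θ_endo + d (θ_epi − θ_endo) degrees, measured in the tangent plane
    from the projection of global +x (fallback +y where the wall is parallel
    to x). The sheet axis completes a right-handed triad with the transmural
    normal.
    """
    depth, n = _element_depth_and_normal(mesh)
    theta = np.radians(theta_endo + depth * (theta_epi - theta_endo))
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(n), 1))
    proj = ref - np.einsum("ij,ij->i", ref, n)[:, None] * n
    bad = np.linalg.norm(proj, axis=1) < 1e-6
    if np.any(bad):
        alt = np.tile(np.array([0.0, 1.0, 0.0]), (int(bad.sum()), 1))
        proj[bad] = alt - np.einsum("ij,ij->i", alt, n[bad])[:, None] * n[bad]
    e1 = proj / np.linalg.norm(proj, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    f = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
    s = np.cross(n, f)
    field = FiberField(f=f, s=s, n=n)
    field.validate(tol=1e-8)
    return field


def map_fibers(
    template_mesh: VolumeMesh, template_field_: FiberField, target_mesh: VolumeMesh
) -> FiberField:
    """Map a template fiber field onto a target mesh.

    The template is aligned to the target by centroid translation plus
    per-axis bounding-box scaling; each target element then takes the triad
    of the nearest aligned template element, re-orthonormalized.
    """
    tc = template_mesh.centroids()
    gc = target_mesh.centroids()
    t_ext = tc.max(axis=0) - tc.min(axis=0)
    g_ext = gc.max(axis=0) - gc.min(axis=0)
    if np.any(t_ext < 1e-12) or np.any(g_ext < 1e-12):
        raise ValueError("degenerate bounding box: zero extent on an axis")
    scale = g_ext / t_ext
    aligned = (tc - tc.mean(axis=0)) * scale + gc.mean(axis=0)
    _, idx = cKDTree(aligned).query(gc)
    f = template_field_.f[idx].copy()
    s = template_field_.s[idx].copy()
    # re-orthonormalize (Gram–Schmidt; n from the right-hand rule)
    f = f / np.linalg.norm(f, axis=1, keepdims=True)
    s = s - np.einsum("ij,ij->i", s, f)[:, None] * f
    s = s / np.linalg.norm(s, axis=1, keepdims=True)
    n = np.cross(f, s)
    field = FiberField(f=f, s=s, n=n)
    field.validate(tol=1e-8)
    return field


def conductivity_tensor(field: FiberField, sigma: ConductivitySet) -> np.ndarray:
    """Per-element 3×3 monodomain tensors σ_l f⊗f + σ_t (I − f⊗f), mS/cm.

    Sheet and sheet-normal directions share σ_t, so the transversely
    isotropic two-parameter form is exact.
    """
    f = field.f
    ff = np.einsum("ei,ej->eij", f, f)
    eye = np.eye(3)[None, :, :]
    return sigma.sigma_l * ff + sigma.sigma_t * (eye - ff)


def measure_cv(
    node_positions_mm: np.ndarray,
    lat_ms: np.ndarray,
    start_set: np.ndarray,
    end_set: np.ndarray,
) -> CVMeasurement:
    """Macroscopic conduction velocity from a node LAT field.

    CV = distance between the start- and end-set centroids (converted to cm)
    divided by the difference of the sets' mean LATs, in cm/s.
    """
    lat_ms = np.asarray(lat_ms, dtype=float)
    start_set = np.asarray(start_set, dtype=np.int64)
    end_set = np.asarray(end_set, dtype=np.int64)
    if len(start_set) == 0 or len(end_set) == 0:
        raise ValueError("empty start or end set")
    if not np.all(np.isfinite(lat_ms[start_set])) or not np.all(
        np.isfinite(lat_ms[end_set])
    ):
        raise ValueError("non-finite LAT in start/end set (unreached nodes)")
    p0 = node_positions_mm[start_set].mean(axis=0)
    p1 = node_positions_mm[end_set].mean(axis=0)
    dist_cm = np.linalg.norm(p1 - p0) / 10.0
    t0 = float(lat_ms[start_set].mean())
    t1 = float(lat_ms[end_set].mean())
    if t1 <= t0:
        raise ValueError("end-set LAT must exceed start-set LAT")
    if dist_cm <= 0:
        raise ValueError("start and end sets coincide")
    cv = dist_cm / ((t1 - t0) / 1000.0)
    return CVMeasurement(
        cv=cv,
        start_points=node_positions_mm[start_set],
        end_points=node_positions_mm[end_set],
        lat_start=t0,
        lat_end=t1,
    )


def calibrate_conductivity(
    run_cv,
    sigma: ConductivitySet,
    cv_target: float,
    rel_tol: float = 0.03,
    max_iter: int = 8,
) -> ConductivitySet:
    """Scale all four bidomain conductivities by a common factor K until the
    simulated CV matches ``cv_target``.

    ``run_cv`` is a callable mapping a ConductivitySet to a simulated CV in
    cm/s (typically a slab simulation + :func:`measure_cv`). The update uses
    K ← K (cv_target / CV)², the inverse of CV ∝ √σ; convergence is judged on
    the simulated CV only, so the final answer does not depend on the update
    rule being exact.
    """
    if cv_target <= 0:
        raise ValueError("cv_target must be positive")
    current = sigma
    for _ in range(max_iter):
        cv = run_cv(current)
        if cv <= 0:
            raise RuntimeError("simulation produced non-positive CV")
        if abs(cv - cv_target) / cv_target <= rel_tol:
            return current
        current = current.scaled(current.K * (cv_target / cv) ** 2)
    raise RuntimeError(
        f"conductivity calibration did not converge in {max_iter} iterations "
        f"(last CV {cv:.1f} cm/s vs target {cv_target:.1f} cm/s)"
    )
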