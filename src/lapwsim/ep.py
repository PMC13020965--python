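"""Monodomain reaction–diffusion solver on tagged tetrahedral meshes.

Solves χ(Cm ∂Vm/∂t + Iion + Istim) = ∇·σ∇Vm with linear (P1) tetrahedral
finite elements, row-sum mass lumping, and operator splitting: a Rush–Larsen
/ forward-Euler ionic step followed by an explicit diffusion step. No-flux
boundary conditions are natural (every stiffness row sums to zero).

Internal solver units are cm / ms / mV / mS/cm / μF/cm²; mesh coordinates
(mm) are converted on entry so the standard parameter values (Cm = 1 μF/cm²,
χ = 1500 cm⁻¹, stimulus 25 pA/pF for 2.5 ms) close dimensionally — in these
units pA/pF and μA/cm² coincide and dVm/dt comes out in mV/ms.

Fibrotic (subdomain-2) elements are skipped during assembly; nodes belonging
only to fibrotic elements carry no state and are reported as inactive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from . import courtemanche
from .geometry import CONDUCTIVE, VolumeMesh

__all__ = [
    "StimulusProtocol",
    "SimulationConfig",
    "SimulationResult",
    "assemble",
    "select_stimulus_nodes",
    "simulate",
    "stability_limit",
]

MM_PER_CM = 10.0


@dataclass
class StimulusProtocol:
    """Cube-region stimulus: all active nodes inside [box_min, box_max] (mm)
    receive ``amplitude`` pA/pF (depolarizing) for ``duration`` ms starting
    at ``start`` ms. ``nodes`` (mesh node indices) overrides the box when
    given, e.g. from :func:`select_stimulus_nodes`."""

    box_min: tuple[float, float, float] | None = None
    box_max: tuple[float, float, float] | None = None
    amplitude: float = 25.0
    duration: float = 2.5
    start: float = 0.0
    nodes: np.ndarray | None = None

    def __post_init__(self):
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("stimulus amplitude and duration must be positive")
        if self.nodes is None:
            if self.box_min is None or self.box_max is None:
                raise ValueError("stimulus needs a box or an explicit node set")
            if np.any(np.asarray(self.box_max) <= np.asarray(self.box_min)):
                raise ValueError("stimulus box is empty")


@dataclass
class SimulationConfig:
    """Monodomain constants and run control.

    Cm in μF/cm² (1), chi in cm⁻¹ (1500), dt in ms (0.01 desk default,
    configurable down to 0.001), duration in ms (140 matches the clinical
    recording window), output_rate in Hz (1000 = clinical sampling).
    """

    Cm: float = 1.0
    chi: float = 1500.0
    dt: float = 0.01
    duration: float = 140.0
    output_rate: float = 1000.0
    stimuli: list[StimulusProtocol] = field(default_factory=list)

    def __post_init__(self):
        if self.dt <= 0 or self.duration <= 0 or self.output_rate <= 0:
            raise ValueError("dt, duration and output_rate must be positive")
        if self.Cm <= 0 or self.chi <= 0:
            raise ValueError("Cm and chi must be positive")


@dataclass
class SimulationResult:
    """Recorded state of a monodomain run, restricted to active nodes."""

    times: np.ndarray  # output sample times, ms
    vm: np.ndarray  # (n_out, n_active) mV
    im: np.ndarray  # (n_out, n_active) μA/cm² membrane current density
    lat: np.ndarray  # (n_mesh_nodes,) ms; NaN = inactive, inf = unreached
    active_nodes: np.ndarray  # mesh node indices of the active set
    node_positions_mm: np.ndarray  # (n_mesh_nodes, 3)
    node_volumes_cm3: np.ndarray  # (n_active,) lumped nodal volumes
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore

    @property
    def active_lat(self) -> np.ndarray:
        return self.lat[self.active_nodes]


def assemble(mesh: VolumeMesh, tensors: np.ndarray, config: SimulationConfig):
    """Lumped mass vector (cm³) and stiffness matrix (mS) over conductive
    elements, in the compact active-node numbering.

    Returns (mass, stiffness, active_nodes). The stiffness is symmetric with
    zero row sums (constant fields are in the null space ⇔ no-flux), and the
    lumped masses sum to the total conductive volume.
    """
    active_el = np.flatnonzero(mesh.element_subdomain == CONDUCTIVE)
    if len(active_el) == 0:
        raise ValueError("no conductive elements")
    tets = mesh.tets[active_el]
    active_nodes = np.unique(tets)
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[active_nodes] = np.arange(len(active_nodes))
    tets_c = remap[tets]
    verts_cm = mesh.vertices[active_nodes] / MM_PER_CM

    n = len(active_nodes)
    mass = np.zeros(n)
    rows, cols, vals = [], [], []
    coords = verts_cm[tets_c]  # (E, 4, 3)
    # P1 gradients: rows of the inverse Jacobian extension
    d1 = coords[:, 1] - coords[:, 0]
    d2 = coords[:, 2] - coords[:, 0]
    d3 = coords[:, 3] - coords[:, 0]
    vol = np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0
    if np.any(vol <= 0):
        raise ValueError("element with non-positive volume")
    J = np.stack([d1, d2, d3], axis=1)  # (E, 3, 3)
    Jinv = np.linalg.inv(J)
    grads = np.empty((len(tets_c), 4, 3))
    grads[:, 1:, :] = np.transpose(Jinv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    sig = tensors[active_el]  # (E, 3, 3) mS/cm
    # K_local[e, a, b] = vol_e * grad_a · σ_e · grad_b
    local = np.einsum("e,eai,eij,ebj->eab", vol, grads, sig, grads)
    for a in range(4):
        np.add.at(mass, tets_c[:, a], vol / 4.0)
        for b in range(4):
            rows.append(tets_c[:, a])
            cols.append(tets_c[:, b])
            vals.append(local[:, a, b])
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return mass, K, active_nodes


def stability_limit(mesh: VolumeMesh, tensors: np.ndarray, config: SimulationConfig):
    """Explicit-diffusion time-step bound 0.9 · h²min · χ Cm / (6 σmax), ms."""
    active_el = mesh.element_subdomain == CONDUCTIVE
    t = mesh.tets[active_el]
    v = mesh.vertices / MM_PER_CM
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    hmin = min(
        float(np.min(np.linalg.norm(v[t[:, a]] - v[t[:, b]], axis=1))) for a, b in pairs
    )
    sigma_max = float(np.max(np.linalg.eigvalsh(tensors[active_el])))
    return 0.9 * hmin * hmin * config.chi * config.Cm / (6.0 * sigma_max)


def select_stimulus_nodes(
    mesh: VolumeMesh,
    electrodes: np.ndarray,
    lats_ms: np.ndarray,
    window: float = 2.0,
    box: tuple | None = None,
) -> np.ndarray:
    """Stimulus node set from electrode LATs.

    Electrodes within ``window`` ms of the earliest LAT are eligible; the
    mesh nodes nearest to each eligible electrode — plus every node within
    one mean edge length of those, to guarantee the stimulus is captured —
    are selected, optionally restricted to a bounding box (mm).
    """
    lats_ms = np.asarray(lats_ms, dtype=float)
    finite = np.isfinite(lats_ms)
    if not np.any(finite):
        raise ValueError("no electrode with finite LAT")
    eligible = np.flatnonzero(finite & (lats_ms <= np.min(lats_ms[finite]) + window))
    tree = cKDTree(mesh.vertices)
    _, seeds = tree.query(np.atleast_2d(electrodes)[eligible])
    mean_edge = float(np.mean(mesh.edge_lengths()))
    groups = tree.query_ball_point(mesh.vertices[np.atleast_1d(seeds)], r=mean_edge)
    nodes = set(np.atleast_1d(seeds).tolist())
    for g in groups:
        nodes.update(g)
    selected = np.array(sorted(nodes), dtype=np.int64)
    if box is not None:
        lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
        v = mesh.vertices[selected]
        inside = np.all((v >= lo) & (v <= hi), axis=1)
        selected = selected[inside]
    if len(selected) == 0:
        raise ValueError("stimulus selection is empty (box excludes all candidates)")
    return selected


def simulate(
    mesh: VolumeMesh,
    tensors: np.ndarray,
    config: SimulationConfig,
    disable_ionic: bool = False,
    initial_vm: np.ndarray | None = None,
) -> SimulationResult:
    """Run the operator-split explicit monodomain simulation.

    Per step: ionic update (Rush–Larsen gates, Euler Vm/concentrations with
    the stimulus current), then explicit diffusion with the lumped mass.
    The per-node LAT is the time of the most negative dVm/dt (tracked online
    at solver resolution); nodes never leaving rest get LAT = ∞ with a
    warning. The membrane current density Im = (∇·σ∇Vm)/χ is recorded at the
    output rate for the electrogram forward model.

    ``disable_ionic`` freezes the reaction term (pure-diffusion runs for
    conservation checks); ``initial_vm`` overrides the resting Vm (mV).
    """
    mass, K, active_nodes = assemble(mesh, tensors, config)
    dt_max = stability_limit(mesh, tensors, config)
    if config.dt > dt_max:
        raise ValueError(
            f"dt {config.dt} ms exceeds the explicit stability bound {dt_max:.4g} ms"
        )
    n = len(active_nodes)
    states = np.tile(courtemanche.initial_state(), (n, 1))
    if initial_vm is not None:
        states[:, courtemanche.IV] = initial_vm
    verts = mesh.vertices
    # stimulus node masks in compact numbering
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[active_nodes] = np.arange(n)
    stim_masks = []
    for stim in config.stimuli:
        if stim.nodes is not None:
            idx = remap[np.asarray(stim.nodes, dtype=np.int64)]
            idx = idx[idx >= 0]
        else:
            lo = np.asarray(stim.box_min, float)
            hi = np.asarray(stim.box_max, float)
            v = verts[active_nodes]
            idx = np.flatnonzero(np.all((v >= lo) & (v <= hi), axis=1))
        if len(idx) == 0:
            raise ValueError(
                "stimulus region contains no active node (fibrosis may have "
                "disconnected it)"
            )
        stim_masks.append(idx)

    n_steps = int(round(config.duration / config.dt))
    out_every = max(1, int(round(1000.0 / (config.output_rate * config.dt))))
    n_out = n_steps // out_every + 1
    vm_hist = np.empty((n_out, n))
    im_hist = np.empty((n_out, n))
    times = np.empty(n_out)
    inv_chi_cm_mass = 1.0 / (config.chi * config.Cm * mass)
    inv_chi_mass = 1.0 / (config.chi * mass)

    lat = np.full(len(verts), np.nan)
    min_dvdt = np.zeros(n)
    lat_time = np.full(n, np.inf)
    istim = np.zeros(n)
    k_out = 0
    for step in range(n_steps + 1):
        t = step * config.dt
        V = states[:, courtemanche.IV]
        KV = K.dot(V)
        if step % out_every == 0 and k_out < n_out:
            times[k_out] = t
            vm_hist[k_out] = V
            im_hist[k_out] = -KV * inv_chi_mass  # μA/cm²
            k_out += 1
        if step == n_steps:
            break
        istim[:] = 0.0
        for stim, idx in zip(config.stimuli, stim_masks):
            if stim.start <= t < stim.start + stim.duration:
                istim[idx] += stim.amplitude
        v_before = V.copy()
        if disable_ionic:
            states[:, courtemanche.IV] += config.dt * istim / config.Cm
        else:
            courtemanche.step_nodes(states, config.dt, istim)
        states[:, courtemanche.IV] -= config.dt * KV * inv_chi_cm_mass
        dvdt = (states[:, courtemanche.IV] - v_before) / config.dt
        upd = dvdt < min_dvdt
        min_dvdt[upd] = dvdt[upd]
        lat_time[upd] = t
        if step % 200 == 0 and not np.all(np.isfinite(states[:, courtemanche.IV])):
            raise RuntimeError(
                f"simulation blew up at step {step} (t = {t:.3f} ms); "
                f"max |Vm| = {np.nanmax(np.abs(states[:, courtemanche.IV])):.3g}"
            )
    vm_max = vm_hist.max(axis=0)
    reached = vm_max > -40.0  # a node that never depolarized has no LAT
    if not disable_ionic and not np.all(reached):
        warnings.warn(
            f"{int(np.sum(~reached))} active nodes were never activated "
            "(LAT = inf)",
            stacklevel=2,
        )
    node_lat = np.where(reached, lat_time, np.inf)
    lat[active_nodes] = node_lat
    return SimulationResult(
        times=times,
        vm=vm_hist,
        im=im_hist,
        lat=lat,
        active_nodes=active_nodes,
        node_positions_mm=verts,
        node_volumes_cm3=mass,
        config=config,
    )
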