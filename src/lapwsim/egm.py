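"""Forward unipolar electrograms from membrane current sources.

A virtual electrode in the (infinite, homogeneous) blood pool sees the
superposition of all tissue membrane-current sources:

    φe(x, t) = 1/(4π σb) ∫ χ Im(x', t) / ‖x − x'‖ dx'

discretized by nodal lumping, which matches the lumped-mass FEM and keeps
the single-point-source case exact. With Im in μA/cm², node volumes in cm³,
distances in cm and σb in mS/cm, φe comes out in mV.

Raw traces are computed at the solver output rate and then post-processed to
the clinical convention: zero-phase 2–220 Hz band-pass and 1 kHz sampling.
(Clinical hardware in the source data band-passed at 2–240 Hz; both edges
are configurable and a mismatch is logged, not silently reconciled.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ep import MM_PER_CM, SimulationResult

__all__ = ["EGMTrace", "forward_egm", "forward_egm_set", "postprocess"]

logger = logging.getLogger(__name__)

MIN_ELECTRODE_DISTANCE_MM = 0.1  # electrodes must sit off-tissue


@dataclass
class EGMTrace:
    """A unipolar electrogram: uniform time base (ms) and φe (mV)."""

    time: np.ndarray
    phi_e: np.ndarray
    electrode_position: np.ndarray  # mm
    provenance: str = "simulated"  # or "recorded"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.phi_e = np.asarray(self.phi_e, dtype=float)
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]):
            raise ValueError("trace time base must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.phi_e)):
            raise ValueError("non-finite trace values")

    @property
    def sample_rate(self) -> float:
        return 1000.0 / (self.time[1] - self.time[0])


def _electrode_weights(result: SimulationResult, chi, sigma_b, electrode_mm):
    pos_cm = result.node_positions_mm[result.active_nodes] / MM_PER_CM
    elec_cm = np.asarray(electrode_mm, dtype=float) / MM_PER_CM
    r = np.linalg.norm(pos_cm - elec_cm, axis=1)
    if np.min(r) * MM_PER_CM < MIN_ELECTRODE_DISTANCE_MM:
        raise ValueError(
            f"electrode {np.asarray(electrode_mm)} lies inside or within "
            f"{MIN_ELECTRODE_DISTANCE_MM} mm of the tissue: invalid virtual "
            "electrode placement"
        )
    return chi * result.node_volumes_cm3 / (4.0 * np.pi * sigma_b * r)


def forward_egm(
    result: SimulationResult,
    electrode_mm,
    sigma_b: float = 6.67,
    chi: float | None = None,
) -> EGMTrace:
    """Raw φe(t) at one virtual electrode (mV, at the solver output rate)."""
    chi = result.config.chi if chi is None else chi
    w = _electrode_weights(result, chi, sigma_b, electrode_mm)
    phi = result.im @ w
    return EGMTrace(result.times, phi, np.asarray(electrode_mm, dtype=float))


def forward_egm_set(
    result: SimulationResult, electrodes_mm, sigma_b: float = 6.67
) -> list[EGMTrace]:
    """Raw traces at many electrodes (shared Im history, one pass)."""
    electrodes_mm = np.atleast_2d(np.asarray(electrodes_mm, dtype=float))
    W = np.column_stack(
        [
            _electrode_weights(result, result.config.chi, sigma_b, e)
            for e in electrodes_mm
        ]
    )
    phi = result.im @ W  # (n_out, n_electrodes)
    return [
        EGMTrace(result.times, phi[:, k], electrodes_mm[k])
        for k in range(len(electrodes_mm))
    ]


def postprocess(
    trace: EGMTrace,
    fs_out: float = 1000.0,
    band: tuple[float, float] = (2.0, 220.0),
) -> EGMTrace:
    """Clinical post-processing: zero-phase band-pass then resample.

    Forward–backward (zero-phase) 2nd-order Butterworth band-pass at
    ``band`` Hz, then polyphase resampling to ``fs_out`` (anti-aliasing is
    inherent in the polyphase filter). Input must be sampled at ≥ 2× the
    upper band edge.
    """
    fs_in = trace.sample_rate
    if fs_in < 2.0 * band[1]:
        raise ValueError(
            f"input sample rate {fs_in:.0f} Hz below 2x band edge {band[1]:.0f} Hz"
        )
    if band != (2.0, 220.0):
        logger.info("non-default electrogram band %s Hz", band)
    sos = signal.butter(2, band, btype="bandpass", fs=fs_in, output="sos")
    padlen = 3 * 2 * 2 * 3  # 3 x filter length (2 biquads)
    if len(trace.phi_e) <= padlen:
        raise ValueError("trace shorter than the filter warm-up length")
    filtered = signal.sosfiltfilt(sos, trace.phi_e)
    if abs(fs_in - fs_out) < 1e-9:
        out = filtered
        time = trace.time.copy()
    else:
        from fractions import Fraction

        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        out = signal.resample_poly(filtered, frac.numerator, frac.denominator)
        time = trace.time[0] + np.arange(len(out)) * (1000.0 / fs_out)
    return EGMTrace(time, out, trace.electrode_position, trace.provenance)
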