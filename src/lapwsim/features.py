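"""Electrogram characterization: the eight characteristic parameters + LAT.

Applies equally to recorded and simulated traces (post-processed to a
uniform 1 kHz base). The characteristic parameters:

- downstroke: most negative derivative (mV/ms),
- rising upstroke: largest derivative before the downstroke,
- recovery upstroke: largest derivative after the downstroke,
- signal width: |t(global max) − t(global min)| (ms),
- EGM duration: span of supra-threshold activity around the baseline (ms),
- baseline: mean potential away from activity (mV),
- peak-to-peak amplitude (mV),
- deflection count: local extrema with prominence ≥ 10% of peak-to-peak.

LAT follows the minimum-derivative convention: the time of the steepest
negative slope. Applied to transmembrane traces this lands a few ms after
the upstroke (phase-1 repolarization) with a spatially constant offset, so
activation sequences and conduction velocities are unaffected; for unipolar
electrograms it is the standard intrinsic deflection marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .egm import EGMTrace

__all__ = ["EGMFeatures", "detect_lat", "characterize", "count_deflections"]


@dataclass
class EGMFeatures:
    downstroke: float  # mV/ms
    rising_upstroke: float  # mV/ms
    recovery_upstroke: float  # mV/ms
    signal_width: float  # ms
    egm_duration: float  # ms
    baseline: float  # mV
    peak_to_peak: float  # mV
    deflection_count: int
    lat: float  # ms

    FIELD_ORDER = (
        "downstroke",
        "rising_upstroke",
        "recovery_upstroke",
        "signal_width",
        "egm_duration",
        "baseline",
        "peak_to_peak",
        "deflection_count",
        "lat",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELD_ORDER], dtype=float)


def _derivative(trace: EGMTrace) -> np.ndarray:
    return np.gradient(trace.phi_e, trace.time)  # central differences, mV/ms


def detect_lat(trace: EGMTrace) -> float:
    """Time of the minimum derivative; ties broken toward the earliest time."""
    if len(trace.phi_e) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(trace.phi_e) == 0:
        raise ValueError("constant trace has no defined minimum slope")
    d = _derivative(trace)
    return float(trace.time[int(np.argmin(d))])


def _baseline(trace: EGMTrace, head_tail_ms: float = 10.0):
    """Mean of the first and last ``head_tail_ms`` unless activity overlaps
    them, in which case the median of the whole trace (robust to the active
    complex) is used. Returns (baseline, baseline_segment_sd)."""
    t = trace.time
    x = trace.phi_e
    edge = (t <= t[0] + head_tail_ms) | (t >= t[-1] - head_tail_ms)
    seg = x[edge]
    p2p = np.ptp(x)
    if p2p > 0 and np.ptp(seg) > 0.5 * p2p:  # activity reaches the edges
        return float(np.median(x)), float(np.std(seg))
    return float(np.mean(seg)), float(np.std(seg))


def _active_window(trace: EGMTrace, baseline: float, threshold: float):
    """Contiguous supra-threshold region around the global extremum."""
    x = np.abs(trace.phi_e - baseline)
    center = int(np.argmax(x))
    above = x > threshold
    if not above[center]:
        return center, center
    lo = center
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = center
    while hi < len(x) - 1 and above[hi + 1]:
        hi += 1
    return lo, hi


def count_deflections(trace: EGMTrace, prominence_frac: float = 0.10) -> int:
    """Number of local extrema with prominence ≥ prominence_frac × peak-to-peak."""
    x = trace.phi_e
    p2p = np.ptp(x)
    if p2p == 0:
        return 0
    prom = prominence_frac * p2p
    peaks_up, _ = find_peaks(x, prominence=prom)
    peaks_dn, _ = find_peaks(-x, prominence=prom)
    # endpoints can carry an extremum that find_peaks cannot see; count the
    # global max/min regardless of position
    n = len(peaks_up) + len(peaks_dn)
    if int(np.argmax(x)) in (0, len(x) - 1):
        n += 1
    if int(np.argmin(x)) in (0, len(x) - 1):
        n += 1
    return int(n)


def characterize(trace: EGMTrace, prominence_frac: float = 0.10) -> EGMFeatures:
    """Extract all characteristic parameters and the LAT from one trace."""
    if len(trace.phi_e) < 3:
        raise ValueError("need at least 3 samples")
    x = trace.phi_e
    t = trace.time
    if np.ptp(x) == 0:
        raise ValueError("constant trace cannot be characterized")
    d = _derivative(trace)
    i_dn = int(np.argmin(d))
    downstroke = float(d[i_dn])
    rising = float(np.max(d[: i_dn + 1]))
    recovery = float(np.max(d[i_dn:]))
    i_max, i_min = int(np.argmax(x)), int(np.argmin(x))
    signal_width = float(abs(t[i_max] - t[i_min]))
    baseline, base_sd = _baseline(trace)
    p2p = float(np.ptp(x))
    threshold = max(0.05 * p2p, 3.0 * base_sd)
    lo, hi = _active_window(trace, baseline, threshold)
    # duration spans all supra-threshold activity (fractionated tails included)
    above = np.flatnonzero(np.abs(x - baseline) > threshold)
    if len(above):
        duration = float(t[above[-1]] - t[above[0]])
    else:
        duration = float(t[hi] - t[lo])
    duration = max(duration, signal_width)
    return EGMFeatures(
        downstroke=downstroke,
        rising_upstroke=rising,
        recovery_upstroke=recovery,
        signal_width=signal_width,
        egm_duration=duration,
        baseline=baseline,
        peak_to_peak=p2p,
        deflection_count=count_deflections(trace, prominence_frac),
        lat=float(t[i_dn]),
    )
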