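"""Recorded-vs-simulated electrogram statistics.

Implements the full comparison battery: Cohen's d effect sizes on the
characteristic parameters (pooled-SD form), per-pair percent errors,
correlation/cross-correlation of trace pairs, the wavelet → PCA → k-means
morphology analysis (biorthogonal detail coefficients, recorded-set PCA
basis, cluster-centroid distances), and LAT isochrone maps projected onto
the wall surface points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as _signal
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .egm import EGMTrace

__all__ = [
    "GroupSummary",
    "PCAEmbedding",
    "ComparisonReport",
    "cohens_d",
    "effect_size_band",
    "error_metrics",
    "correlation_metrics",
    "normalize_trace",
    "wavelet_detail_coeffs",
    "pca_embed",
    "project",
    "kmeans_cluster",
    "centroid_distances",
    "isochrone_map",
    "anova_tukey",
    "compare_sets",
]


@dataclass
class GroupSummary:
    """Per-group summary entering the pooled effect size: mean, SD, count."""

    M: float
    SD: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.SD < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(M=float(values.mean()), SD=float(values.std(ddof=1)), n=len(values))


def cohens_d(recorded: GroupSummary, simulated: GroupSummary):
    """|d| = |M_rec − M_sim| / SD_pooled with the (n−1)-weighted pooled SD.

    Returns (|d|, band) where band classifies the effect size by the 0.2 /
    0.5 / 0.8 thresholds. The magnitude is reported (signed d is simply
    (M_rec − M_sim)/SD_pooled if needed).
    """
    n1, n2 = recorded.n, simulated.n
    if n1 + n2 <= 2:
        raise ValueError("need n_recorded + n_simulated > 2")
    sd_pooled = np.sqrt(
        ((n1 - 1) * recorded.SD**2 + (n2 - 1) * simulated.SD**2) / (n1 + n2 - 2)
    )
    if sd_pooled == 0:
        raise ValueError("zero pooled SD")
    d = abs(recorded.M - simulated.M) / sd_pooled
    return float(d), effect_size_band(d)


def effect_size_band(d: float) -> str:
    d = abs(d)
    if d < 0.2:
        return "negligible"
    if d < 0.5:
        return "small"
    if d < 0.8:
        return "medium"
    return "large"


def error_metrics(recorded: np.ndarray, simulated: np.ndarray):
    """Per-pair absolute percent errors 100·|sim − rec|/|rec|.

    Returns (mean, sd, n_excluded) where pairs with rec = 0 are excluded
    from the statistics and counted.
    """
    rec = np.asarray(recorded, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if rec.shape != sim.shape:
        raise ValueError("recorded/simulated must pair one-to-one")
    valid = rec != 0
    if not np.any(valid):
        raise ValueError("no valid pairs (all recorded values are zero)")
    err = 100.0 * np.abs(sim[valid] - rec[valid]) / np.abs(rec[valid])
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    return float(err.mean()), sd, int(np.sum(~valid))


def normalize_trace(x: np.ndarray) -> np.ndarray:
    """Baseline-removed, unit peak-to-peak amplitude (morphology only)."""
    x = np.asarray(x, dtype=float)
    x = x - np.median(x)
    p2p = np.ptp(x)
    if p2p == 0:
        raise ValueError("zero-variance trace cannot be normalized")
    return x / p2p


def correlation_metrics(rec: EGMTrace | np.ndarray, sim: EGMTrace | np.ndarray):
    """(Pearson r on the original traces, max normalized cross-correlation
    over lags on the amplitude-normalized traces)."""
    xr = rec.phi_e if isinstance(rec, EGMTrace) else np.asarray(rec, float)
    xs = sim.phi_e if isinstance(sim, EGMTrace) else np.asarray(sim, float)
    if len(xr) != len(xs):
        raise ValueError("traces must have equal length (resample first)")
    if np.std(xr) == 0 or np.std(xs) == 0:
        raise ValueError("zero-variance trace")
    r = float(np.corrcoef(xr, xs)[0, 1])
    a = normalize_trace(xr) - np.mean(normalize_trace(xr))
    b = normalize_trace(xs) - np.mean(normalize_trace(xs))
    cc = _signal.correlate(a, b, mode="full")
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    return r, float(np.max(cc) / denom)


def wavelet_detail_coeffs(
    normalized_trace: np.ndarray, level: int = 4, wavelet: str = "bior4.4"
) -> np.ndarray:
    """Concatenated detail coefficients of a level-``level`` biorthogonal
    wavelet decomposition (approximation coefficients excluded)."""
    x = np.asarray(normalized_trace, dtype=float)
    if len(x) < pywt.Wavelet(wavelet).dec_len * 2:
        raise ValueError("trace too short for the requested decomposition level")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    return np.concatenate(coeffs[1:])  # cD_level ... cD_1


@dataclass
class PCAEmbedding:
    components: np.ndarray  # (k, p) orthonormal rows
    mean: np.ndarray  # (p,)
    explained_variance_ratio: np.ndarray  # all components
    n_retained: int
    scores: np.ndarray = field(repr=False, default=None)  # type: ignore


def pca_embed(coeff_matrix: np.ndarray, variance_target: float = 0.90) -> PCAEmbedding:
    """PCA of the recorded coefficient matrix; retains the smallest number of
    components whose cumulative explained variance reaches the target."""
    X = np.asarray(coeff_matrix, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least 2 waveforms")
    p = PCA(n_components=min(X.shape), svd_solver="full")
    scores_all = p.fit_transform(X)
    cum = np.cumsum(p.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, len(cum))
    return PCAEmbedding(
        components=p.components_[:k],
        mean=p.mean_,
        explained_variance_ratio=p.explained_variance_ratio_,
        n_retained=k,
        scores=scores_all[:, :k],
    )


def project(coeff_matrix: np.ndarray, embedding: PCAEmbedding) -> np.ndarray:
    """Project waveforms into an existing recorded-set PC space."""
    X = np.atleast_2d(np.asarray(coeff_matrix, dtype=float))
    if X.shape[1] != embedding.mean.shape[0]:
        raise ValueError("coefficient dimension mismatch with the embedding")
    return (X - embedding.mean) @ embedding.components.T


def kmeans_cluster(scores: np.ndarray, k: int = 3, seed: int = 0):
    """Seeded k-means++ / Lloyd clustering in PC space."""
    X = np.asarray(scores, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError("k exceeds the number of waveforms")
    km = KMeans(n_clusters=k, n_init=1, init="k-means++", random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def centroid_distances(
    sim_scores: np.ndarray, rec_labels: np.ndarray, centroids: np.ndarray
):
    """Distance statistics of simulated waveforms in the recorded PC space.

    Pairing is positional: row i of ``sim_scores`` corresponds to the
    recorded waveform with label ``rec_labels[i]`` (same electrode). Returns
    (mean distance to the common centroid, mean distance to the closest
    centroid, percent of pairs whose closest centroid differs).
    """
    S = np.atleast_2d(np.asarray(sim_scores, dtype=float))
    labels = np.asarray(rec_labels, dtype=int)
    if len(S) == 0 or len(labels) != len(S):
        raise ValueError("empty or mismatched sim/rec pairing")
    d_all = np.linalg.norm(S[:, None, :] - centroids[None, :, :], axis=2)
    common = d_all[np.arange(len(S)), labels]
    closest_idx = np.argmin(d_all, axis=1)
    closest = d_all[np.arange(len(S)), closest_idx]
    pct_diff = 100.0 * float(np.mean(closest_idx != labels))
    return float(common.mean()), float(closest.mean()), pct_diff


def isochrone_map(
    surface_points: np.ndarray,
    electrode_positions: np.ndarray,
    lats: np.ndarray,
    n_bins: int = 8,
    bin_range: tuple[float, float] | None = None,
):
    """Project electrode LATs onto wall surface points by proximity.

    Each surface point takes the LAT of its nearest electrode (exact-tie
    break: the lower electrode index). Bins are ``n_bins`` equal-width
    intervals over ``bin_range`` — pass the recorded set's (min, max) so the
    recorded and simulated maps of a patient share color ranges. Returns
    (per-point LAT, per-point bin index, bin_edges).
    """
    lats = np.asarray(lats, dtype=float)
    finite = np.isfinite(lats)
    if not np.any(finite):
        raise ValueError("no finite electrode LATs")
    elec = np.atleast_2d(np.asarray(electrode_positions, dtype=float))[finite]
    lat_f = lats[finite]
    pts = np.atleast_2d(np.asarray(surface_points, dtype=float))
    if len(pts) * len(elec) <= 5_000_000:
        # full distance matrix + argmin: first occurrence wins, which gives
        # the documented lower-electrode-index tie-break
        dmat = np.linalg.norm(pts[:, None, :] - elec[None, :, :], axis=2)
        idx = np.argmin(dmat, axis=1)
    else:
        _, idx = cKDTree(elec).query(pts)
    point_lat = lat_f[idx]
    lo, hi = bin_range if bin_range is not None else (lat_f.min(), lat_f.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.searchsorted(edges, point_lat, side="right") - 1, 0, n_bins - 1)
    return point_lat, bins, edges


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """One-way ANOVA + Tukey HSD over named groups (thin convenience over
    the standard routines, for fibrosis-sweep reporting)."""
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    F, p = f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(a) for k, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    return {"F": float(F), "p": float(p), "tukey": tukey}


@dataclass
class ComparisonReport:
    """Aggregate of all recorded-vs-simulated metrics for one EGM set pair."""

    cohens_d: dict[str, float]
    effect_bands: dict[str, str]
    percent_errors: dict[str, tuple[float, float]]  # feature -> (mean, sd)
    mean_pearson_r: float
    mean_max_xcorr: float
    n_retained_pcs: int
    explained_variance: float
    mean_dist_rec: float
    mean_dist_common: float
    mean_dist_closest: float
    percent_different_centroid: float
    cluster_labels_recorded: np.ndarray = field(repr=False, default=None)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "cohens_d": self.cohens_d,
            "effect_bands": self.effect_bands,
            "percent_errors": {k: list(v) for k, v in self.percent_errors.items()},
            "mean_pearson_r": self.mean_pearson_r,
            "mean_max_xcorr": self.mean_max_xcorr,
            "n_retained_pcs": self.n_retained_pcs,
            "explained_variance": self.explained_variance,
            "mean_dist_rec": self.mean_dist_rec,
            "mean_dist_common": self.mean_dist_common,
            "mean_dist_closest": self.mean_dist_closest,
            "percent_different_centroid": self.percent_different_centroid,
        }


ERROR_FEATURES = ("peak_to_peak", "deflection_count", "egm_duration", "lat")
COHEN_FEATURES = (
    "downstroke",
    "rising_upstroke",
    "recovery_upstroke",
    "signal_width",
    "baseline",
    "egm_duration",
    "peak_to_peak",
    "deflection_count",
)


def compare_sets(
    recorded: list[EGMTrace],
    simulated: list[EGMTrace],
    k_clusters: int = 3,
    seed: int = 0,
    variance_target: float = 0.90,
) -> ComparisonReport:
    """Run the whole comparison battery on paired EGM sets (same electrodes,
    same order)."""
    from .features import characterize

    if len(recorded) != len(simulated) or len(recorded) < 2:
        raise ValueError("need >= 2 paired traces")
    feats_r = [characterize(t) for t in recorded]
    feats_s = [characterize(t) for t in simulated]

    d_vals, bands = {}, {}
    for name in COHEN_FEATURES:
        gr = GroupSummary.from_values([getattr(f, name) for f in feats_r])
        gs = GroupSummary.from_values([getattr(f, name) for f in feats_s])
        try:
            d_vals[name], bands[name] = cohens_d(gr, gs)
        except ValueError:  # zero pooled SD on degenerate synthetic sets
            d_vals[name], bands[name] = 0.0, "negligible"

    perr = {}
    for name in ERROR_FEATURES:
        m, sd, _ = error_metrics(
            [getattr(f, name) for f in feats_r], [getattr(f, name) for f in feats_s]
        )
        perr[name] = (m, sd)

    corr = [correlation_metrics(r, s) for r, s in zip(recorded, simulated)]
    mean_r = float(np.mean([c[0] for c in corr]))
    mean_cc = float(np.mean([c[1] for c in corr]))

    Xr = np.array([wavelet_detail_coeffs(normalize_trace(t.phi_e)) for t in recorded])
    Xs = np.array([wavelet_detail_coeffs(normalize_trace(t.phi_e)) for t in simulated])
    emb = pca_embed(Xr, variance_target=variance_target)
    scores_r = emb.scores
    scores_s = project(Xs, emb)
    k = min(k_clusters, len(scores_r))
    labels, centroids = kmeans_cluster(scores_r, k=k, seed=seed)
    dist_rec = float(
        np.mean(np.linalg.norm(scores_r - centroids[labels], axis=1))
    )
    d_common, d_closest, pct_diff = centroid_distances(scores_s, labels, centroids)
    return ComparisonReport(
        cohens_d=d_vals,
        effect_bands=bands,
        percent_errors=perr,
        mean_pearson_r=mean_r,
        mean_max_xcorr=mean_cc,
        n_retained_pcs=emb.n_retained,
        explained_variance=float(
            np.sum(emb.explained_variance_ratio[: emb.n_retained])
        ),
        mean_dist_rec=dist_rec,
        mean_dist_common=d_common,
        mean_dist_closest=d_closest,
        percent_different_centroid=pct_diff,
        cluster_labels_recorded=labels,
    )
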