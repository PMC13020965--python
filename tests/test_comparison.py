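"""Comparison statistics: effect sizes, errors, correlations, wavelet-PCA-
k-means morphology analysis, and isochrone mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapwsim.comparison import (
    GroupSummary,
    centroid_distances,
    cohens_d,
    compare_sets,
    correlation_metrics,
    error_metrics,
    isochrone_map,
    kmeans_cluster,
    normalize_trace,
    pca_embed,
    project,
    wavelet_detail_coeffs,
)
from lapwsim.egm import EGMTrace
from lapwsim.synthetic_data import biphasic_template


class TestCohensD:
    def test_equal_means_give_zero(self):
        d, band = cohens_d(GroupSummary(1.0, 0.5, 100), GroupSummary(1.0, 2.0, 100))
        assert d == 0.0
        assert band == "negligible"

    def test_band_thresholds(self):
        assert cohens_d(GroupSummary(0.3, 1.0, 50), GroupSummary(0.0, 1.0, 50))[1] == "small"
        assert cohens_d(GroupSummary(0.6, 1.0, 50), GroupSummary(0.0, 1.0, 50))[1] == "medium"
        assert cohens_d(GroupSummary(1.0, 1.0, 50), GroupSummary(0.0, 1.0, 50))[1] == "large"

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(GroupSummary(1.0, 0.0, 10), GroupSummary(2.0, 0.0, 10))

    @settings(max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-100.0, 100.0),
    )
    def test_invariant_under_common_affine_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.7, 1.5, 40)
        d0, _ = cohens_d(GroupSummary.from_values(a), GroupSummary.from_values(b))
        d1, _ = cohens_d(
            GroupSummary.from_values(scale * a + shift),
            GroupSummary.from_values(scale * b + shift),
        )
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestErrorMetrics:
    def test_identical_pairs_zero_error(self):
        m, sd, excl = error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == 0.0 and sd == 0.0 and excl == 0

    def test_simple_arithmetic(self):
        m, _, _ = error_metrics([2.0], [3.0])
        assert m == pytest.approx(50.0)

    def test_constructed_error_distribution(self):
        rec = np.array([10.0, 10.0, 10.0])
        sim = np.array([11.0, 12.0, 13.0])  # 10, 20, 30 % errors
        m, sd, _ = error_metrics(rec, sim)
        assert m == pytest.approx(20.0)
        assert sd == pytest.approx(10.0)

    def test_zero_recorded_excluded_and_counted(self):
        m, _, excl = error_metrics([0.0, 2.0], [1.0, 3.0])
        assert excl == 1
        assert m == pytest.approx(50.0)


class TestCorrelation:
    def trace(self, x):
        return EGMTrace(np.arange(len(x), dtype=float), x, np.zeros(3))

    def test_self_correlation(self):
        x = biphasic_template(np.arange(140.0), 60.0, 5.0)
        r, cc = correlation_metrics(self.trace(x), self.trace(x))
        assert r == pytest.approx(1.0)
        assert cc == pytest.approx(1.0, abs=1e-9)

    def test_delay_hurts_pearson_but_not_xcorr(self):
        t = np.arange(140.0)
        a = biphasic_template(t, 50.0, 5.0)
        b = biphasic_template(t, 70.0, 5.0)
        r, cc = correlation_metrics(self.trace(a), self.trace(b))
        assert r < 0.5
        assert cc == pytest.approx(1.0, abs=1e-6)

    def test_sign_flip_gives_minus_one(self):
        x = biphasic_template(np.arange(140.0), 60.0, 5.0)
        r, _ = correlation_metrics(self.trace(x), self.trace(-x))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_metrics(self.trace(np.zeros(50)), self.trace(np.ones(50)))


class TestWavelet:
    def test_zero_trace_zero_coeffs(self):
        out = wavelet_detail_coeffs(np.zeros(140))
        assert np.allclose(out, 0.0)

    def test_linearity(self):
        x = np.sin(np.linspace(0, 10, 140))
        assert np.allclose(
            wavelet_detail_coeffs(3.0 * x), 3.0 * wavelet_detail_coeffs(x), atol=1e-12
        )

    def test_perfect_reconstruction_bank(self):
        import pywt

        x = biphasic_template(np.arange(140.0), 60.0, 5.0)
        coeffs = pywt.wavedec(x, "bior4.4", level=4, mode="symmetric")
        rec = pywt.waverec(coeffs, "bior4.4", mode="symmetric")[: len(x)]
        assert np.allclose(rec, x, atol=1e-8)

    def test_deterministic_length(self):
        a = wavelet_detail_coeffs(np.random.default_rng(0).normal(size=140))
        b = wavelet_detail_coeffs(np.random.default_rng(1).normal(size=140))
        assert len(a) == len(b)


class TestPCA:
    def test_one_dimensional_data_retains_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        X = np.outer(t, [1.0, 2.0, 3.0]) + 1e-9 * rng.normal(size=(50, 3))
        emb = pca_embed(X, variance_target=0.90)
        assert emb.n_retained == 1

    def test_components_orthonormal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 20))
        emb = pca_embed(X)
        gram = emb.components @ emb.components.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-10)

    def test_total_score_variance_equals_data_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 10))
        emb = pca_embed(X, variance_target=1.0)
        total_data = np.var(X - X.mean(0), axis=0, ddof=1).sum()
        total_scores = np.var(emb.scores, axis=0, ddof=1).sum()
        assert total_scores == pytest.approx(total_data, rel=1e-9)

    def test_project_consistency_with_embedding_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 12))
        emb = pca_embed(X)
        assert np.allclose(project(X, emb), emb.scores, atol=1e-9)

    def test_project_mean_to_origin_and_component_to_unit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 12))
        emb = pca_embed(X)
        assert np.allclose(project(emb.mean[None, :], emb), 0.0, atol=1e-10)
        probe = emb.mean + emb.components[0]
        scores = project(probe[None, :], emb)[0]
        expected = np.zeros(emb.n_retained)
        expected[0] = 1.0
        assert np.allclose(scores, expected, atol=1e-10)

    def test_reconstruction_error_within_variance_budget(self):
        rng = np.random.default_rng(5)
        basis = rng.normal(size=(3, 60))
        X = rng.normal(size=(50, 3)) @ basis + 0.05 * rng.normal(size=(50, 60))
        emb = pca_embed(X, variance_target=0.90)
        Xc = X - emb.mean
        recon = project(X, emb) @ emb.components
        rel = np.linalg.norm(Xc - recon) / np.linalg.norm(Xc)
        assert rel <= np.sqrt(0.10) + 0.05


class TestKMeans:
    def blobs(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.concatenate([c + 0.3 * rng.normal(size=(20, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 20)
        return X, truth

    def test_separated_blobs_recovered(self):
        X, truth = self.blobs()
        labels, _ = kmeans_cluster(X, k=3, seed=0)
        # partition equality up to relabeling
        for c in range(3):
            members = labels[truth == c]
            assert len(np.unique(members)) == 1
        assert len(np.unique(labels)) == 3

    def test_k_equals_n_gives_zero_wcss(self):
        X = np.random.default_rng(1).normal(size=(6, 2))
        labels, centroids = kmeans_cluster(X, k=6, seed=0)
        assert np.allclose(np.sort(centroids, axis=0), np.sort(X, axis=0))

    def test_seed_determinism(self):
        X, _ = self.blobs()
        a, _ = kmeans_cluster(X, k=3, seed=5)
        b, _ = kmeans_cluster(X, k=3, seed=5)
        assert np.array_equal(a, b)

    def test_invalid_k(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=4)


class TestCentroidDistances:
    def test_identical_scores_zero_percent_different(self):
        X, truth = TestKMeans().blobs()
        labels, centroids = kmeans_cluster(X, k=3, seed=0)
        d_common, d_closest, pct = centroid_distances(X, labels, centroids)
        assert d_common == pytest.approx(d_closest)
        assert pct == 0.0

    def test_moved_point_counted_exactly(self):
        X, truth = TestKMeans().blobs()
        labels, centroids = kmeans_cluster(X, k=3, seed=0)
        moved = X.copy()
        other = (labels[0] + 1) % 3
        moved[0] = centroids[other]
        _, _, pct = centroid_distances(moved, labels, centroids)
        assert pct == pytest.approx(100.0 / len(X))

    def test_empty_pairing_rejected(self):
        with pytest.raises(ValueError):
            centroid_distances(np.empty((0, 2)), np.empty(0, dtype=int), np.zeros((3, 2)))


class TestIsochroneMap:
    def test_coincident_point_gets_electrode_lat(self):
        electrodes = np.array([[0.0, 0, 1], [10.0, 0, 1]])
        lats = np.array([5.0, 25.0])
        point_lat, _, _ = isochrone_map(electrodes[:1], electrodes, lats, n_bins=4)
        assert point_lat[0] == 5.0

    def test_equidistant_tie_goes_to_lower_index(self):
        electrodes = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        lats = np.array([3.0, 9.0])
        mid = np.array([[5.0, 0, 0]])
        point_lat, _, _ = isochrone_map(mid, electrodes, lats, n_bins=2)
        assert point_lat[0] == 3.0

    def test_planar_lat_field_gives_parallel_bands(self):
        xs, ys = np.meshgrid(np.linspace(0, 20, 21), np.linspace(0, 20, 21))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
        ex = np.linspace(0, 20, 6)
        electrodes = np.column_stack([ex, 10 * np.ones(6), np.ones(6)])
        lats = ex * 1.5
        _, bins, _ = isochrone_map(pts, electrodes, lats, n_bins=6)
        bins = bins.reshape(xs.shape)
        # bin index depends on x only
        assert np.all(bins == bins[0][None, :])

    def test_no_finite_lats_rejected(self):
        with pytest.raises(ValueError):
            isochrone_map(np.zeros((1, 3)), np.zeros((2, 3)), np.array([np.inf, np.nan]))


class TestEndToEndIdentity:
    def test_set_compared_to_itself_is_perfect(self):
        rng = np.random.default_rng(0)
        t = np.arange(140.0)
        traces = []
        for _ in range(40):
            center = rng.uniform(30, 90)
            width = rng.uniform(3, 8)
            amp = rng.uniform(0.5, 4.0)
            x = amp * biphasic_template(t, center, width)
            x += 0.2 * amp * biphasic_template(t, center + rng.uniform(10, 25), width)
            traces.append(EGMTrace(t, x, np.zeros(3)))
        report = compare_sets(traces, traces, seed=1)
        for mean_err, _sd in report.percent_errors.values():
            assert mean_err == pytest.approx(0.0, abs=1e-9)
        assert report.mean_pearson_r == pytest.approx(1.0)
        assert report.mean_max_xcorr == pytest.approx(1.0, abs=1e-9)
        assert report.percent_different_centroid == 0.0
        assert report.mean_dist_common == pytest.approx(report.mean_dist_closest)
        assert report.explained_variance >= 0.90


def test_normalize_trace_rejects_flat_input():
    with pytest.raises(ValueError):
        normalize_trace(np.full(30, 2.0))
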