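"""Downstream evaluation suite: PCA, smoothing, clustering, IoU, probes."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from plicl.contrastive import FeatureMap
from plicl.downstream import (
    cross_section_iou,
    linear_probe,
    morphology_regression,
    pca_reduce,
    rbf_retrieval,
    smooth_feature_map,
    two_step_cluster,
)


class TestPCA:
    def test_full_rank_cumulative_variance_is_one(self):
        x = np.random.default_rng(0).standard_normal((200, 5))
        _, evr, _ = pca_reduce(x, n_components=5)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(evr) <= 1e-12).all()

    def test_rank_one_data_concentrates_first_component(self):
        rng = np.random.default_rng(1)
        direction = rng.standard_normal(6)
        x = np.outer(rng.standard_normal(100), direction)
        _, evr, _ = pca_reduce(x, n_components=3)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_near_equal_ratios(self):
        x = np.random.default_rng(2).standard_normal((20000, 8))
        _, evr, _ = pca_reduce(x, n_components=8)
        assert evr.max() / evr.min() < 1.2

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((10, 3)), n_components=4)

    def test_subset_fit_is_seeded(self):
        x = np.random.default_rng(3).standard_normal((5000, 4))
        a = pca_reduce(x, 2, subset=500, seed=9)[0]
        b = pca_reduce(x, 2, subset=500, seed=9)[0]
        np.testing.assert_array_equal(a, b)


class TestSmoothing:
    def _fm(self, features):
        return FeatureMap(features=features, tile_px=128, stride_px=64)

    def test_zero_sigma_is_identity(self):
        f = np.random.default_rng(4).standard_normal((6, 6, 3))
        out = smooth_feature_map(self._fm(f), 0.0)
        np.testing.assert_array_equal(out.features, f)

    def test_constant_map_fixed_point(self):
        f = np.full((6, 6, 2), 1.7)
        out = smooth_feature_map(self._fm(f), 2.0)
        np.testing.assert_allclose(out.features, 1.7, rtol=1e-12)

    def test_impulse_response_is_normalized_symmetric_kernel(self):
        f = np.zeros((11, 11, 1))
        f[5, 5, 0] = 1.0
        out = smooth_feature_map(self._fm(f), 1.0).features[:, :, 0]
        assert out.sum() == pytest.approx(1.0, rel=1e-6)
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        np.testing.assert_allclose(out, out[::-1, ::-1], atol=1e-12)
        assert out[5, 5] == out.max()
        assert out[5, 5] > out[5, 6] > out[5, 7] > out[5, 8]

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_feature_map(self._fm(np.zeros((4, 4, 1))), -1.0)


class TestTwoStepCluster:
    def test_recovers_well_separated_blobs(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels_true = rng.integers(3, size=3000)
        x = centers[labels_true] + rng.normal(0, 0.5, (3000, 2))
        result = two_step_cluster(x, k=30, subset=2000, seed=0)
        labels = result.cut_labels(3)
        assert adjusted_rand_score(labels_true, labels) > 0.95

    def test_fixed_seed_identical_centroids(self):
        x = np.random.default_rng(6).standard_normal((500, 3))
        a = two_step_cluster(x, k=10, subset=400, seed=4)
        b = two_step_cluster(x, k=10, subset=400, seed=4)
        np.testing.assert_array_equal(a.kmeans_centroids, b.kmeans_centroids)

    def test_single_cluster_silhouette_flagged(self):
        x = np.random.default_rng(7).standard_normal((200, 2))
        result = two_step_cluster(x, k=8, subset=200, seed=0)
        assert np.isnan(result.silhouette(1))

    def test_silhouette_curve_bounded(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, (300, 2)), rng.normal(6, 1, (300, 2))])
        result = two_step_cluster(x, k=16, subset=600, seed=0)
        for k in (2, 3, 5):
            s = result.silhouette(k)
            assert -1.0 <= s <= 1.0
        assert result.silhouette(2) > result.silhouette(5)

    def test_linkage_heights_non_decreasing(self):
        x = np.random.default_rng(9).standard_normal((400, 4))
        result = two_step_cluster(x, k=20, subset=400, seed=0)
        heights = result.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError):
            two_step_cluster(np.zeros((10, 2)), k=50, subset=10)


class TestCrossSectionIoU:
    def test_identical_sections_score_one(self):
        labels = np.tile(np.random.default_rng(10).integers(0, 4, (8, 8)), (3, 1, 1))
        assert cross_section_iou(labels) == pytest.approx(1.0)

    def test_disjoint_label_sets_score_zero(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.ones((4, 4), dtype=int)
        assert cross_section_iou(np.stack([a, b])) == pytest.approx(0.0)

    def test_half_overlapping_strips(self):
        # two half-width strips cyclically shifted by half their width:
        # each cluster overlaps itself on 2 of 6 occupied columns, IoU = 1/3
        a = np.zeros((8, 8), dtype=int)
        a[:, 0:4] = 1
        b = np.roll(a, 2, axis=1)
        got = cross_section_iou(np.stack([a, b]))
        assert got == pytest.approx(1.0 / 3.0)

    def test_respects_foreground_mask(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.ones((4, 4), dtype=int)
        fg = np.zeros((2, 4, 4), dtype=bool)
        fg[:, :2] = True
        b[:2] = 0  # identical on the foreground rows
        assert cross_section_iou(np.stack([a, b]), fg) == pytest.approx(1.0)

    def test_single_section_rejected(self):
        with pytest.raises(ValueError):
            cross_section_iou(np.zeros((1, 4, 4), dtype=int))


class TestLinearProbe:
    def test_separable_classes_perfect_score(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 0.1, (50, 3)), rng.normal(5, 0.1, (50, 3))])
        y = np.repeat([0, 1], 50)
        res = linear_probe(x, y, x, y, n_per_class=[2], repeats=5, seed=0)
        assert res.f1_mean[0] == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((600, 4))
        y = rng.integers(0, 3, 600)  # labels independent of features
        res = linear_probe(x, y, x[:200], y[:200], n_per_class=[30], repeats=10, seed=0)
        assert abs(res.f1_mean[0] - 1.0 / 3.0) < 0.12

    def test_standard_error_reported_and_positive(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 2.0, (100, 2)), rng.normal(1, 2.0, (100, 2))])
        y = np.repeat([0, 1], 100)
        res = linear_probe(x, y, x, y, n_per_class=[5], repeats=20, seed=0)
        assert res.f1_se[0] > 0
        res_more = linear_probe(x, y, x, y, n_per_class=[5], repeats=40, seed=0)
        assert res_more.f1_se[0] < res.f1_se[0] * 1.5  # SE shrinks with repeats

    def test_insufficient_class_samples_rejected(self):
        x = np.zeros((4, 2))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError):
            linear_probe(x, y, x, y, n_per_class=[10], repeats=1, seed=0)


class TestMorphologyRegression:
    def test_exact_linear_target_recovered(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((2000, 5))
        w = rng.standard_normal(5)
        y = x @ w
        scores = morphology_regression(x, {"depth": y}, x[:500], {"depth": y[:500]}, l2=1e-6, n_train=1500, seed=0)
        assert scores["depth"] == pytest.approx(1.0, abs=1e-3)

    def test_independent_target_near_zero(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((3000, 5))
        y = rng.standard_normal(3000)
        scores = morphology_regression(x, {"t": y}, x[:1000], {"t": rng.standard_normal(1000)}, seed=0)
        assert abs(scores["t"]) < 0.05

    def test_nan_targets_filtered(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((500, 3))
        y = x @ np.ones(3)
        y[::5] = np.nan
        scores = morphology_regression(x, {"d": y}, x, {"d": y}, l2=1e-6, seed=0)
        assert scores["d"] > 0.99

    def test_training_fit_non_increasing_in_regularization(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((400, 8))
        y = x @ rng.standard_normal(8) + rng.normal(0, 0.5, 400)
        fits = [
            morphology_regression(x, {"y": y}, x, {"y": y}, l2=l2, n_train=400, seed=0)["y"]
            for l2 in (1e-4, 1e0, 1e4)
        ]
        assert fits[0] >= fits[1] >= fits[2]

    def test_zero_variance_target_rejected(self):
        x = np.random.default_rng(18).standard_normal((100, 3))
        with pytest.raises(ValueError):
            morphology_regression(x, {"flat": np.ones(100)}, x, {"flat": np.ones(100)}, seed=0)


class TestRBFRetrieval:
    def test_single_query_affinity_one_at_query(self):
        x = np.random.default_rng(19).standard_normal((50, 4))
        aff = rbf_retrieval(x, np.array([7]), sigma=3.5)
        assert aff[7] == pytest.approx(1.0)
        assert (aff <= 1.0).all() and (aff > 0.0).all()

    def test_distance_sigma_sqrt2_gives_inverse_e(self):
        sigma = 3.5
        q = np.zeros((1, 3))
        v = np.array([[sigma * np.sqrt(2.0), 0.0, 0.0]])
        aff = rbf_retrieval(np.concatenate([q, v]), np.array([0]), sigma=sigma)
        assert aff[1] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            rbf_retrieval(np.zeros((5, 2)), np.array([]), sigma=1.0)

    def test_rare_region_retrieval_ranks_same_region_higher(self, small_phantom):
        # phantom retrieval: query voxels from one region should rank that
        # region's voxels above the rest (feature proxy: channel encoding)
        from plicl.physics import channel_encode
        from sklearn.metrics import roc_auc_score

        sec = small_phantom.sections[0]
        enc = channel_encode(sec).reshape(3, -1).T
        labels = small_phantom.region_labels[0].ravel()
        target = labels == 3  # parallel-bundle region (most coherent signature)
        rng = np.random.default_rng(20)
        queries = rng.choice(np.flatnonzero(target), size=6, replace=False)
        aff = rbf_retrieval(enc, queries, sigma=0.5)
        fg = labels > 0
        auc = roc_auc_score(target[fg], aff[fg])
        assert auc > 0.9
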