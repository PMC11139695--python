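"""Encoding, embedding, cluster-number selection, KDE modes, overlap."""

import numpy as np
import pandas as pd
import pytest

from dietclust import (ClusteringConfig, DietaryPatternClusterer,
                       cluster_overlap, embed_umap, encode_matrix,
                       kde_peak_count, kmeans_assign, select_k)
from dietclust.cluster import Embedding2D, _scott_bandwidth


class TestEncodeMatrix:
    def test_full_schema_shape_and_range(self, preset_cohort):
        cohort, _ = preset_cohort
        mat = encode_matrix(cohort)
        assert mat.shape == (len(cohort), 79)
        assert mat.min().min() >= 1
        assert mat.max().max() <= 9
        assert (mat == mat.round()).all().all()   # integer scale positions

    def test_category_subsets(self, preset_cohort):
        cohort, _ = preset_cohort
        assert encode_matrix(cohort, ["food_item"]).shape[1] == 58
        assert encode_matrix(cohort, ["food_item",
                                      "dietary_behavior"]).shape[1] == 70
        assert encode_matrix(cohort, ["dietary_behavior"]).shape[1] == 12

    def test_singleton_grouping_is_identity(self, preset_cohort):
        cohort, _ = preset_cohort
        base = encode_matrix(cohort, ["cooking_method"])
        grouping = {c: [c] for c in base.columns}
        grouped = encode_matrix(cohort, ["cooking_method"], grouping)
        pd.testing.assert_frame_equal(grouped[base.columns], base)

    def test_group_column_is_member_mean(self, preset_cohort):
        cohort, _ = preset_cohort
        base = encode_matrix(cohort, ["food_item"])
        grouping = {"dairy": ["milk_yogurt", "reduced_fat_milk_yogurt"]}
        grouped = encode_matrix(cohort, ["food_item"], grouping)
        expected = base[["milk_yogurt", "reduced_fat_milk_yogurt"]].mean(axis=1)
        assert np.allclose(grouped["dairy"], expected)

    def test_empty_subset_errors(self, preset_cohort):
        cohort, _ = preset_cohort
        with pytest.raises(ValueError):
            encode_matrix(cohort, [])


class TestEmbedUmap:
    def test_shape_and_determinism(self, preset_cohort):
        cohort, _ = preset_cohort
        mat = encode_matrix(cohort).iloc[:80]
        cfg = ClusteringConfig(seed=7)
        e1 = embed_umap(mat, cfg)
        e2 = embed_umap(mat, cfg)
        assert e1.values.shape == (80, 2)
        assert np.array_equal(e1.values, e2.values)

    def test_too_few_rows(self, preset_cohort):
        cohort, _ = preset_cohort
        mat = encode_matrix(cohort).iloc[:5]
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_umap(mat, ClusteringConfig())

    def test_separated_blocks_stay_separated(self, schema, cohort_factory):
        # two response blocks at opposite scale extremes
        n = 60
        responses = {}
        for var in schema:
            lo, hi = var.scale_labels[0], var.scale_labels[-1]
            responses[var.id] = [lo] * 30 + [hi] * 30
        cohort = cohort_factory(responses, n=n)
        mat = encode_matrix(cohort)
        emb = embed_umap(mat, ClusteringConfig(seed=0, n_neighbors=5))
        from sklearn.metrics import silhouette_score
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette_score(emb.values, labels) > 0.5


class TestSelectK:
    @staticmethod
    def blobs(k, n_per=60, spread=0.4, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8], [4, 14]])[:k]
        pts = np.vstack([rng.normal(c, spread, size=(n_per, 2))
                         for c in centers])
        return pts

    def test_four_blobs_silhouette_and_kde_agree(self):
        X = self.blobs(4)
        diag = select_k(X, ClusteringConfig())
        assert diag.silhouette_k == 4
        assert diag.kde_peak_count == 4
        assert diag.selected_k == 4 and diag.agreed

    def test_single_blob_one_mode(self):
        X = self.blobs(1, n_per=150, spread=1.0)
        diag = select_k(X, ClusteringConfig())
        assert diag.kde_peak_count == 1
        # WCSS smooth and decreasing; silhouette never strong
        w = [diag.wcss[k] for k in sorted(diag.wcss)]
        assert all(b <= a + 1e-9 for a, b in zip(w, w[1:]))
        assert max(diag.silhouette.values()) < 0.6

    def test_wcss_monotone_and_silhouette_bounded(self):
        X = self.blobs(3, seed=5)
        diag = select_k(X, ClusteringConfig())
        w = [diag.wcss[k] for k in sorted(diag.wcss)]
        assert all(b <= a + 1e-9 for a, b in zip(w, w[1:]))
        assert all(-1 <= s <= 1 for s in diag.silhouette.values())

    def test_degenerate_embedding_errors(self):
        X = np.ones((50, 2))
        with pytest.raises(ValueError, match="degenerate"):
            select_k(X, ClusteringConfig())


class TestKdePeaks:
    def test_two_point_masses(self):
        # closed form: two Gaussian bumps 10 bandwidths apart have two modes
        a = np.zeros((25, 2))
        b = np.full((25, 2), 10.0)
        X = np.vstack([a, b])
        assert kde_peak_count(X, bandwidth=1.0) == 2

    def test_coincident_points_single_mode(self):
        X = np.zeros((30, 2))
        assert kde_peak_count(X, bandwidth=1.0) == 1

    def test_threshold_one_keeps_only_global_max(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (80, 2)),
                       rng.normal(6, 0.3, (40, 2))])
        assert kde_peak_count(X, bandwidth=0.5, threshold=1.0) == 1

    def test_nonpositive_bandwidth_errors(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="bandwidth"):
            kde_peak_count(X, bandwidth=0.0)

    def test_scott_rule_positive(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        assert _scott_bandwidth(X) > 0


class TestClusterOverlap:
    def test_identity_and_permutation_are_full_overlap(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.integers(0, 4, size=200))
        assert (cluster_overlap(labels, labels) == 100.0).all()
        permuted = labels.map({0: 3, 1: 2, 2: 0, 3: 1})
        assert (cluster_overlap(labels, permuted) == 100.0).all()

    def test_single_moved_point(self):
        a = pd.Series([0] * 5 + [1] * 5)
        b = a.copy()
        b.iloc[0] = 1  # one member of cluster 0 defects
        overlap = cluster_overlap(a, b)
        assert overlap[0] == pytest.approx(100 * 4 / 5)
        assert overlap[1] == pytest.approx(100.0)

    def test_differing_participants_error(self):
        a = pd.Series([0, 1], index=["x", "y"])
        b = pd.Series([0, 1], index=["x", "z"])
        with pytest.raises(ValueError, match="different participants"):
            cluster_overlap(a, b)


class TestEstimator:
    def test_sklearn_contract(self, preset_cohort):
        cohort, latent = preset_cohort
        est = DietaryPatternClusterer(k=4, random_state=0)
        params = est.get_params()
        assert params["n_neighbors"] == 10 and params["metric"] == "chebyshev"
        est.set_params(random_state=1)
        X = encode_matrix(cohort)
        labels = est.fit_predict(X)
        assert labels.shape == (len(cohort),)
        assert est.embedding_.shape == (len(cohort), 2)
        assert est.k_ == 4
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(latent, labels) > 0.8
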