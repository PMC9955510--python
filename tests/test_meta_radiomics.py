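import logging

import numpy as np
import pytest

from radtx.io import FeatureTable
from radtx.meta_radiomics import (
    extract_meta_features,
    homogeneity_scores,
    kmeans_fit,
    pca_project,
    prepare_features,
    select_k,
)
from radtx.synthetic import generate_radiomics


def table_from(values, prefix="original_glcm_f"):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return FeatureTable(
        [f"s{i}" for i in range(n)], [f"{prefix}{j:03d}" for j in range(f)], values
    )


class TestPrepareFeatures:
    def test_drops_constants_and_standardizes(self, rng):
        vals = rng.normal(size=(6, 3))
        vals[:, 1] = 4.2
        t = table_from(vals)
        std, dropped = prepare_features(t)
        assert dropped == ["original_glcm_f001"]
        assert std.n_features == 2
        np.testing.assert_allclose(std.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(std.values.std(axis=0), 1, atol=1e-12)

    def test_all_constant_error(self):
        with pytest.raises(ValueError, match="constant"):
            prepare_features(table_from(np.ones((4, 3))))


class TestKmeans:
    def test_two_group_toy_inertia(self):
        # two well-separated pairs in 2-D; hand-computed within-group SS
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        model = kmeans_fit(pts, 2, seed=0)
        groups = {tuple(sorted(model.members(c))) for c in range(2)}
        assert groups == {("f0", "f1"), ("f2", "f3")}
        assert model.inertia == pytest.approx(1.0)  # 4 * 0.5^2

    def test_k1_grand_mean(self, rng):
        pts = rng.normal(size=(12, 5))
        model = kmeans_fit(pts, 1, seed=0)
        np.testing.assert_allclose(model.centroids[0], pts.mean(axis=0), atol=1e-12)
        assert model.inertia == pytest.approx(((pts - pts.mean(0)) ** 2).sum())

    def test_best_of_restarts_not_worse_than_single(self, rng):
        pts = rng.normal(size=(40, 6))
        multi = kmeans_fit(pts, 5, n_restarts=10, seed=3)
        singles = [kmeans_fit(pts, 5, n_restarts=1, seed=s).inertia for s in range(5)]
        assert multi.inertia <= min(singles) + 1e-9

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.normal(size=(5, 3)), 5)


class TestSelectK:
    def test_recovers_planted_k(self):
        hits = 0
        for seed in range(4):
            feats, _ = generate_radiomics(
                n_samples=24, k_true=4, members_per_cluster=20, n_constant=0,
                noise_sd=0.1, seed=seed,
            )
            std, _ = prepare_features(feats)
            k, table = select_k(std, 2, 10, seed=seed)
            hits += k == 4
            assert table.table["silhouette"].between(-1, 1).all()
            assert (table.table["davies_bouldin"] >= 0).all()
        assert hits >= 3

    def test_kmax_capped_with_warning(self, rng, caplog):
        pts = rng.normal(size=(10, 4))
        with caplog.at_level(logging.WARNING):
            k, table = select_k(pts, 2, 50, seed=0)
        assert "capped" in caplog.text
        assert table.table["k"].max() == 9


class TestHomogeneity:
    def test_monotone_transforms_score_one(self, rng):
        base = rng.normal(size=8)
        vals = np.stack([base, 2 * base + 1, np.exp(base)], axis=1)
        t = table_from(vals)
        model = kmeans_fit(t, 1, seed=0)
        # force single cluster over all members
        assert homogeneity_scores(model, t) == {0: pytest.approx(1.0)}

    def test_antiphase_pair_scores_minus_one(self, rng):
        f = rng.normal(size=10)
        t = table_from(np.stack([f, -f], axis=1))
        model = kmeans_fit(t, 1, seed=0)
        assert homogeneity_scores(model, t)[0] == pytest.approx(-1.0)

    def test_invariant_to_standardization(self, rng):
        vals = rng.normal(size=(12, 6)) + rng.normal(size=(12, 1))
        raw = table_from(vals)
        std, _ = prepare_features(raw)
        model = kmeans_fit(std, 2, seed=1)
        h_std = homogeneity_scores(model, std)
        h_raw = homogeneity_scores(model, raw)
        for c in h_std:
            assert h_std[c] == pytest.approx(h_raw[c], abs=1e-12)

    def test_singleton_conventions(self, rng):
        from radtx.meta_radiomics import ClusterModel

        t = table_from(rng.normal(size=(6, 3)))
        model = ClusterModel(
            2, list(t.feature_ids), np.array([0, 0, 1]), np.zeros((2, 6)), 0.0, 0
        )
        assert homogeneity_scores(model, t)[1] == 1.0
        assert np.isnan(homogeneity_scores(model, t, singleton="exclude")[1])


class TestExtractMetaFeatures:
    def test_nearest_member_chosen_and_values_copied(self, rng):
        feats, _ = generate_radiomics(
            n_samples=12, k_true=3, members_per_cluster=6, n_constant=0,
            noise_sd=0.1, seed=2,
        )
        std, _ = prepare_features(feats)
        model = kmeans_fit(std, 3, seed=2)
        h = homogeneity_scores(model, std)
        sig = extract_meta_features(model, h, std, threshold=0.75, seed=2)
        pos = {f: i for i, f in enumerate(std.feature_ids)}
        for summary in sig.clusters:
            if summary.representative is None:
                continue
            assert summary.representative in summary.members
            pts = std.values[:, [pos[f] for f in summary.members]].T
            d2 = ((pts - model.centroids[summary.cluster_id]) ** 2).sum(axis=1)
            assert pos[summary.representative] == pos[summary.members[int(d2.argmin())]]

    def test_threshold_gates_representatives(self, rng):
        feats, _ = generate_radiomics(
            n_samples=12, k_true=3, members_per_cluster=6, n_constant=0,
            noise_sd=0.1, seed=5,
        )
        std, _ = prepare_features(feats)
        model = kmeans_fit(std, 3, seed=5)
        h = homogeneity_scores(model, std)
        sig = extract_meta_features(model, h, std, threshold=1.0, seed=5)
        assert sig.n_meta_features == 0  # h can never exceed 1 strictly

    def test_tie_break_deterministic(self, rng):
        # two members mirrored around the centroid -> exact distance tie
        z = rng.normal(size=6)
        vals = np.stack([z + 1.0, z - 1.0], axis=1)
        t = table_from(vals)
        model = kmeans_fit(t, 1, seed=0)
        h = {0: 1.0}
        picks = {
            extract_meta_features(model, h, t, threshold=0.5, seed=9).meta_feature_ids[0]
            for _ in range(5)
        }
        assert len(picks) == 1


class TestPcaProject:
    def test_variance_ordering_and_rank1(self, rng):
        u = rng.normal(size=(10, 1))
        v = rng.normal(size=(1, 6))
        coords, var = pca_project(u @ v)
        assert var[0] >= var[1]
        assert var[1] == pytest.approx(0, abs=1e-18)

    def test_matches_eigendecomposition_oracle(self):
        pts = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 5.0], [0.0, 4.0, 1.0]])
        coords, var = pca_project(pts)
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered
        w, vecs = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        expected = centered @ vecs[:, order[:2]]
        for j in range(2):
            assert np.allclose(coords[:, j], expected[:, j], atol=1e-9) or np.allclose(
                coords[:, j], -expected[:, j], atol=1e-9
            )
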