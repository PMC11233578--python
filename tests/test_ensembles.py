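"""Ensemble discovery: binning, PCA, k-means, silhouette selection,
ensemble labelling and group proportions."""

import numpy as np
import pytest

from gabacircuit.ensembles import (
    EnsembleClustering,
    EnsembleParams,
    build_feature_matrix,
    ensemble_proportions,
    kmeans_cluster,
    label_ensembles,
    optimal_k_silhouette,
    pca_project,
)

FS = 20.0


def _axis():
    return (np.arange(-20, 40) + 0.0) / FS  # [-1, +2) s at 20 Hz


def _blobs(rng, centers, n=20, sd=0.05):
    pts = np.vstack([c + sd * rng.normal(size=(n, len(c))) for c in centers])
    truth = np.repeat(np.arange(len(centers)), n)
    return pts, truth


class TestBuildFeatureMatrix:
    def test_default_dimensions_are_bins_times_sessions(self, rng):
        traces = rng.normal(0, 1, (3, 7, 60))
        X = build_feature_matrix(traces, _axis(), FS)
        assert X.shape == (7, 90)

    def test_constant_trace_fills_all_bins(self):
        traces = np.full((3, 2, 60), 1.7)
        X = build_feature_matrix(traces, _axis(), FS)
        assert np.allclose(X, 1.7)

    def test_matches_brute_force_binning(self, rng):
        traces = rng.normal(0, 1, (3, 4, 60))
        X = build_feature_matrix(traces, _axis(), FS)
        ta = _axis()
        for s in range(3):
            for b in range(30):
                lo = -1.0 + 0.1 * b
                frames = [i for i, t in enumerate(ta) if lo - 1e-9 <= t < lo + 0.1 - 1e-9]
                want = traces[s][:, frames].mean(axis=1)
                np.testing.assert_allclose(X[:, s * 30 + b], want, rtol=1e-12)

    def test_uneven_window_rejected(self):
        with pytest.raises(ValueError):
            EnsembleParams(bin_width=0.07)


class TestPcaProject:
    def test_rank_two_data_fully_explained(self, rng):
        base = rng.normal(size=(2, 40))
        X = rng.normal(size=(25, 2)) @ base
        _, var = pca_project(X)
        assert var.sum() > 1.0 - 1e-9

    def test_variance_spectrum_invariant_to_rotation(self, rng):
        X = rng.normal(size=(30, 12))
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        _, v1 = pca_project(X)
        _, v2 = pca_project(X @ q)
        np.testing.assert_allclose(np.sort(v1), np.sort(v2), rtol=1e-8)

    def test_variances_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(40, 10))
        proj, var = pca_project(X, EnsembleParams(n_components=4))
        C = np.cov(X - X.mean(0), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(var[:4], eig[:4] / eig.sum(), rtol=1e-8)

    def test_needs_more_neurons_than_components(self, rng):
        with pytest.raises(ValueError):
            pca_project(rng.normal(size=(3, 10)), EnsembleParams(n_components=4))


class TestKmeansCluster:
    def test_separated_blobs_perfectly_partitioned(self, rng):
        pts, truth = _blobs(rng, [(0, 0), (10, 10)])
        labels = kmeans_cluster(pts, 2)
        agree = (labels == truth).mean()
        assert agree in (0.0, 1.0)  # up to label permutation

    def test_duplicate_rows_share_labels(self, rng):
        pts, _ = _blobs(rng, [(0, 0), (8, 8)], n=10)
        doubled = np.vstack([pts, pts])
        labels = kmeans_cluster(doubled, 2)
        np.testing.assert_array_equal(labels[: len(pts)], labels[len(pts):])

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(10, 2)), 1)


class TestOptimalKSilhouette:
    def brute_force_silhouette(self, X, labels):
        n = len(X)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        s = np.empty(n)
        for i in range(n):
            same = (labels == labels[i]) & (np.arange(n) != i)
            a = d[i, same].mean() if same.any() else 0.0
            b = min(d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
            s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
        return s.mean()

    @pytest.mark.parametrize("n_centers", [2, 3])
    def test_selects_true_cluster_count(self, rng, n_centers):
        centers = [(0, 0), (10, 0), (0, 10)][:n_centers]
        pts, _ = _blobs(rng, centers)
        k, scores = optimal_k_silhouette(pts, EnsembleParams(seed=0))
        assert k == n_centers
        assert scores[k] == max(scores.values())

    def test_matches_quadratic_time_oracle(self, rng):
        pts, _ = _blobs(rng, [(0, 0), (6, 6)], n=15, sd=1.0)
        labels = kmeans_cluster(pts, 2)
        from sklearn.metrics import silhouette_score

        got = silhouette_score(pts, labels)
        want = self.brute_force_silhouette(pts, labels)
        assert abs(got - want) < 1e-10

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            optimal_k_silhouette(np.ones((10, 3)))


class TestLabelEnsembles:
    def _features(self, rng, flip=False):
        # 2 groups × 5 neurons, 90 features; group 0 rises after onset
        X = 0.01 * rng.normal(size=(10, 90))
        for s in range(3):
            X[:5, s * 30 + 10: s * 30 + 30] += 1.0
            X[5:, s * 30 + 10: s * 30 + 30] -= 1.0
        return -X if flip else X

    def test_mapping_agrees_with_construction_and_flips_with_sign(self, rng):
        X = self._features(rng)
        labels = np.array([0] * 5 + [1] * 5)
        assert label_ensembles(labels, X)[0] == "vF-activated"
        assert label_ensembles(labels, self._features(rng, flip=True))[0] == "vF-inactivated"

    def test_tie_breaks_to_cluster_zero_with_warning(self, caplog):
        X = np.zeros((6, 90))
        labels = np.array([0, 0, 0, 1, 1, 1])
        with caplog.at_level("WARNING"):
            m = label_ensembles(labels, X)
        assert m[0] == "vF-activated"
        assert any("tie" in r.message for r in caplog.records)

    def test_refuses_more_than_two_clusters(self, rng):
        with pytest.raises(ValueError):
            label_ensembles(np.array([0, 1, 2] * 3), rng.normal(size=(9, 90)))


class TestEnsembleProportions:
    def test_balanced_table_gives_odds_ratio_one(self):
        labs = {"control": np.array(["a"] * 10 + ["b"] * 10),
                "treated": np.array(["a"] * 10 + ["b"] * 10)}
        table, tests = ensemble_proportions(labs)
        assert tests["fisher_odds_ratio"] == pytest.approx(1.0)
        assert table.to_numpy().tolist() == [[10, 10], [10, 10]]

    def test_proportions_reproduce_input_ratios(self):
        a = np.array(["act"] * 189 + ["inact"] * 118)  # 61.6% of 307
        b = np.array(["act"] * 254 + ["inact"] * 143)  # 64.0% of 397
        table, _ = ensemble_proportions({"control": a, "chrimson": b})
        assert table.loc["control", "act"] / table.loc["control"].sum() == pytest.approx(189 / 307)
        assert table.loc["chrimson", "act"] / table.loc["chrimson"].sum() == pytest.approx(254 / 397)

    def test_null_p_values_roughly_uniform(self, rng):
        # equal-proportion groups: Fisher p should not over-reject
        ps = []
        for _ in range(300):
            x = rng.binomial(50, 0.5)
            y = rng.binomial(50, 0.5)
            _, tests = ensemble_proportions(
                {"g1": np.array(["a"] * x + ["b"] * (50 - x)),
                 "g2": np.array(["a"] * y + ["b"] * (50 - y))}
            )
            ps.append(tests["fisher_p"])
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.08
        assert ps.mean() > 0.3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ensemble_proportions({"a": np.array(["x"]), "b": np.array([])})


class TestEnsembleClusteringModel:
    def test_end_to_end_on_synthetic_two_ensembles(self, rng):
        ta = _axis()
        kinetic = np.exp(-np.clip(ta, 0, None)) * (ta >= 0)
        traces = np.zeros((3, 30, ta.size))
        truth = np.array([1] * 15 + [0] * 15)
        for s in range(3):
            traces[s, truth == 1] = 0.5 * kinetic
            traces[s, truth == 0] = -0.3 * kinetic
        traces += 0.02 * rng.normal(size=traces.shape)
        res = EnsembleClustering(traces, ta, FS, EnsembleParams(seed=1)).fit()
        assert res.chosen_k == 2
        labs = res.ensemble_labels()
        agree = ((labs == "vF-activated") == (truth == 1)).mean()
        assert agree in (0.0, 1.0) or agree == 1.0
        assert agree == 1.0
        assert "chosen k: 2" in res.summary()
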