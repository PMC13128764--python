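"""k-POD core: exact small-case oracles, the fit-integrity statistic,
missing-data behavior, and algorithmic invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cortclust as cc
from cortclust.kpod import DataMatrix, fit_integrity


def brute_force_wcss(X, K):
    """Exhaustive minimum WCSS over all K-partitions (complete data)."""
    n = X.shape[0]
    best = np.inf
    for a in itertools.product(range(K), repeat=n):
        if len(set(a)) < K:
            continue
        a = np.asarray(a)
        w = sum(float(((X[a == k] - X[a == k].mean(axis=0)) ** 2).sum())
                for k in range(K))
        best = min(best, w)
    return best


def partition_sets(labels):
    out = {}
    for i, l in enumerate(labels):
        out.setdefault(l, set()).add(i)
    return frozenset(frozenset(s) for s in out.values())


WELL_SEPARATED = np.array(
    [[0, 0], [0.1, 0], [10, 10], [10.1, 10], [20, 0], [20, 0.1]], dtype=float)


class TestKPOD:
    def test_k1_centroid_is_column_mean_and_fit_zero(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0], [7.0, 2.0]])
        est = cc.KPOD(n_clusters=1, n_init=2, random_state=0).fit(X)
        np.testing.assert_allclose(est.cluster_centers_[0], X.mean(axis=0))
        assert est.fit_ == 0.0
        assert est.wcss_ == pytest.approx(est.tss_)

    def test_recovers_exhaustive_optimum_on_separated_points(self):
        est = cc.KPOD(n_clusters=3, n_init=10, random_state=0).fit(WELL_SEPARATED)
        assert partition_sets(est.labels_) == frozenset(
            {frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})})
        assert est.wcss_ == pytest.approx(brute_force_wcss(WELL_SEPARATED, 3),
                                          abs=1e-9)

    def test_missing_cell_completed_at_centroid_coordinate(self):
        X = WELL_SEPARATED.copy()
        X[1, 1] = np.nan
        est = cc.KPOD(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert partition_sets(est.labels_) == frozenset(
            {frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})})
        k = est.labels_[1]
        assert est.completed_data_[1, 1] == pytest.approx(
            est.cluster_centers_[k, 1])

    def test_objective_history_non_increasing(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            X = rng.normal(size=(40, 5))
            X[rng.random(X.shape) < 0.2] = np.nan
            X[np.isnan(X).all(axis=1), 0] = 0.0
            est = cc.KPOD(n_clusters=3, n_init=3, random_state=seed).fit(X)
            if est.n_reseeds_ == 0:
                diffs = np.diff(est.objective_history_)
                assert (diffs <= 1e-8).all()

    def test_determinism_under_fixed_seed(self, remission_matrix):
        a = cc.KPOD(n_clusters=3, random_state=7).fit(remission_matrix)
        b = cc.KPOD(n_clusters=3, random_state=7).fit(remission_matrix)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)
        assert a.fit_ == b.fit_

    def test_mcar_deletion_preserves_partition(self):
        # well-separated clusters survive 20% MCAR deletion
        rng = np.random.default_rng(42)
        centers = np.array([[0.0] * 4, [20.0] * 4, [40.0] * 4])
        ok = 0
        trials = 20
        for t in range(trials):
            labels_true = np.repeat([0, 1, 2], 8)
            X = centers[labels_true] + rng.normal(scale=1.0, size=(24, 4))
            ref = cc.KPOD(n_clusters=3, n_init=5, random_state=t).fit(X)
            Xm = X.copy()
            drop = rng.random(X.shape) < 0.2
            drop[drop.all(axis=1), 0] = False
            Xm[drop] = np.nan
            est = cc.KPOD(n_clusters=3, n_init=5, random_state=t).fit(Xm)
            ok += partition_sets(est.labels_) == partition_sets(ref.labels_)
        assert ok >= 0.9 * trials

    def test_duplicate_points_trigger_reseeding_not_hang(self):
        X = np.vstack([np.tile([0.0, 0.0], (4, 1)), np.tile([5.0, 5.0], (4, 1))])
        est = cc.KPOD(n_clusters=4, n_init=5, random_state=0).fit(X)
        assert (np.bincount(est.labels_, minlength=4) > 0).all()

    def test_predict_uses_observed_coordinates_only(self, fitted_kpod):
        centers = fitted_kpod.cluster_centers_
        probe = np.full((centers.shape[0], centers.shape[1]), np.nan)
        probe[:, :2] = centers[:, :2]
        np.testing.assert_array_equal(fitted_kpod.predict(probe),
                                      np.arange(centers.shape[0]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cc.KPOD(n_clusters=5).fit(np.zeros((3, 2)))

    def test_fully_missing_row_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="observed"):
            cc.KPOD(n_clusters=1).fit(X)

    def test_sklearn_param_interface(self):
        est = cc.KPOD(n_clusters=4, tol=1e-3)
        assert est.get_params()["n_clusters"] == 4
        est.set_params(n_clusters=2)
        assert est.fit_predict(WELL_SEPARATED[:4]).shape == (4,)


class TestFitIntegrity:
    def test_hand_computed_toy_example(self):
        X = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]])
        fi = fit_integrity(X, [0, 0, 1, 1])
        assert fi.tss == pytest.approx(104.0)
        assert fi.wcss == pytest.approx(4.0)
        assert fi.fit == pytest.approx(25 / 26)
        assert not fi.degenerate

    def test_singleton_clusters_give_fit_one(self):
        X = np.arange(8.0).reshape(4, 2)
        fi = fit_integrity(X, np.arange(4))
        assert fi.wcss == 0.0
        assert fi.fit == 1.0

    def test_constant_matrix_flagged_degenerate(self):
        fi = fit_integrity(np.full((4, 3), 2.5), [0, 0, 1, 1])
        assert fi.degenerate
        assert fi.fit == 1.0

    def test_observed_cells_only(self):
        # the imputable cell must not contribute to either sum
        X = np.array([[0.0, 0.0], [0.0, np.nan], [10.0, 0.0], [10.0, 2.0]])
        fi = fit_integrity(X, [0, 0, 1, 1])
        # column means over observed cells: 5 and 2/3
        tss_expected = 4 * 25 + (2 * (2 / 3) ** 2 + (4 / 3) ** 2)
        assert fi.tss == pytest.approx(tss_expected)
        assert fi.wcss == pytest.approx(2.0)  # only the 0/2 column-1 pair varies

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fit_bounded_on_random_incomplete_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, t = rng.integers(3, 12), rng.integers(2, 6)
        X = rng.normal(scale=rng.uniform(0.1, 50), size=(n, t))
        X[rng.random((n, t)) < 0.3] = np.nan
        X[np.isnan(X).all(axis=1), 0] = 0.0
        K = int(rng.integers(1, n))
        est = cc.KPOD(n_clusters=K, n_init=3, random_state=seed).fit(X)
        assert 0.0 <= est.fit_ <= 1.0
        assert est.wcss_ <= est.tss_ + 1e-9


class TestKpodFitWrapper:
    def test_result_bundle_fields(self, remission_matrix):
        res = cc.kpod_fit(remission_matrix, K=3, n_restarts=5, seed=1)
        assert res.K == 3
        assert res.assignments.shape == (77,)
        assert set(res.assignments) == {0, 1, 2}
        assert res.centroids.shape == (3, 6)
        assert 0.0 <= res.fit <= 1.0
        assert res.wcss <= res.tss
        assert (res.cluster_sizes() > 0).all()
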