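"""Imputation, CCA, model-order selection, transferred evaluation and the
permutation test, with brute-force and sklearn cross-checks."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import connectocca as cc
from connectocca.synth import BehaviorTable

from oracles import cca_first_r_gridsearch


class TestImputeKnn:
    def test_twin_row_with_k1(self):
        Y = np.array([
            [1.0, 2.0, 3.0],
            [1.0, 2.0, np.nan],
            [9.0, 9.0, 9.0],
        ])
        out = cc.impute_knn(Y, k=1)
        assert out[1, 2] == pytest.approx(3.0)
        assert np.array_equal(out[0], Y[0])

    def test_identical_observed_rows_share_value(self):
        Y = np.tile([2.0, 5.0], (4, 1))
        Y[2, 1] = np.nan
        out = cc.impute_knn(Y, k=3)
        assert out[2, 1] == pytest.approx(5.0)

    def test_five_row_toy_matches_brute_force_search(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(5, 3)).round(2)
        Y[0, 1] = np.nan
        Y[3, 2] = np.nan
        out = cc.impute_knn(Y, k=2)
        # independent brute-force: z-score observed columns, full distance
        # table over jointly observed cells, mean of the k nearest
        mu = np.nanmean(Y, axis=0)
        sd = np.nanstd(Y, axis=0)
        Z = (Y - mu) / sd
        for (i, j) in [(0, 1), (3, 2)]:
            dists = []
            for l in range(5):
                if l == i or np.isnan(Y[l, j]):
                    continue
                joint = [c for c in range(3)
                         if not np.isnan(Y[i, c]) and not np.isnan(Y[l, c])]
                d = np.sqrt(np.mean([(Z[i, c] - Z[l, c]) ** 2 for c in joint]))
                dists.append((d, l))
            dists.sort()
            neigh = [l for _, l in dists[:2]]
            expected = mu[j] + sd[j] * np.mean([Z[l, j] for l in neigh])
            assert out[i, j] == pytest.approx(expected)

    def test_behavior_table_roundtrip_and_errors(self):
        Y = np.array([[1.0, np.nan], [2.0, 3.0], [1.5, 2.5]])
        table = BehaviorTable(Y, ("a", "b"), ("cognition", "motor"))
        out = cc.impute_knn(table, k=2)
        assert isinstance(out, BehaviorTable)
        assert not np.isnan(out.Y).any()
        with pytest.raises(ValueError, match="fully missing"):
            cc.impute_knn(np.array([[1.0, np.nan], [2.0, np.nan]]), k=1)
        with pytest.raises(ValueError, match="k must be"):
            cc.impute_knn(Y, k=0)


class TestCcaFirstMode:
    def test_perfect_linear_relations(self, rng):
        x = rng.standard_normal((40, 1))
        res = cc.cca_first_mode(x, 2 * x)
        assert res.R == pytest.approx(1.0)
        res = cc.cca_first_mode(x, -x)
        assert res.R == pytest.approx(1.0)  # magnitude after sign convention
        assert res.B[0, 0] > 0

    def test_matches_angle_grid_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((50, 2))
            Y = 0.4 * X @ rng.normal(size=(2, 2)) + rng.standard_normal((50, 2))
            res = cc.cca_first_mode(X, Y)
            assert res.R == pytest.approx(cca_first_r_gridsearch(X, Y), abs=1e-3)

    def test_matches_sklearn_first_pair(self, rng):
        from sklearn.cross_decomposition import CCA as SkCCA
        X = rng.standard_normal((120, 4))
        Y = 0.5 * X[:, :2] @ rng.normal(size=(2, 3)) + rng.standard_normal((120, 3))
        res = cc.cca_first_mode(X, Y)
        sk = SkCCA(n_components=1, max_iter=2000).fit(X, Y)
        u, v = sk.transform(X, Y)
        assert res.R == pytest.approx(abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1]), abs=1e-5)

    def test_realized_first_pair_correlation_equals_r(self, rng):
        X = rng.standard_normal((60, 3))
        Y = rng.standard_normal((60, 2))
        res = cc.cca_first_mode(X, Y)
        u = (X - X.mean(0)) @ res.A[:, 0]
        v = (Y - Y.mean(0)) @ res.B[:, 0]
        assert abs(np.corrcoef(u, v)[0, 1]) == pytest.approx(res.R, abs=1e-10)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_under_affine_score_transforms(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 3))
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # well-conditioned
        shift = rng.normal(size=3)
        r1 = cc.cca_first_mode(X, Y).R
        r2 = cc.cca_first_mode(X, Y @ M + shift).R
        assert r2 == pytest.approx(r1, abs=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        Y = rng.standard_normal((30, 2))
        with pytest.raises(ValueError, match="rank-deficient"):
            cc.cca_first_mode(X, np.column_stack([Y[:, 0], Y[:, 0]]))
        with pytest.raises(ValueError, match="N > D"):
            cc.cca_first_mode(rng.standard_normal((10, 6)), rng.standard_normal((10, 5)))
        with pytest.raises(ValueError, match="at least one column"):
            cc.cca_first_mode(np.empty((30, 0)), Y)


def _planted_lowrank_data(rng, n=400, f=50, k_sig=3, noise=0.8):
    Z = rng.standard_normal((n, k_sig))
    W = rng.normal(size=(k_sig, f))
    X = Z @ W + noise * rng.standard_normal((n, f))
    b = rng.normal(size=k_sig)
    y = Z @ b
    y = y / y.std()
    Y = np.column_stack([
        0.7 * y + np.sqrt(1 - 0.49) * rng.standard_normal(n),
        rng.standard_normal(n),
    ])
    return X, Y


class TestModelOrderSelection:
    def test_training_r_is_nondecreasing_in_d(self, rng):
        X = rng.standard_normal((80, 20))
        Y = rng.standard_normal((80, 3))
        model = cc.select_model_order((X[:50], Y[:50]), (X[50:], Y[50:]),
                                      d_grid=range(1, 11))
        assert np.all(np.diff(model.r_train_curve) >= -1e-10)

    def test_selected_order_maximizes_validation_curve(self, rng):
        X, Y = _planted_lowrank_data(rng)
        model = cc.select_model_order((X[:300], Y[:300]), (X[300:], Y[300:]),
                                      d_grid=range(1, 31))
        curve = model.r_val_curve
        assert model.D == model.d_grid[int(np.argmax(curve))]

    def test_recovers_small_order_for_low_rank_signal(self, rng):
        # 3-dimensional planted signal: selected order should be small and
        # the validation R close to the planted 0.7 association
        X, Y = _planted_lowrank_data(rng)
        model = cc.select_model_order((X[:300], Y[:300]), (X[300:], Y[300:]),
                                      d_grid=range(1, 41))
        assert model.D <= 10
        assert model.r_val_curve.max() == pytest.approx(0.7, abs=0.15)

    def test_empty_grid_rejected(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 2))
        with pytest.raises(ValueError, match="empty"):
            cc.select_model_order((X[:30], Y[:30]), (X[30:], Y[30:]), d_grid=[])
        with pytest.raises(ValueError, match="no candidate order"):
            cc.select_model_order((X[:30], Y[:30]), (X[30:], Y[30:]), d_grid=[999])

    def test_zero_variance_feature_columns_dropped(self, rng):
        X = rng.standard_normal((60, 6))
        X[:, 2] = 7.0
        Y = rng.standard_normal((60, 2))
        model = cc.select_model_order((X[:40], Y[:40]), (X[40:], Y[40:]),
                                      d_grid=[1, 2, 3])
        assert model.x_scaler.n_dropped == 1
        assert model.w_pca.shape[0] == 5


class TestEvaluateAndPermutation:
    def _fit(self, rng, n=120, assoc_strength=0.9):
        X = rng.standard_normal((n, 8))
        y = X[:, 0] * assoc_strength + np.sqrt(1 - assoc_strength**2) * rng.standard_normal(n)
        Y = np.column_stack([y, rng.standard_normal(n)])
        model = cc.select_model_order((X[: n // 2], Y[: n // 2]),
                                      (X[n // 2 :], Y[n // 2 :]),
                                      d_grid=range(1, 9))
        return X, Y, model

    def test_training_set_self_consistency(self, rng):
        X, Y, model = self._fit(rng)
        n = X.shape[0]
        r = cc.evaluate_test((X[: n // 2], Y[: n // 2]), model)
        best = int(np.argmax(model.r_val_curve))
        assert r == pytest.approx(model.r_train_curve[best], abs=1e-10)

    def test_scale_invariance_of_test_features(self, rng):
        X, Y, model = self._fit(rng)
        r1 = cc.evaluate_test((X[60:], Y[60:]), model)
        r2 = cc.evaluate_test((X[60:] * 3.7, Y[60:]), model)
        # PCA projection is affine in X, correlation is scale-free
        assert r2 == pytest.approx(r1, abs=1e-10)

    def test_score_column_mismatch_rejected(self, rng):
        X, Y, model = self._fit(rng)
        with pytest.raises(ValueError, match="different column set"):
            cc.evaluate_test((X[60:], Y[60:, :1]), model)

    def test_add_one_p_value_for_dominant_association(self, rng):
        X, Y, model = self._fit(rng, assoc_strength=0.98)
        test = (X[60:], Y[60:])
        cc.evaluate_test(test, model)
        p = cc.permutation_pvalue(test, model, n_perm=99, seed=0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_invariant_to_joint_row_relabeling(self, rng):
        X, Y, model = self._fit(rng)
        test = (X[60:], Y[60:])
        p1 = cc.permutation_pvalue(test, model, n_perm=199, seed=11)
        perm = rng.permutation(60)
        p2 = cc.permutation_pvalue((X[60:][perm], Y[60:][perm]), model,
                                   n_perm=199, seed=11)
        assert p1 == pytest.approx(p2)

    def test_refit_mode_runs_and_is_valid_probability(self, rng):
        X, Y, model = self._fit(rng)
        test = (X[60:], Y[60:])
        p = cc.permutation_pvalue(test, model, n_perm=30, seed=2, mode="refit",
                                  train=(X[:60], Y[:60]))
        assert 0 < p <= 1

    def test_tiny_test_set_rejected(self, rng):
        X, Y, model = self._fit(rng)
        with pytest.raises(ValueError, match="at least 5"):
            cc.permutation_pvalue((X[:4], Y[:4]), model, n_perm=10)
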