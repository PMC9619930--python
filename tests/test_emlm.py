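import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import cdist

from confpot import (
    MinMaxScaler,
    emlm_fit,
    emlm_predict,
    load_model,
    maximin_select,
    save_model,
)


def maximin_oracle(X, m):
    """Exhaustive re-implementation of the greedy maximin rule."""
    X = np.asarray(X, float)
    n = len(X)
    mean = X.mean(axis=0)
    best, best_d = 0, np.inf
    for i in range(n):
        d = np.linalg.norm(X[i] - mean)
        if d < best_d:
            best, best_d = i, d
    selected = [best]
    while len(selected) < m:
        cand, cand_d = None, -np.inf
        for i in range(n):
            if i in selected:
                continue
            dmin = min(np.linalg.norm(X[i] - X[j]) for j in selected)
            if dmin > cand_d:
                cand, cand_d = i, dmin
        selected.append(cand)
    return selected


class TestMaximin:
    def test_single_point(self):
        assert maximin_select(np.zeros((1, 2)), 1) == [0]

    def test_1d_hand_example(self):
        # mean of (0,1,2,10) is 3.25 -> nearest is index 2; then the far
        # point 10; then 0 (distance 2) beats 1 (distance 1)
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        assert maximin_select(X, 3) == [2, 3, 0]

    def test_m_equals_n_is_permutation(self, rng):
        X = rng.normal(size=(17, 4))
        sel = maximin_select(X, 17)
        assert sorted(sel) == list(range(17))

    def test_errors(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            maximin_select(X, 6)
        with pytest.raises(ValueError):
            maximin_select(np.zeros((0, 3)), 1)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 60))
            m = int(rng.integers(1, n + 1))
            X = rng.normal(size=(n, int(rng.integers(1, 6))))
            assert maximin_select(X, m) == maximin_oracle(X, m)


class TestMinMaxScaler:
    def test_basic_columns(self):
        sc = MinMaxScaler.fit(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(sc.apply(np.array([[0.0], [10.0]])),
                                   [[0.0], [1.0]])

    def test_constant_column_midpoint(self):
        X = np.array([[5.0], [5.0], [5.0]])
        sc = MinMaxScaler.fit(X, -1.0, 1.0)
        np.testing.assert_allclose(sc.apply(X), 0.0)
        np.testing.assert_allclose(sc.invert(sc.apply(X)), 5.0)

    def test_no_clamping_out_of_range(self):
        sc = MinMaxScaler.fit(np.array([[0.0], [1.0]]))
        assert sc.apply(np.array([[2.0]]))[0, 0] == pytest.approx(2.0)
        assert sc.apply(np.array([[-1.0]]))[0, 0] == pytest.approx(-1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_random(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(scale=rng.uniform(0.1, 50), size=(6, 4))
        X[:, 2] = 3.7  # one constant column
        sc = MinMaxScaler.fit(X, -1.0, 1.0)
        np.testing.assert_allclose(sc.invert(sc.apply(X)), X, atol=1e-12)


def pinv_oracle(Xtr, Y, m_idx):
    """Independent minimum-norm solution via the dense pseudoinverse."""
    H = cdist(Xtr, Xtr[m_idx])
    return np.linalg.pinv(H) @ Y


class TestFit:
    def test_two_point_hand_solution(self):
        # x = (0, 1) as its own references; feature scaling maps 0->0, 1->1
        # so H = [[0,1],[1,0]]; targets (0,1) scaled to (-1,1); the solve
        # gives scaled prediction at x=0.5 equal to 0 -> 0.5 unscaled
        X = np.array([[0.0], [1.0]])
        y = np.array([[0.0], [1.0]])
        model = emlm_fit(X, y, reference_fraction=2)
        H = cdist(model.feature_scaler.apply(X),
                  model.feature_scaler.apply(model.reference_descriptors))
        np.testing.assert_allclose(np.sort(np.diag(H)), [0.0, 0.0], atol=1e-12)
        pred = emlm_predict(model, np.array([[0.5]]))
        assert pred.iloc[0, 0] == pytest.approx(0.5, abs=1e-10)

    def test_zero_targets_zero_weights(self, rng):
        X = rng.normal(size=(12, 3))
        model = emlm_fit(X, np.zeros((12, 2)), reference_fraction=0.5)
        pred = emlm_predict(model, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(pred.to_numpy(), 0.0, atol=1e-9)

    def test_interpolation_when_m_equals_n(self, rng):
        X = rng.normal(size=(40, 5))
        Y = rng.normal(size=(40, 2))
        model = emlm_fit(X, Y, reference_fraction=40)
        pred = emlm_predict(model, X)
        np.testing.assert_allclose(pred.to_numpy(), Y, atol=1e-6)

    def test_weights_match_pinv_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            d = int(rng.integers(2, 20))
            X = rng.normal(size=(n, d))
            Y = rng.normal(size=(n, 2))
            m = int(rng.integers(1, n + 1))
            model = emlm_fit(X, Y, reference_fraction=m)
            # reproduce the internal scaling to call the oracle identically
            Xs = model.feature_scaler.apply(X)
            ref_idx = maximin_select(Xs, m)
            Ys = np.column_stack([
                model.target_scalers[s].apply(Y[:, j:j + 1])
                for j, s in enumerate(model.solvent_labels)
            ])
            W_oracle = pinv_oracle(Xs, Ys, ref_idx)
            np.testing.assert_allclose(model.weights, W_oracle, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 4))
        Y = rng.normal(size=(30, 2))
        query = rng.normal(size=(7, 4))
        a = emlm_predict(emlm_fit(X, Y, reference_fraction=10), query)
        perm = rng.permutation(30)
        b = emlm_predict(emlm_fit(X[perm], Y[perm], reference_fraction=10), query)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_monotone_capacity(self, rng):
        """Nested maximin prefixes: more references never hurt training RMSE."""
        X = rng.normal(size=(50, 6))
        Y = rng.normal(size=(50, 1))
        prev = np.inf
        for m in (5, 10, 25, 50):
            model = emlm_fit(X, Y, reference_fraction=m)
            resid = emlm_predict(model, X).to_numpy() - Y
            r = float(np.sqrt(np.mean(resid**2)))
            assert r <= prev + 1e-9
            prev = r

    def test_input_validation(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="NaN|Inf"):
            emlm_fit(np.array([[np.nan, 0]]), np.array([[1.0]]))
        with pytest.raises(ValueError):
            emlm_fit(X, np.zeros((4, 1)))
        with pytest.raises(ValueError):
            emlm_fit(X, np.zeros((5, 1)), reference_fraction=6)


class TestPredict:
    def test_empty_query(self, rng):
        model = emlm_fit(rng.normal(size=(8, 3)), rng.normal(size=(8, 1)),
                         reference_fraction=4)
        pred = emlm_predict(model, np.zeros((0, 3)))
        assert pred.shape == (0, 1)

    def test_duplicate_rows_identical_predictions(self, rng):
        model = emlm_fit(rng.normal(size=(8, 3)), rng.normal(size=(8, 1)),
                         reference_fraction=4)
        q = rng.normal(size=(1, 3))
        pred = emlm_predict(model, np.vstack([q, q]))
        assert pred.iloc[0, 0] == pred.iloc[1, 0]

    def test_fingerprint_mismatch_rejected(self, rng):
        model = emlm_fit(rng.normal(size=(8, 3)), rng.normal(size=(8, 1)),
                         reference_fraction=4, mbtr_fingerprint="abc123")
        with pytest.raises(ValueError, match="fingerprint"):
            emlm_predict(model, rng.normal(size=(2, 3)), fingerprint="zzz999")


class TestPersistence:
    def test_save_load_bit_identical_predictions(self, tmp_path, rng):
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 3))
        model = emlm_fit(X, Y, reference_fraction=0.25,
                         solvent_labels=["water", "pure", "wiom"],
                         mbtr_fingerprint="fp01")
        before = emlm_predict(model, X)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        after = emlm_predict(loaded, X)
        assert np.array_equal(before.to_numpy(), after.to_numpy())
        assert loaded.solvent_labels == ["water", "pure", "wiom"]
        assert len(loaded.target_scalers) == 3
        assert loaded.mbtr_fingerprint == "fp01"

    def test_truncated_file_clean_error(self, tmp_path, rng):
        model = emlm_fit(rng.normal(size=(6, 2)), rng.normal(size=(6, 1)),
                         reference_fraction=3)
        path = tmp_path / "model.npz"
        save_model(model, path)
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(ValueError):
            load_model(path)
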