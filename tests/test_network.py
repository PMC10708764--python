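import numpy as np
import pandas as pd
import pytest

from forestagb.network import (
    MLPConfig,
    MLPWeights,
    _pack,
    forward,
    hidden_size_candidates,
    hidden_size_search,
    init_weights,
    output_jacobian,
    predict_mlp,
    split_dataset,
    train_mlp_lm,
)


class TestSplit:
    def test_100_splits_70_15_15(self):
        s = split_dataset(100, seed=1)
        assert (len(s.train), len(s.val), len(s.test)) == (70, 15, 15)

    def test_162_splits_113_24_25(self):
        s = split_dataset(162, seed=1)
        assert (len(s.train), len(s.val), len(s.test)) == (113, 24, 25)

    def test_disjoint_and_exhaustive(self):
        s = split_dataset(53, seed=9)
        union = np.concatenate([s.train, s.val, s.test])
        assert sorted(union) == list(range(53))

    def test_deterministic(self):
        a, b = split_dataset(40, seed=7), split_dataset(40, seed=7)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(5)


class TestHiddenSizeHeuristics:
    def test_log2_of_21_inputs(self):
        assert hidden_size_candidates(21)["log2"] == 5

    def test_sqrt_range_for_21_inputs(self):
        # ceil(sqrt(22)) = 5, a in [0, 10] -> 5..15
        assert hidden_size_candidates(21, 1)["sqrt_range"] == list(range(5, 16))

    def test_trial_range_is_5_to_20(self):
        assert hidden_size_candidates(4)["trial_range"] == list(range(5, 21))

    def test_combinatorial_small_case(self):
        # n=2, k=4: M=2 gives 1+2+1=4 (not >4); M=3 gives 1+3+3=7 > 4
        assert hidden_size_candidates(2, k_samples=4)["combinatorial"] == 3

    def test_literal_sum_variant(self):
        assert hidden_size_candidates(21, 1, literal_sum=True)["sqrt_range"][0] == 22


class TestJacobian:
    def test_backprop_matches_central_differences(self, rng):
        n_in, hidden, n = 3, 4, 6
        params = init_weights(n_in, hidden, rng)
        X = rng.normal(size=(n, n_in))
        J = output_jacobian(params, X, hidden)
        eps = 1e-6
        for k in range(len(params)):
            up, dn = params.copy(), params.copy()
            up[k] += eps
            dn[k] -= eps
            fd = (forward(up, X, hidden)[0] - forward(dn, X, hidden)[0]) / (2 * eps)
            assert np.allclose(J[:, k], fd, atol=1e-5)


class TestTraining:
    def test_accepted_steps_strictly_decrease_train_mse(self, rng):
        X = rng.normal(size=(60, 2))
        y = X @ [1.0, -2.0] + 0.1 * rng.normal(size=60)
        cfg = MLPConfig(n_inputs=2, hidden_size=4, max_epochs=40, seed=0)
        _, hist = train_mlp_lm(X, y, cfg)
        acc = hist[hist["accepted"]]["train_mse"].to_numpy()
        assert (np.diff(acc) < 0).all()

    def test_constant_target_reproduced(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.full(30, 42.0)
        cfg = MLPConfig(n_inputs=2, hidden_size=3, max_epochs=20, seed=0)
        w, _ = train_mlp_lm(X, y, cfg)
        assert np.allclose(w.predict(X), 42.0)

    def test_linear_target_high_r2(self, rng):
        from forestagb.evaluation import r_squared

        X = rng.normal(size=(200, 3))
        y = 5.0 + X @ [2.0, -1.0, 0.5] + 0.01 * rng.normal(size=200)
        split = split_dataset(200, seed=2)
        cfg = MLPConfig(n_inputs=3, hidden_size=10, max_epochs=100, seed=1)
        w, _ = train_mlp_lm(X, y, cfg, split)
        assert r_squared(w.predict(X[split.test]), y[split.test]) >= 0.99

    def test_xor_pattern_fit(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 1.0, 0.0])
        cfg = MLPConfig(n_inputs=2, hidden_size=3, max_epochs=300, seed=4)
        w, hist = train_mlp_lm(X, y, cfg)
        assert np.mean((w.predict(X) - y) ** 2) < 1e-3

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            train_mlp_lm(X, np.ones(3), MLPConfig(n_inputs=2, hidden_size=2))

    def test_early_stopping_returns_best_validation_weights(self, rng):
        X = rng.normal(size=(80, 2))
        y = np.tanh(X @ [1.0, 1.0]) + 0.3 * rng.normal(size=80)
        split = split_dataset(80, seed=3)
        cfg = MLPConfig(n_inputs=2, hidden_size=8, max_epochs=200, validation_patience=4, seed=5)
        w, hist = train_mlp_lm(X, y, cfg, split)
        val = np.mean((w.predict(X[split.val]) - y[split.val]) ** 2)
        # returned weights are never worse on validation than any epoch's best
        y_span = y[split.train].max() - y[split.train].min()
        best_norm = hist["val_mse"].min() * (y_span / 2) ** 2
        assert val == pytest.approx(best_norm, rel=1e-6)


class TestPredict:
    def test_round_trip_determinism(self, rng):
        X = rng.normal(size=(10, 2))
        cfg = MLPConfig(n_inputs=2, hidden_size=3, max_epochs=5, seed=0)
        w, _ = train_mlp_lm(X, X @ [1.0, 1.0], cfg)
        assert np.array_equal(w.predict(X), w.predict(X))

    def test_zero_weight_network_outputs_constant_bias(self):
        w = MLPWeights(
            w1=np.zeros((2, 3)),
            b1=np.zeros(2),
            w2=np.zeros(2),
            b2=0.25,
            x_min=np.zeros(3),
            x_max=np.ones(3),
            y_min=0.0,
            y_max=100.0,
        )
        out = predict_mlp(w, np.random.default_rng(0).normal(size=(5, 3)))
        # normalized output 0.25 denormalizes to (0.25+1)/2 * 100
        assert np.allclose(out, 62.5)

    def test_hand_coded_2_2_1_forward_pass(self):
        w1 = np.array([[0.3, -0.2], [0.1, 0.4]])
        b1 = np.array([0.05, -0.1])
        w2 = np.array([0.7, -0.5])
        b2 = 0.2
        w = MLPWeights(
            w1=w1, b1=b1, w2=w2, b2=b2,
            x_min=np.array([-1.0, -1.0]), x_max=np.array([1.0, 1.0]),
            y_min=-1.0, y_max=1.0,
        )
        x = np.array([[0.5, -0.25]])
        h = np.tanh(w1 @ x[0] + b1)
        expected = float(w2 @ h + b2)  # identity normalization by construction
        assert predict_mlp(w, x)[0] == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        cfg = MLPConfig(n_inputs=2, hidden_size=2, max_epochs=2, seed=0)
        w, _ = train_mlp_lm(X, X[:, 0], cfg)
        with pytest.raises(ValueError):
            w.predict(rng.normal(size=(4, 3)))

    def test_dataframe_features_reordered_by_name(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        cfg = MLPConfig(n_inputs=2, hidden_size=3, max_epochs=10, seed=0)
        w, _ = train_mlp_lm(X, X["a"] * 2, cfg)
        assert np.allclose(w.predict(X[["b", "a"]]), w.predict(X))


class TestHiddenSizeSearch:
    def test_table_covers_every_size_and_is_reproducible(self, rng):
        X = rng.normal(size=(60, 2))
        y = X @ [1.0, 1.0] + 0.1 * rng.normal(size=60)
        split = split_dataset(60, seed=1)
        sizes = [2, 3, 4]
        best1, t1 = hidden_size_search(X, y, split, sizes=sizes, max_epochs=15)
        best2, t2 = hidden_size_search(X, y, split, sizes=sizes, max_epochs=15)
        assert list(t1["hidden_size"]) == sizes
        assert t1.equals(t2) and best1 == best2
        assert best1 == int(t1.loc[t1["val_mse"].idxmin(), "hidden_size"])

    def test_small_sizes_suffice_on_linear_target(self, rng):
        X = rng.normal(size=(120, 2))
        y = 3.0 + X @ [2.0, -1.0] + 0.02 * rng.normal(size=120)
        split = split_dataset(120, seed=2)
        _, table = hidden_size_search(X, y, split, sizes=[5, 20], max_epochs=40)
        t = table.set_index("hidden_size")["val_mse"]
        assert t[5] <= 1.5 * t[20] + 1e-9
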