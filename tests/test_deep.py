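"""Network forward/backward passes, training behavior, and the
successive-halving hyperparameter search."""

import numpy as np
import pytest

import svpredict as sv
from svpredict import deep, nnet
from svpredict.nnet import Conv1D, Dense, Flatten, MaxPool1D, Network


class TestForwardOracles:
    def test_hand_convolution(self):
        """(1,2,3,4) * filter (1,1), stride 1, no padding -> (3,5,7)."""
        conv = Conv1D(filters=1, kernel_width=2, stride=1, activation="linear")
        conv.build(length=4, channels=1, rng=np.random.default_rng(0))
        conv.W = np.ones((2, 1, 1))
        conv.b = np.zeros(1)
        out = conv.forward(np.array([[1.0, 2, 3, 4]])[:, :, None])
        assert np.allclose(out.ravel(), [3.0, 5.0, 7.0])

    def test_zero_filter_zero_feature_map(self, rng):
        conv = Conv1D(filters=2, kernel_width=3, activation="linear")
        conv.build(10, 1, rng)
        conv.W[...] = 0.0
        out = conv.forward(rng.normal(size=(4, 10, 1)))
        assert np.all(out == 0.0)

    def test_maxpool_stride_conventions(self):
        x = np.array([[3.0, 5.0, 7.0]])[:, :, None]
        assert np.allclose(MaxPool1D(2, stride=1).forward(x).ravel(), [5.0, 7.0])
        assert np.allclose(MaxPool1D(2, stride=2).forward(x).ravel(), [5.0])

    def test_relu_definition(self, rng):
        layer = Dense(2, activation="relu")
        layer.build(2, rng)
        layer.W = np.eye(2)
        layer.b = np.zeros(2)
        out = layer.forward(np.array([[1.0, -1.0]]))
        assert np.allclose(out, [[1.0, 0.0]])

    def test_sigmoid_output_in_unit_interval(self, rng):
        spec = deep.NetworkSpec(out_activation="sigmoid")
        model = deep.build_mlp(spec, n_features=5, seed=0)
        preds = model.predict(rng.normal(size=(20, 5)) * 50)
        assert np.all((preds > 0) & (preds < 1))

    def test_input_shorter_than_kernel_errors(self):
        spec = deep.NetworkSpec(arch="cnn", kernel_width=3)
        with pytest.raises(ValueError, match="shorter"):
            deep.build_cnn(spec, n_features=2, seed=0)


class TestGradients:
    @staticmethod
    def _finite_diff_check(model, X, y, kind):
        pred = model.forward(X, training=False)
        _, grad = nnet._loss_and_grad(kind, y, pred)
        model.backward(grad)
        analytic = [g.copy() for g in model.grads()]
        eps = 1e-6
        for p_idx, param in enumerate(model.params()):
            flat = param.ravel()
            for j in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[j]
                flat[j] = orig + eps
                up, _ = nnet._loss_and_grad(kind, y, model.forward(X))
                up += model.penalty()
                flat[j] = orig - eps
                dn, _ = nnet._loss_and_grad(kind, y, model.forward(X))
                dn += model.penalty()
                flat[j] = orig
                numeric = (up - dn) / (2 * eps)
                assert analytic[p_idx].ravel()[j] == pytest.approx(numeric, abs=1e-5)

    def test_mlp_gradients_match_finite_differences(self, rng):
        model = Network([Dense(4, "tanh", l1=0.01, l2=0.01), Dense(1, "linear")])
        model.build((3,), seed=1)
        self._finite_diff_check(model, rng.normal(size=(6, 3)),
                                rng.normal(size=6), "quantitative")

    def test_cnn_gradients_match_finite_differences(self, rng):
        model = Network([Conv1D(2, 3, 2, "tanh"), MaxPool1D(2, 1), Flatten(),
                         Dense(3, "relu"), Dense(1, "sigmoid")])
        model.build((12, 1), seed=2)
        y = rng.integers(0, 2, size=5).astype(float)
        self._finite_diff_check(model, rng.normal(size=(5, 12, 1)), y, "binary")

    def test_multi_input_zero_block_freezes_branch_weights(self, rng):
        spec = deep.NetworkSpec(arch="multi_input", activation="linear",
                                n_hidden=1)
        model = deep.build_multi_input(spec, [3] * 6, seed=3)
        xs = [rng.normal(size=(4, 3)) for _ in range(5)] + [np.zeros((4, 3))]
        pred = model.forward(xs)
        _, grad = nnet._loss_and_grad("quantitative", rng.normal(size=4), pred)
        model.backward(grad)
        dW_dead = model.branches[5].layers[0].dW
        dW_live = model.branches[0].layers[0].dW
        assert np.all(dW_dead == 0.0)
        assert np.any(dW_live != 0.0)


class TestMultiInput:
    def test_concatenated_width(self):
        spec = deep.NetworkSpec(arch="multi_input", n_hidden=1, branch_units=4)
        model = deep.build_multi_input(spec, [3, 3, 3, 3, 3, 3], seed=0)
        assert model.trunk.layers[0].W.shape[0] == 24

    def test_block_count_enforced(self):
        spec = deep.NetworkSpec(arch="multi_input")
        with pytest.raises(ValueError, match="6"):
            deep.build_multi_input(spec, [3, 3, 3], seed=0)

    def test_tied_branches_equal_single_network(self, rng):
        """Six identical blocks with tied branch weights and trunk weights
        tiled by 1/6 reproduce the single-input forward pass exactly."""
        x = rng.normal(size=(7, 5))
        single = Network([Dense(4, "tanh"), Dense(1, "linear")]).build((5,), seed=4)
        spec = deep.NetworkSpec(arch="multi_input", activation="tanh", n_hidden=0)
        multi = deep.build_multi_input(spec, [5] * 6, seed=5)
        for br in multi.branches:
            br.layers[0].units = 4
            br.layers[0].W = single.layers[0].W.copy()
            br.layers[0].b = single.layers[0].b.copy()
        # rebuild trunk output layer to accept width 24, weights tiled /6
        out = multi.trunk.layers[-1]
        out.W = np.tile(single.layers[1].W / 6.0, (6, 1))
        out.b = single.layers[1].b.copy()
        assert np.allclose(multi.forward([x] * 6), single.forward(x))


class TestTraining:
    def test_linear_mlp_attains_ols_loss(self, rng):
        """An affine network on noiseless linear data reaches the ordinary
        least-squares optimum (loss 0) within 1e-3."""
        X = rng.normal(size=(40, 3))
        w = np.array([1.0, -2.0, 0.5])
        y = X @ w + 0.3
        spec = deep.NetworkSpec(activation="linear", n_hidden=0, dropout=0.0,
                                l1=0.0, l2=0.0, optimizer="adam")
        fitted = deep.train(spec, X, y, epochs=800, batch_size=40, seed=0)
        final = fitted.history["train_loss"][-1]
        assert final < 1e-3

    def test_zero_epochs_returns_initialized_model(self, rng):
        X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        spec = deep.NetworkSpec()
        fresh = deep.build_mlp(spec, 4, seed=42)
        fitted = deep.train(spec, X, y, epochs=0, seed=42)
        assert fitted.history["train_loss"] == []
        for a, b in zip(fitted.model.params(), fresh.params()):
            assert np.array_equal(a, b)

    def test_overparameterized_fit_memorizes_noiseless_points(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.tanh(X @ rng.normal(size=10))
        spec = deep.NetworkSpec(first_units=64, n_hidden=1, hidden_units=16,
                                activation="tanh", optimizer="adam")
        fitted = deep.train(spec, X, y, epochs=600, batch_size=20, seed=1)
        assert fitted.history["train_loss"][-1] < 1e-3

    def test_early_stopping_restores_best_epoch(self, rng):
        """Training halts ``patience`` epochs after the last improvement and
        the returned parameters reproduce the best validation loss."""
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)  # pure noise: validation loss soon worsens
        Xv, yv = rng.normal(size=(15, 8)), rng.normal(size=15)
        spec = deep.NetworkSpec(first_units=64, hidden_units=16, optimizer="adam")
        fitted = deep.train(spec, X, y, Xv, yv, epochs=200, patience=3, seed=2)
        hist = fitted.history["val_loss"]
        assert fitted.best_epoch == int(np.argmin(hist))
        assert fitted.best_val_loss == pytest.approx(min(hist))
        if len(hist) < 200:  # stopped early
            assert len(hist) == fitted.best_epoch + 3 + 1
        restored, _ = nnet._loss_and_grad("quantitative", yv, fitted.predict(Xv))
        assert restored == pytest.approx(fitted.best_val_loss, rel=1e-9)

    def test_evaluation_is_deterministic_despite_dropout(self, rng):
        X, y = rng.normal(size=(30, 6)), rng.normal(size=30)
        spec = deep.NetworkSpec(dropout=0.3)
        fitted = deep.train(spec, X, y, epochs=5, seed=3)
        p1 = fitted.predict(X)
        p2 = fitted.predict(X)
        assert np.array_equal(p1, p2)

    def test_seed_reproducible_training(self, rng):
        X, y = rng.normal(size=(25, 5)), rng.normal(size=25)
        spec = deep.NetworkSpec()
        a = deep.train(spec, X, y, epochs=10, seed=7)
        b = deep.train(spec, X, y, epochs=10, seed=7)
        assert a.history["train_loss"] == b.history["train_loss"]


class TestSpecGrid:
    @pytest.mark.parametrize("bad", [
        dict(first_units=20), dict(n_hidden=5), dict(hidden_units=3),
        dict(activation="gelu"), dict(optimizer="adagrad"),
        dict(dropout=0.4), dict(l1=0.5), dict(arch="rnn"),
    ])
    def test_out_of_grid_rejected(self, bad):
        with pytest.raises(ValueError):
            deep.NetworkSpec(**bad)

    def test_cnn_hidden_grid_differs(self):
        deep.NetworkSpec(arch="cnn", n_hidden=1)
        with pytest.raises(ValueError):
            deep.NetworkSpec(arch="cnn", n_hidden=0)

    def test_random_specs_stay_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            spec = deep.random_spec(rng, arch="cnn")
            assert spec.first_units in deep.GRID_FIRST_UNITS
            assert spec.n_hidden in deep.GRID_HIDDEN_CNN
            assert spec.dropout in deep.GRID_DROPOUT
            assert spec.l1 in deep.GRID_PENALTY and spec.l2 in deep.GRID_PENALTY


class TestSuccessiveHalving:
    def _table_search(self, losses, seed=0):
        specs = [deep.NetworkSpec(first_units=u)
                 for u in (16, 38, 64, 128) for _ in range(2)][:len(losses)]
        table = {id(s): l for s, l in zip(specs, losses)}
        settings = deep.SearchSettings(n_configs=len(specs), seed=seed)
        result = deep.hyperband_search(
            specs, settings, train_fn=lambda cfg, ep: table[id(cfg)])
        return specs, result

    def test_argmin_of_fixed_loss_table(self):
        losses = [5.0, 3.0, 8.0, 0.5, 4.0, 9.0, 2.0, 7.0]
        specs, result = self._table_search(losses)
        assert result.best_spec is specs[3]
        assert result.best_loss == 0.5

    def test_bracket_sizes_8_4_2_1(self):
        losses = [5.0, 3.0, 8.0, 0.5, 4.0, 9.0, 2.0, 7.0]
        _, result = self._table_search(losses)
        counts = result.log.groupby("round").size().tolist()
        assert counts == [8, 4, 2, 1]
        epochs = result.log.groupby("round")["epochs"].first().tolist()
        assert epochs == [2, 4, 8, 16]

    def test_survivor_stable_across_search_seeds(self):
        losses = [5.0, 3.0, 8.0, 0.5, 4.0, 9.0, 2.0, 7.0]
        _, r1 = self._table_search(losses, seed=1)
        _, r2 = self._table_search(losses, seed=2)
        assert r1.best_loss == r2.best_loss == 0.5

    def test_search_on_real_data_returns_grid_config(self, rng):
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8)
        tr, val = np.arange(45), np.arange(45, 60)
        settings = deep.SearchSettings(n_configs=4, min_epochs=1, seed=5)
        result = deep.hyperband_search(("mlp", "linear"), settings,
                                       X=X[tr], y=y[tr], X_val=X[val], y_val=y[val])
        # returned config validates against the grids by construction
        assert isinstance(result.best_spec, deep.NetworkSpec)
        assert len(result.log) == 4 + 2 + 1

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            deep.SearchSettings(halving_factor=1)
        with pytest.raises(ValueError):
            deep.SearchSettings(min_epochs=0)
        with pytest.raises(ValueError):
            deep.hyperband_search([], deep.SearchSettings(), train_fn=lambda c, e: 0)
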