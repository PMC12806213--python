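import numpy as np
import pytest

from pandaml import neuralnet as nn


def numerical_grads(Ws, bs, X, Y, act, task, reg, strength, eps=1e-6):
    """Central finite differences of the loss for every parameter entry."""
    def loss():
        return nn.loss_and_grads(Ws, bs, X, Y, act, task, reg, strength)[0]

    num_dWs, num_dbs = [], []
    for P, store in ((Ws, num_dWs), (bs, num_dbs)):
        for arr in P:
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = arr[i]
                arr[i] = old + eps
                lp = loss()
                arr[i] = old - eps
                lm = loss()
                arr[i] = old
                g[i] = (lp - lm) / (2 * eps)
            store.append(g)
    return num_dWs, num_dbs


def separable_data(rng, n=100, margin=2.0):
    y = np.array(["neg"] * (n // 2) + ["pos"] * (n - n // 2))
    X = rng.standard_normal((n, 2))
    X[y == "pos"] += margin
    return X, y


class TestGradients:
    @pytest.mark.parametrize("act", ["relu", "tanh", "sigmoid"])
    @pytest.mark.parametrize("reg,strength",
                             [("none", 0.0), ("l1", 1e-2), ("l2", 1e-2)])
    def test_analytic_matches_central_difference(self, act, reg, strength):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 2))
        Y = np.eye(2)[rng.integers(0, 2, 6)]
        Ws, bs = nn._init_params([2, 3, 2], act, np.random.default_rng(1))
        _, dWs, dbs = nn.loss_and_grads(Ws, bs, X, Y, act, "softmax",
                                        reg, strength)
        num_dWs, num_dbs = numerical_grads(Ws, bs, X, Y, act, "softmax",
                                           reg, strength)
        for a, b in zip(dWs + dbs, num_dWs + num_dbs):
            rel = np.abs(a - b) / np.maximum(1e-8, np.abs(a) + np.abs(b))
            assert rel.max() < 1e-5

    def test_autoencoder_grads_match(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 4))
        Ws, bs = nn._init_params([4, 3, 2, 3, 4], "tanh",
                                 np.random.default_rng(3))
        linear = {1, 3}
        _, dWs, dbs = nn._ae_grads(Ws, bs, X, "tanh", linear, "l2", 1e-3)

        def loss():
            return nn._ae_grads(Ws, bs, X, "tanh", linear, "l2", 1e-3)[0]

        eps = 1e-6
        for arrs, grads in ((Ws, dWs), (bs, dbs)):
            for arr, g in zip(arrs, grads):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    old = arr[i]
                    arr[i] = old + eps
                    lp = loss()
                    arr[i] = old - eps
                    lm = loss()
                    arr[i] = old
                    num = (lp - lm) / (2 * eps)
                    rel = abs(num - g[i]) / max(1e-8, abs(num) + abs(g[i]))
                    assert rel < 1e-5


class TestTrainAnn:
    def test_separable_data_learned(self):
        rng = np.random.default_rng(4)
        X, y = separable_data(rng)
        cfg = nn.AnnConfig(hidden_layers=1, layer_size=30, epochs=100,
                           learning_rate=1e-2, seed=0)
        _, hist = nn.train_ann(X, y, X, y, cfg)
        assert hist.train_accuracy[-1] >= 0.95
        assert len(hist.train_loss) == cfg.epochs

    def test_same_seed_bit_identical_history(self):
        rng = np.random.default_rng(5)
        X, y = separable_data(rng, n=40)
        cfg = nn.AnnConfig(epochs=20, seed=7)
        _, h1 = nn.train_ann(X, y, X, y, cfg)
        _, h2 = nn.train_ann(X, y, X, y, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_zero_hidden_layers_is_linear_boundary(self):
        rng = np.random.default_rng(6)
        X, y = separable_data(rng, n=80)
        cfg = nn.AnnConfig(hidden_layers=0, epochs=150, learning_rate=1e-1,
                           seed=0)
        model, _ = nn.train_ann(X, y, config=cfg)
        # linear decision regions are convex: same-label endpoints imply
        # same-label midpoint
        pts = rng.standard_normal((60, 2)) * 3
        labels = np.asarray(nn.predict_labels(model, pts), dtype=object)
        for i in range(0, 60, 2):
            if labels[i] == labels[i + 1]:
                mid = nn.predict_labels(model, (pts[i] + pts[i + 1]) / 2)
                assert mid[0] == labels[i]

    def test_validation_class_missing_from_training_errors(self):
        rng = np.random.default_rng(7)
        X, y = separable_data(rng, n=20)
        with pytest.raises(ValueError, match="absent"):
            nn.train_ann(X, y, X[:2], np.array(["other", "other"]))

    def test_validation_content_does_not_leak_into_training(self):
        rng = np.random.default_rng(8)
        X, y = separable_data(rng, n=60)
        cfg = nn.AnnConfig(epochs=15, seed=1)
        _, h1 = nn.train_ann(X[:40], y[:40], X[40:], y[40:], cfg)
        garbage = rng.standard_normal((20, 2)) * 100
        _, h2 = nn.train_ann(X[:40], y[:40], garbage, y[40:], cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.train_accuracy == h2.train_accuracy
        assert h1.val_loss != h2.val_loss

    def test_sgd_loss_non_increasing_on_convex_problem(self):
        rng = np.random.default_rng(9)
        X, y = separable_data(rng, n=50, margin=1.0)
        cfg = nn.AnnConfig(hidden_layers=0, optimizer="sgd",
                           learning_rate=1e-2, batch_size=50, epochs=60,
                           seed=0)
        _, hist = nn.train_ann(X, y, config=cfg)
        diffs = np.diff(hist.train_loss)
        assert np.all(diffs <= 1e-8)


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(10)
    X, y = separable_data(rng, n=40)
    return nn.train_ann(X, y, config=nn.AnnConfig(epochs=10, seed=0))[0]


class TestPredictProba:
    def test_rows_sum_to_one(self, model):
        rng = np.random.default_rng(11)
        P = nn.predict_proba(model, rng.standard_normal((20, 2)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_labels_are_argmax(self, model):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((10, 2))
        P = nn.predict_proba(model, X)
        labels = nn.predict_labels(model, X)
        assert labels == [model.class_levels[k] for k in P.argmax(axis=1)]

    def test_duplicated_rows_identical(self, model):
        x = np.array([[0.5, -1.0]])
        P = nn.predict_proba(model, np.vstack([x, x]))
        np.testing.assert_array_equal(P[0], P[1])

    def test_shape_mismatch_errors(self, model):
        with pytest.raises(ValueError):
            nn.predict_proba(model, np.zeros((2, 5)))


class TestHyperparameterSearch:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(13)
        X, y = separable_data(rng, n=40)
        cfg = nn.AnnConfig(epochs=5, seed=0)
        best, _, table = nn.hyperparameter_search(X[:30], y[:30], X[30:],
                                                  y[30:], [cfg])
        assert best == cfg and len(table) == 1

    def test_crippled_config_not_selected(self):
        rng = np.random.default_rng(14)
        X, y = separable_data(rng, n=80)
        crippled = nn.AnnConfig(learning_rate=1e-9, epochs=1, seed=0)
        sane = nn.AnnConfig(learning_rate=1e-2, epochs=60, seed=0)
        best, _, table = nn.hyperparameter_search(
            X[:60], y[:60], X[60:], y[60:], [crippled, sane])
        assert best.learning_rate == sane.learning_rate
        assert len(table) == 2

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            nn.hyperparameter_search(None, None, None, None, [])

    def test_default_grid_covers_all_axes(self):
        grid = nn.default_search_grid()
        assert len({g.hidden_layers for g in grid}) == 3
        assert len({g.activation for g in grid}) == 2
        assert len({g.regularization for g in grid}) == 2


class TestAutoencoder:
    def test_linear_subspace_recovered(self):
        rng = np.random.default_rng(15)
        Z = rng.standard_normal((80, 2))
        A = rng.standard_normal((2, 10))
        X = Z @ A  # exactly rank-2 data in 10-D
        cfg = nn.AnnConfig(hidden_layers=0, learning_rate=1e-2, epochs=300,
                           seed=0)
        ae = nn.train_autoencoder(X, 2, cfg)
        mse = ae.reconstruction_mse(X)
        total_var = X.var(axis=0).mean()
        assert mse < 0.1 * total_var

    def test_capacity_monotonicity_on_average(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((60, 8))
        lo, hi = [], []
        for seed in range(5):
            cfg = nn.AnnConfig(hidden_layers=0, learning_rate=1e-2,
                               epochs=150, seed=seed)
            hi.append(nn.train_autoencoder(X, 7, cfg).reconstruction_mse(X))
            lo.append(nn.train_autoencoder(X, 2, cfg).reconstruction_mse(X))
        assert np.mean(hi) <= np.mean(lo)

    def test_decoded_mean_stays_in_bounding_box(self):
        rng = np.random.default_rng(17)
        X = rng.uniform(-2, 5, size=(50, 6))
        cfg = nn.AnnConfig(hidden_layers=0, learning_rate=1e-2, epochs=100,
                           seed=0)
        ae = nn.train_autoencoder(X, 3, cfg)
        rec = ae.decode(ae.encode(X.mean(axis=0)))
        assert np.all(rec >= X.min(axis=0) - 1.0)
        assert np.all(rec <= X.max(axis=0) + 1.0)

    def test_no_compression_errors(self):
        with pytest.raises(ValueError, match="compression"):
            nn.train_autoencoder(np.zeros((10, 3)), 3, nn.AnnConfig())


class TestSelectLatentDim:
    def test_singleton_dims_returned(self):
        rng = np.random.default_rng(18)
        X, y = separable_data(rng, n=40)
        X = np.hstack([X, rng.standard_normal((40, 6))])
        cfg = nn.AnnConfig(hidden_layers=0, epochs=20, learning_rate=1e-2,
                           seed=0)
        best, table = nn.select_latent_dim(X[:30], y[:30], X[30:], y[30:],
                                           dims=[4], config=cfg)
        assert best == 4 and len(table) == 1

    def test_informative_structure_found_and_reproducible(self):
        rng = np.random.default_rng(19)
        n = 120
        latent = rng.standard_normal((n, 3))
        y = np.where(latent[:, 0] + latent[:, 1] - latent[:, 2] > 0,
                     "pos", "neg")
        A = rng.standard_normal((3, 15))
        X = latent @ A + 0.05 * rng.standard_normal((n, 15))
        cfg = nn.AnnConfig(hidden_layers=1, layer_size=20, epochs=60,
                           learning_rate=1e-2, seed=0)
        best1, table1 = nn.select_latent_dim(X[:80], y[:80], X[80:], y[80:],
                                             dims=[2, 3, 5], config=cfg)
        best2, _ = nn.select_latent_dim(X[:80], y[:80], X[80:], y[80:],
                                        dims=[2, 3, 5], config=cfg)
        assert best1 == best2
        best_acc = table1["val_accuracy"].max()
        chosen_acc = table1.loc[table1["latent_dim"] == best1,
                                "val_accuracy"].iloc[0]
        assert chosen_acc >= best_acc - 0.05
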