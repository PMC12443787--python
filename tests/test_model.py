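"""biGRU classifier: architecture, gradients, loss, training dynamics."""

import numpy as np
import pytest

from rxseq import model as M
from rxseq import pipeline as P
from rxseq.evaluation import mean_auc


class TestParameterCount:
    def test_encoder_block(self):
        assert 88 * 32 + 32 == 2848

    def test_single_direction_formula(self):
        # 3 gates x (input, recurrent, bias) at e=32, h=8
        assert 3 * (32 * 8 + 8 * 8 + 8) == 984

    def test_default_configuration_total(self):
        assert M.count_parameters() == 5601

    @pytest.mark.parametrize("h", [4, 8, 16, 32])
    def test_formula_matches_built_model(self, h):
        cfg = M.ModelConfig(hidden_size=h)
        params = M.init_params(cfg, seed=0)
        assert M.count_parameters(cfg) == M.n_params(params)


class TestForward:
    def test_output_shape_and_range(self):
        net = M.build_model(seed=0)
        rng = np.random.default_rng(1)
        probs = M.predict(net, rng.random((7, 18, 88)), rng.random((7, 4)))
        assert probs.shape == (7, 9)
        assert np.all((probs > 0) & (probs < 1))

    def test_zero_parameters_give_half(self):
        net = M.build_model(seed=0)
        net.params = {k: np.zeros_like(v) for k, v in net.params.items()}
        probs = M.predict(net, np.zeros((3, 18, 88)), np.zeros((3, 4)))
        assert np.allclose(probs, 0.5)

    def test_bidirectional_symmetry_under_time_reversal(self):
        """Reversing the month axis while swapping the forward/backward
        parameter blocks (and the head rows that consume them) leaves the
        output unchanged — the two directions are exact mirrors."""
        cfg = M.ModelConfig()
        net = M.build_model(cfg, seed=3)
        rng = np.random.default_rng(4)
        Xb, Sb = rng.random((5, 18, 88)), rng.random((5, 4))
        base = M.predict(net, Xb, Sb)

        swapped = dict(net.params)
        for gate in ("z", "r", "n"):
            for kind in ("W", "U", "b"):
                f, b = f"{kind}{gate}_f", f"{kind}{gate}_b"
                swapped[f], swapped[b] = net.params[b], net.params[f]
        h = cfg.hidden_size
        W1 = net.params["W1"].copy()
        W1[:h], W1[h:2 * h] = net.params["W1"][h:2 * h], net.params["W1"][:h]
        swapped["W1"] = W1
        mirrored = M.predict(M.Model(cfg, swapped), Xb[:, ::-1, :], Sb)
        assert np.allclose(base, mirrored, atol=1e-12)

    def test_batch_invariance_and_row_permutation(self):
        net = M.build_model(seed=0)
        rng = np.random.default_rng(2)
        Xb, Sb = rng.random((6, 18, 88)), rng.random((6, 4))
        batch = M.predict(net, Xb, Sb)
        single = np.vstack([M.predict(net, Xb[i:i + 1], Sb[i:i + 1]) for i in range(6)])
        assert np.allclose(batch, single, atol=1e-12)
        perm = rng.permutation(6)
        assert np.allclose(M.predict(net, Xb[perm], Sb[perm]), batch[perm])

    def test_unnormalized_input_warns(self):
        net = M.build_model(seed=0)
        X = np.zeros((1, 18, 88))
        X[0, 0, 0] = 400.0
        with pytest.warns(UserWarning, match="unnormalized"):
            M.predict(net, X, np.zeros((1, 4)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = M.ModelConfig()
        params = M.init_params(cfg, 0)
        rng = np.random.default_rng(0)
        X, S = rng.random((3, 18, 88)) * 0.5, rng.random((3, 4))
        y = (rng.random((3, 9)) < 0.3).astype(float)
        w = np.full(9, 0.9)

        probs, cache = M.forward(params, X, S, cfg)
        grads, dX, dS = M.backward(params, cache, M._bce_dlogits(probs, y, w), cfg)

        def loss():
            p, _ = M.forward(params, X, S, cfg)
            return M.weighted_bce(p, y, w)

        eps = 1e-6
        for name in ("Wenc", "Wz_f", "Un_b", "W1", "W3", "bn_f", "b2"):
            flat = params[name].ravel()
            for i in rng.choice(flat.size, size=3, replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name].ravel()[i] == pytest.approx(num, rel=5e-3, abs=1e-9)
        # input gradient
        i, t, f = 1, 4, 10
        old = X[i, t, f]
        X[i, t, f] = old + eps
        lp = loss()
        X[i, t, f] = old - eps
        lm = loss()
        X[i, t, f] = old
        assert dX[i, t, f] == pytest.approx((lp - lm) / (2 * eps), rel=5e-3, abs=1e-9)

    def test_probability_input_gradients(self):
        cfg = M.ModelConfig()
        net = M.build_model(cfg, seed=5)
        rng = np.random.default_rng(6)
        X, S = rng.random((2, 18, 88)) * 0.5, rng.random((2, 4))
        probs, gX, gS = M.input_gradients(net, X, S)
        eps = 1e-6
        i, e, t, f = 1, 3, 5, 10
        old = X[i, t, f]
        X[i, t, f] = old + eps
        p1 = M.predict(net, X, S)[i, e]
        X[i, t, f] = old - eps
        p2 = M.predict(net, X, S)[i, e]
        X[i, t, f] = old
        assert gX[i, e, t, f] == pytest.approx((p1 - p2) / (2 * eps), rel=1e-4, abs=1e-10)

    def test_gradient_reaches_earliest_month(self, planted_run):
        """Bidirectionality keeps month-1 inputs connected: the trained
        model's input gradient at the earliest month is nonzero."""
        net = planted_run["net"]
        X, S = planted_run["X_test"][:8], planted_run["S_test"][:8]
        _, gX, _ = M.input_gradients(net, X, S)
        assert np.linalg.norm(gX[:, :, 0, :]) > 0


class TestWeightedBCE:
    def test_perfect_predictions_vanish(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[1 - 1e-9, 1e-9]])
        assert M.weighted_bce(p, y, np.array([0.9, 0.9])) == pytest.approx(0.0, abs=1e-6)

    def test_single_event_analytic_value(self):
        # y=1, p=0.5, w=0.8 -> 0.8 ln 2
        loss = M.weighted_bce(np.array([[0.5]]), np.array([[1.0]]), np.array([0.8]))
        assert loss == pytest.approx(0.8 * np.log(2))

    def test_false_negative_costs_more_than_false_positive(self):
        w = np.array([0.9])
        fn = M.weighted_bce(np.array([[0.1]]), np.array([[1.0]]), w)
        fp = M.weighted_bce(np.array([[0.9]]), np.array([[0.0]]), w)
        assert fn > fp

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            M.weighted_bce(np.array([[1.5]]), np.array([[1.0]]), np.array([0.9]))


class TestEarlyStopping:
    def test_monotone_worsening_stops_after_patience(self):
        stopper = M.EarlyStopper(patience=15)
        stopped_at = None
        for epoch, loss in enumerate(np.linspace(1.0, 2.0, 100), start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 16
        assert stopper.best_epoch == 1

    @pytest.mark.parametrize("patience", [1, 5])
    def test_patience_arithmetic(self, patience):
        stopper = M.EarlyStopper(patience)
        losses = [3.0, 2.0, 2.5, 2.4, 2.3, 2.2, 2.1]  # best at epoch 2
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 2 + patience
        assert stopper.best_epoch == 2


class TestTraining:
    def test_empty_subsets_rejected(self):
        net = M.build_model(seed=0)
        empty = (np.zeros((0, 18, 88)), np.zeros((0, 4)), np.zeros((0, 9)))
        data = (np.zeros((4, 18, 88)), np.zeros((4, 4)), np.zeros((4, 9)))
        with pytest.raises(ValueError):
            M.train_with_early_stopping(net, empty, data, M.TrainConfig(), np.ones(9))

    def test_same_seed_reproduces_loss_curves(self):
        rng = np.random.default_rng(0)
        data = (rng.random((32, 18, 88)), rng.random((32, 4)),
                (rng.random((32, 9)) < 0.3).astype(float))
        val = (rng.random((16, 18, 88)), rng.random((16, 4)),
               (rng.random((16, 9)) < 0.3).astype(float))
        tc = M.TrainConfig(max_epochs=5, patience=15, seed=9)
        f1 = M.train_with_early_stopping(M.build_model(seed=1), data, val, tc, np.full(9, 0.8))
        f2 = M.train_with_early_stopping(M.build_model(seed=1), data, val, tc, np.full(9, 0.8))
        assert f1.train_losses == f2.train_losses
        assert f1.val_losses == f2.val_losses

    def test_best_epoch_minimizes_validation_loss(self, planted_run):
        fit = planted_run["fit"]
        assert fit.best_epoch == int(np.argmin(fit.val_losses)) + 1

    def test_planted_signal_beats_uninformed_baseline(self, planted_run):
        """Final validation loss must undercut the all-0.5 prediction whose
        loss is computable in closed form from weights and label rates."""
        fit = planted_run["fit"]
        y = planted_run["y_train"]
        w = planted_run["weights"]
        base = M.weighted_bce(np.full_like(y, 0.5, dtype=float), y, w)
        assert min(fit.val_losses) < base

    def test_training_loss_decreases(self, planted_run):
        losses = planted_run["fit"].train_losses
        assert losses[-1] < losses[0]


class TestCrossValidation:
    def make_folds(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        def block(m):
            return (rng.random((m, 18, 88)), rng.random((m, 4)),
                    (rng.random((m, 9)) < 0.4).astype(float))
        return [(block(n), block(max(n // 4, 4))) for _ in range(5)]

    def test_single_candidate_grid_returns_it(self):
        folds = self.make_folds()
        tc = M.TrainConfig(max_epochs=2, patience=15, seed=0)
        best, table = M.cross_validate_hidden_size(folds, grid=(8,), train_config=tc)
        assert best == 8

    def test_score_table_shape(self):
        folds = self.make_folds()
        tc = M.TrainConfig(max_epochs=1, patience=15, seed=0)
        best, table = M.cross_validate_hidden_size(folds, grid=(4, 8), train_config=tc)
        assert set(table["per_fold"]) == {4, 8}
        assert all(len(v) == 5 for v in table["per_fold"].values())
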