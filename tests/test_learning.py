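"""Surrogate gradient, reward signal, weight updates, and the epoch loop."""

import dataclasses

import numpy as np
import pytest

from spikeloop import (
    Adam,
    LearningConfig,
    fit,
    forward_sequence,
    make_feedback,
    make_reward_signal,
    reward_gradient,
    surrogate_grad,
    train_epoch,
    weight_update,
)
from spikeloop.learning import (
    compute_gradients,
    gradients_reward_propagation,
    mse_loss,
    _model_params,
    _one_hot,
)

from conftest import random_input_run, small_model


@pytest.mark.parametrize(
    "V, theta, expected",
    [
        (0.5, 0.5, 1.0),   # exactly at threshold: inside the window
        (0.6, 0.5, 1.0),
        (1.2, 0.5, 0.0),   # outside
        (1.0, 0.5, 0.0),   # |V - theta| == V_window: strict inequality excludes it
        (0.0, 0.5, 0.0),   # lower boundary excluded too
    ],
)
def test_surrogate_boxcar(V, theta, expected):
    assert surrogate_grad(V, theta, V_window=0.5) == expected


def test_surrogate_requires_positive_window():
    with pytest.raises(ValueError):
        surrogate_grad(0.5, 0.5, 0.0)


class TestRewardSignal:
    def test_repeated_one_hot(self):
        rp = make_reward_signal(3, n_classes=10, T=5)
        assert rp.shape == (5, 10)
        np.testing.assert_array_equal(rp[:, 3], 1.0)
        np.testing.assert_array_equal(rp.sum(axis=1), 1.0)

    def test_single_class_degenerate(self):
        np.testing.assert_array_equal(make_reward_signal(0, 1, 4), np.ones((4, 1)))

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            make_reward_signal(10, n_classes=10, T=5)


class TestRewardGradient:
    def test_satisfied_target_gives_zero(self):
        B = np.eye(3)
        rp = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(reward_gradient(B, rp, B @ rp), 0.0)

    def test_identity_projection(self):
        np.testing.assert_array_equal(
            reward_gradient(np.eye(3), np.array([0.0, 0.0, 1.0]), np.zeros(3)),
            [0.0, 0.0, 1.0],
        )

    def test_matrix_arithmetic(self):
        B = np.array([[1.0, 0.0], [0.0, 2.0]])
        out = reward_gradient(B, np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(out, [-0.5, 1.5])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reward_gradient(np.eye(3), np.zeros(2), np.zeros(3))


class TestWeightUpdate:
    def _traces(self, T=6, n=4, pre=3, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "grad_rp": rng.normal(size=(T, n)),
            "surrogate": (rng.random((T, n)) < 0.7).astype(float),
            "pre": rng.random((T, pre)),
            "s_prev": (rng.random((T, n)) < 0.3).astype(float),
            "W_r": rng.normal(size=(n, n)),
            "mask": (rng.random((n, n)) < 0.5).astype(float),
        }

    def test_zero_error_no_update(self):
        tr = self._traces()
        dW_f, dW_r = weight_update(np.zeros_like(tr["grad_rp"]), tr["surrogate"], tr["pre"],
                                   tr["s_prev"], tr["W_r"], tr["mask"], LearningConfig())
        assert not dW_f.any() and not dW_r.any()

    def test_closed_surrogate_gate_kills_update(self):
        tr = self._traces()
        dW_f, dW_r = weight_update(tr["grad_rp"], np.zeros_like(tr["surrogate"]), tr["pre"],
                                   tr["s_prev"], tr["W_r"], tr["mask"], LearningConfig())
        assert not dW_f.any() and not dW_r.any()

    def test_recurrent_update_respects_mask(self):
        tr = self._traces()
        _, dW_r = weight_update(tr["grad_rp"], tr["surrogate"], tr["pre"],
                                tr["s_prev"], tr["W_r"], tr["mask"], LearningConfig())
        np.testing.assert_array_equal(dW_r * (1 - tr["mask"]), 0.0)

    def test_descent_on_layer_target(self):
        """One small-eta update moves the hidden state toward B @ RP on a toy model."""
        model = small_model(n_in=2, n_hidden=2, n_classes=2, density=1.0, seed=1, T=6)
        fb = make_feedback(model, 1)
        X = np.random.default_rng(1).uniform(0.3, 1.0, (1, 2, 6))
        Y = _one_hot(np.array([1]), 2)
        cfg = LearningConfig(eta_f=1e-3, eta_r=1e-3)

        def layer_target_mse():
            res = forward_sequence(X, model)
            tr = res.traces[0]
            target = Y @ fb.B[0].T
            return float(np.mean((tr["h"] - target[None]) ** 2)), res

        before, res = layer_target_mse()
        tr = res.traces[0]
        sg = surrogate_grad(tr["h"], tr["theta"], cfg.V_window)
        target = (Y @ fb.B[0].T)[None]
        dW_f, dW_r = weight_update(target - tr["h"], sg, tr["x"], tr["s_prev"],
                                   model.hidden[0].W_r, model.hidden[0].mask, cfg)
        model.hidden[0].W_f += dW_f
        model.hidden[0].W_r += dW_r
        after, _ = layer_target_mse()
        assert after < before


def test_gating_soundness(tiny_model):
    """Nonzero update columns require at least one step within the surrogate window."""
    res = random_input_run(tiny_model, n_samples=2, seed=9)
    fb = make_feedback(tiny_model, 0)
    cfg = LearningConfig()
    grads = gradients_reward_propagation(tiny_model, res, _one_hot(np.array([0, 1]), 4), fb, cfg)
    tr = res.traces[0]
    sg = surrogate_grad(tr["h"], tr["theta"], cfg.V_window)
    never_gated = sg.sum(axis=(0, 1)) == 0  # per postsynaptic neuron
    assert not grads["h0.W_f"][:, never_gated].any()
    assert not grads["h0.W_r"][:, never_gated].any()


def test_layer_updates_are_order_invariant():
    """Reward-propagation gradients per layer are independent of evaluation order."""
    model = small_model(n_in=10, n_hidden=14, n_classes=3, seed=2)
    spec = dataclasses.replace(model.spec, layer_sizes=(10, 14, 12, 3))
    from spikeloop import init_weights

    deep = init_weights(spec, 2)
    res = random_input_run(deep, n_samples=2, seed=2)
    fb = make_feedback(deep, 2)
    Y = _one_hot(np.array([0, 2]), 3)
    cfg = LearningConfig()
    grads = gradients_reward_propagation(deep, res, Y, fb, cfg)
    # recompute each layer in isolation (reverse order) from the same traces
    for li in reversed(range(len(deep.hidden))):
        tr = res.traces[li]
        sg = surrogate_grad(tr["h"], tr["theta"], cfg.V_window)
        E = (tr["h"] - (Y @ fb.B[li].T)[None]) * sg
        nxt = np.zeros_like(E)
        nxt[:-1] = sg[:-1] * (E[1:] @ deep.hidden[li].W_r.T)
        g_f = np.einsum("tbi,tbj->ij", tr["x"], E) / 2
        g_r = np.einsum("tbi,tbj->ij", tr["s_prev"], E + nxt) * deep.hidden[li].mask / 2
        np.testing.assert_array_equal(g_f, grads[f"h{li}.W_f"])
        np.testing.assert_array_equal(g_r, grads[f"h{li}.W_r"])


class TestTrainEpoch:
    def test_zero_learning_rate_freezes_weights(self, easy_task):
        X, y = easy_task[0][:20], easy_task[1][:20]
        model = small_model(n_in=39, n_hidden=15, T=39, seed=0)
        before = {k: v.copy() for k, v in _model_params(model).items()}
        cfg = LearningConfig(eta_f=0.0, eta_r=0.0, epochs=1, seed=0)
        train_epoch(X, y, model, cfg, Adam(), epoch=0, feedback=make_feedback(model, 0))
        for k, v in _model_params(model).items():
            np.testing.assert_array_equal(v, before[k])

    def test_repeatable_given_seed(self, easy_task):
        X, y = easy_task[0][:20], easy_task[1][:20]
        metrics = []
        for _ in range(2):
            model = small_model(n_in=39, n_hidden=15, T=39, seed=0)
            cfg = LearningConfig(epochs=1, seed=3)
            m = train_epoch(X, y, model, cfg, Adam(), epoch=0, feedback=make_feedback(model, 3))
            metrics.append(m)
        assert metrics[0] == metrics[1]

    def test_empty_dataset_rejected(self):
        model = small_model()
        with pytest.raises(ValueError):
            train_epoch(np.empty((0, 10, 10)), np.empty(0, dtype=int), model,
                        LearningConfig(), Adam())


def test_both_rules_descend_readout_loss(easy_task):
    """RP and pseudo-BP both reduce the MSE loss over a short run from shared init."""
    X, y = easy_task[0], easy_task[1]
    losses = {}
    for rule in ("reward_propagation", "pseudo_bp"):
        model = small_model(n_in=39, n_hidden=40, T=39, seed=4)
        hist = fit(model, X, y, LearningConfig(epochs=5, seed=4, rule=rule))
        losses[rule] = [h["loss"] for h in hist]
        assert losses[rule][-1] < losses[rule][0]


def test_lr_schedule_steps_down():
    cfg = LearningConfig(lr_decay=0.5, lr_step_epochs=100)
    assert cfg.lr_at(0) == 1.0
    assert cfg.lr_at(99) == 1.0
    assert cfg.lr_at(100) == 0.5
    assert cfg.lr_at(250) == 0.25


def test_config_validation():
    with pytest.raises(ValueError):
        LearningConfig(rule="hebbian")
    with pytest.raises(ValueError):
        LearningConfig(V_window=0.0)
    with pytest.raises(ValueError):
        LearningConfig(eta_f=-1.0)
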