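"""Training rules: global reward propagation and truncated pseudo-BP.

Reward propagation replaces layer-by-layer error backpropagation with a
global teaching signal: the one-hot class label, repeated at every time
step (``RP_t``), is projected into each hidden layer's state space through
a fixed random feedback matrix ``B``.  The per-step layer error is the
projected-target-minus-state difference

    Grad_RP(t) = B @ RP_t - h(t)

gated elementwise by the boxcar surrogate derivative of the spike function
(1 within ``V_window`` of the effective threshold, 0 outside).  Because each
hidden layer's update depends only on its own traces and its own ``B``, the
updates for different layers are independent and can be computed in any
order (or in parallel).  Recurrent weights additionally receive a one-step
truncated flow of the next step's error through W_r.

The pseudo-BP comparator chains the readout error down through the layers
with the same surrogate derivative and a depth-1 backward pass through time.
Both rules feed gradients to an adaptive-moment (Adam) optimiser and
minimise the mean squared error between the time-averaged readout and the
one-hot label; recurrent updates are re-masked after every step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .network import ForwardResult, SpikingNetwork, forward_sequence

__all__ = [
    "FeedbackProjection",
    "LearningConfig",
    "Adam",
    "surrogate_grad",
    "make_reward_signal",
    "reward_gradient",
    "make_feedback",
    "weight_update",
    "train_epoch",
    "fit",
]


@dataclass
class FeedbackProjection:
    """Fixed random feedback matrices, one per hidden layer (width x n_classes)."""

    B: List[np.ndarray]
    seed: int


@dataclass(frozen=True)
class LearningConfig:
    """Training hyperparameters.

    ``eta_f``/``eta_r`` are the feedforward and recurrent learning rates
    (both stepped down by ``lr_decay`` every ``lr_step_epochs`` epochs);
    ``V_window`` is the surrogate half-width in mV; ``rule`` selects reward
    propagation or the pseudo-BP comparator.  Loss is always MSE against the
    one-hot label; optimisation is Adam with standard moment defaults.
    """

    eta_f: float = 1e-3
    eta_r: float = 1e-3
    V_window: float = 0.5
    rule: str = "reward_propagation"
    batch_size: int = 50
    epochs: int = 30
    seed: int = 0
    lr_decay: float = 0.5
    lr_step_epochs: int = 100

    def __post_init__(self) -> None:
        if self.eta_f < 0 or self.eta_r < 0:
            raise ValueError("learning rates must be non-negative (zero freezes the weights)")
        if self.V_window <= 0:
            raise ValueError("V_window must be positive")
        if self.rule not in ("reward_propagation", "pseudo_bp"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")

    def lr_at(self, epoch: int) -> float:
        """Step-wise schedule: multiply by lr_decay every lr_step_epochs."""
        return self.lr_decay ** (epoch // self.lr_step_epochs)


def surrogate_grad(V, V_th_eff, V_window: float):
    """Boxcar surrogate spike derivative: 1 iff |V - V_th_eff| < V_window."""
    if V_window <= 0:
        raise ValueError("V_window must be positive")
    return (np.abs(np.asarray(V, float) - np.asarray(V_th_eff, float)) < V_window).astype(float)


def make_reward_signal(label: int, n_classes: int, T: int) -> np.ndarray:
    """The repeated one-hot teaching signal: (T, n_classes), column `label` all ones."""
    if not (0 <= label < n_classes):
        raise ValueError(f"label {label} out of range for {n_classes} classes")
    if T < 1:
        raise ValueError("T must be at least 1")
    rp = np.zeros((T, n_classes))
    rp[:, label] = 1.0
    return rp


def reward_gradient(B: np.ndarray, rp_t: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Projected-target-minus-state difference ``B @ rp_t - h``."""
    B = np.asarray(B, float)
    rp_t = np.asarray(rp_t, float)
    h = np.asarray(h, float)
    if B.shape[1] != rp_t.shape[-1] or B.shape[0] != h.shape[-1]:
        raise ValueError(f"shape mismatch: B {B.shape}, RP_t {rp_t.shape}, h {h.shape}")
    return rp_t @ B.T - h


def make_feedback(model: SpikingNetwork, seed: int) -> FeedbackProjection:
    """Per-layer random feedback, entries uniform on +-1/sqrt(n_classes)."""
    n_classes = model.spec.n_classes
    lim = 1.0 / np.sqrt(n_classes)
    rng = np.random.default_rng([seed, 23])
    B = [rng.uniform(-lim, lim, size=(n, n_classes)) for n in model.spec.hidden_sizes]
    return FeedbackProjection(B=B, seed=seed)


def weight_update(grad_rp, surrogate, pre_activity, prev_spikes, W_r, mask, config: LearningConfig):
    """Plain (non-Adam) reward-propagation increments for one layer.

    Inputs are per-step traces of shape (T, ..., n): ``grad_rp`` the raw
    Grad_RP, ``surrogate`` the boxcar values, ``pre_activity`` the
    presynaptic drive (T, ..., pre) and ``prev_spikes`` the layer's own
    spikes from the previous step.  Returns ``(dW_f, dW_r)`` to be *added*
    to the weights; the direction descends ||h - B @ RP||^2 to first order
    and ``dW_r`` respects the mask.
    """
    E = np.asarray(grad_rp, float) * np.asarray(surrogate, float)  # gated target-minus-state
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("non-finite gated error in weight update")
    X = np.asarray(pre_activity, float)
    S_prev = np.asarray(prev_spikes, float)
    if E.ndim == 2:  # promote (T, n) to (T, 1, n)
        E, X, S_prev = E[:, None], X[:, None], S_prev[:, None]
        sg = np.asarray(surrogate, float)[:, None]
    else:
        sg = np.asarray(surrogate, float)
    # credit from step t+1 flowing back through the recurrent weights
    nxt = np.zeros_like(E)
    nxt[:-1] = sg[:-1] * (E[1:] @ np.asarray(W_r, float).T)
    batch = E.shape[1]
    dW_f = config.eta_f * np.einsum("tbi,tbj->ij", X, E) / batch
    dW_r = config.eta_r * np.einsum("tbi,tbj->ij", S_prev, E + nxt) * np.asarray(mask, float) / batch
    return dW_f, dW_r


class Adam:
    """Adaptive-moment estimation over a dict of named NumPy arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray],
             lr_scale: Optional[Dict[str, float]] = None) -> None:
        """Update ``params`` in place from ``grads`` (descent direction)."""
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for {k}")
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            scale = self.lr * (lr_scale.get(k, 1.0) if lr_scale else 1.0)
            params[k] -= scale * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _model_params(model: SpikingNetwork) -> Dict[str, np.ndarray]:
    p = {"W_out": model.W_out}
    for li, layer in enumerate(model.hidden):
        p[f"h{li}.W_f"] = layer.W_f
        p[f"h{li}.W_r"] = layer.W_r
    return p


def _readout_error(res: ForwardResult, Y: np.ndarray):
    """d(MSE)/d(out_mean) and the readout weight gradient."""
    n_c = Y.shape[1]
    err = 2.0 * (res.out_mean - Y) / n_c  # (B, n_classes)
    s_top_mean = res.traces[-1]["s"].mean(axis=0)  # (B, n_top)
    g_out = s_top_mean.T @ err / Y.shape[0]
    return err, g_out


def mse_loss(res: ForwardResult, Y: np.ndarray) -> float:
    return float(np.mean((res.out_mean - Y) ** 2))


def gradients_reward_propagation(model: SpikingNetwork, res: ForwardResult, Y: np.ndarray,
                                 feedback: FeedbackProjection, config: LearningConfig) -> Dict[str, np.ndarray]:
    """Per-layer parallel gradients from the repeated-label reward signal.

    The teaching signal is constant over the window (the label repeats), so
    the per-step projected target ``B @ RP_t`` is one vector per sample.
    Gradients are oriented for *descent*: they are the derivatives of
    ``0.5 * ||h - B @ RP||^2`` through the surrogate-gated linear model.
    """
    grads: Dict[str, np.ndarray] = {}
    batch = Y.shape[0]
    for li, layer in enumerate(model.hidden):
        tr = res.traces[li]
        sg = surrogate_grad(tr["h"], tr["theta"], config.V_window)  # (T, B, n)
        target = Y @ feedback.B[li].T  # (B, n)
        E = (tr["h"] - target[None]) * sg  # minus Grad_RP, gated
        nxt = np.zeros_like(E)
        nxt[:-1] = sg[:-1] * (E[1:] @ layer.W_r.T)
        grads[f"h{li}.W_f"] = np.einsum("tbi,tbj->ij", tr["x"], E) / batch
        grads[f"h{li}.W_r"] = np.einsum("tbi,tbj->ij", tr["s_prev"], E + nxt) * layer.mask / batch
    _, grads["W_out"] = _readout_error(res, Y)
    return grads


def gradients_pseudo_bp(model: SpikingNetwork, res: ForwardResult, Y: np.ndarray,
                        config: LearningConfig) -> Dict[str, np.ndarray]:
    """Layer-by-layer chained gradients with the boxcar surrogate.

    The readout error is propagated down through W_out and each W_f, with a
    depth-1 backward pass through time via W_r at every hidden layer.
    """
    grads: Dict[str, np.ndarray] = {}
    batch, T = Y.shape[0], res.n_steps
    err, grads["W_out"] = _readout_error(res, Y)
    d_s = np.broadcast_to((err @ model.W_out.T) / T, (T, batch, model.spec.hidden_sizes[-1])).copy()
    for li in range(len(model.hidden) - 1, -1, -1):
        layer = model.hidden[li]
        tr = res.traces[li]
        sg = surrogate_grad(tr["h"], tr["theta"], config.V_window)
        delta = np.zeros_like(d_s)
        for t in range(T - 1, -1, -1):
            back = delta[t + 1] @ layer.W_r.T if t + 1 < T else 0.0
            delta[t] = sg[t] * (d_s[t] + back)
        grads[f"h{li}.W_f"] = np.einsum("tbi,tbj->ij", tr["x"], delta) / batch
        grads[f"h{li}.W_r"] = np.einsum("tbi,tbj->ij", tr["s_prev"], delta) * layer.mask / batch
        if li > 0:
            d_s = delta @ layer.W_f.T
    return grads


def compute_gradients(model, res, Y, config, feedback=None):
    if config.rule == "reward_propagation":
        if feedback is None:
            raise ValueError("reward propagation needs a FeedbackProjection")
        return gradients_reward_propagation(model, res, Y, feedback, config)
    return gradients_pseudo_bp(model, res, Y, config)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    Y = np.zeros((len(y), n_classes))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def train_epoch(X: np.ndarray, y: np.ndarray, model: SpikingNetwork, config: LearningConfig,
                opt: Adam, epoch: int = 0, feedback: Optional[FeedbackProjection] = None) -> dict:
    """One pass over the data in shuffled mini-batches; updates the model in place.

    Returns mean loss, training accuracy and mean spike rate for the epoch.
    Fully deterministic given (config.seed, epoch, data, model state).
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    n_classes = model.spec.n_classes
    rng = np.random.default_rng([config.seed, 31, epoch])
    order = rng.permutation(len(X))
    params = _model_params(model)
    lr_scale = {k: (config.eta_r if k.endswith(".W_r") else config.eta_f) for k in params}
    opt.lr = config.lr_at(epoch)

    losses, correct, rates = [], 0, []
    for start in range(0, len(X), config.batch_size):
        idx = order[start:start + config.batch_size]
        Y = _one_hot(y[idx], n_classes)
        res = forward_sequence(X[idx], model)
        loss = mse_loss(res, Y)
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged")
        grads = compute_gradients(model, res, Y, config, feedback)
        opt.step(params, grads, lr_scale)
        for layer in model.hidden:  # re-impose sparseness after the update
            layer.W_r *= layer.mask
        losses.append(loss)
        correct += int(np.sum(res.predictions == y[idx]))
        rates.append(res.spike_rate)
    return {
        "loss": float(np.mean(losses)),
        "train_acc": correct / len(X),
        "spike_rate": float(np.mean(rates)),
    }


def fit(model: SpikingNetwork, X: np.ndarray, y: np.ndarray, config: LearningConfig,
        X_test: Optional[np.ndarray] = None, y_test: Optional[np.ndarray] = None,
        feedback: Optional[FeedbackProjection] = None, log_path=None):
    """Full training loop; returns the per-epoch history as a list of dicts.

    The feedback projection is derived from ``config.seed`` when not given.
    If ``log_path`` is set, the history is written as CSV (one row per epoch:
    epoch, loss, train_acc, test_acc, lr, spike_rate).
    """
    if feedback is None and config.rule == "reward_propagation":
        feedback = make_feedback(model, config.seed)
    opt = Adam(lr=config.eta_f)
    history = []
    for epoch in range(config.epochs):
        metrics = train_epoch(X, y, model, config, opt, epoch=epoch, feedback=feedback)
        row = {"epoch": epoch, "loss": metrics["loss"], "train_acc": metrics["train_acc"],
               "test_acc": np.nan, "lr": config.eta_f * config.lr_at(epoch),
               "spike_rate": metrics["spike_rate"]}
        if X_test is not None and y_test is not None:
            preds = forward_sequence(X_test, model).predictions
            row["test_acc"] = float(np.mean(preds == y_test))
        history.append(row)
    if log_path is not None:
        import pandas as pd

        pd.DataFrame(history).to_csv(log_path, index=False)
    return history
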