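"""Metrics, the noise-robustness protocol, and raster export.

The robustness statistic is the accuracy-noise ratio

    RobustRatio = Acc_noiseless,noise / Acc_noise,noise

where the numerator is the accuracy of a model trained on clean data and
tested on corrupted data, and the denominator that of a model trained *and*
tested on corrupted data.  Two regimes are run per corruption proportion:
"noise-noise" (corrupt train and test) and "noiseless-noise" (corrupt the
test set only).  A dense non-spiking single-hidden-layer network of matched
width, trained with the same optimiser and loss on the flattened input,
serves as the minimal comparator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import fit_scale, stack_samples
from .learning import Adam, LearningConfig, fit
from .network import ModelSpec, SpikeRaster, SpikingNetwork, forward_sequence, init_weights
from .synthdata import SynthSpec, corrupt_dataset, generate_dataset

__all__ = [
    "RunMetrics",
    "RobustnessReport",
    "accuracy",
    "confusion_matrix",
    "robust_ratio",
    "evaluate_model",
    "DenseBaseline",
    "run_robustness_experiment",
    "export_raster",
    "read_raster",
]


@dataclass
class RunMetrics:
    accuracy: float
    loss: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = true label
    spike_rate: float


@dataclass
class RobustnessReport:
    """Per-seed, per-proportion robustness results for one model family."""

    model_tag: str
    proportions: List[float]
    acc_noise_noise: np.ndarray      # (n_seeds, n_proportions)
    acc_noiseless_noise: np.ndarray  # (n_seeds, n_proportions)

    @property
    def robust_ratio(self) -> np.ndarray:
        """Elementwise ratio; NaN marks cells with a zero denominator."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.acc_noiseless_noise / self.acc_noise_noise
        return np.where(self.acc_noise_noise > 0, r, np.nan)

    def median_ratio(self) -> np.ndarray:
        return np.nanmedian(self.robust_ratio, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si in range(self.acc_noise_noise.shape[0]):
            for pi, p in enumerate(self.proportions):
                rows.append({
                    "model": self.model_tag, "seed_index": si, "proportion": p,
                    "acc_noise_noise": self.acc_noise_noise[si, pi],
                    "acc_noiseless_noise": self.acc_noiseless_noise[si, pi],
                    "robust_ratio": self.robust_ratio[si, pi],
                })
        return pd.DataFrame(rows)


def accuracy(predictions, labels) -> float:
    """Fraction of correctly identified samples."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be non-empty and of equal length")
    return float(np.mean(predictions == labels))


def confusion_matrix(predictions, labels, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(labels), np.asarray(predictions)):
        cm[t, p] += 1
    return cm


def robust_ratio(acc_noiseless_noise: float, acc_noise_noise: float) -> float:
    """The accuracy-noise ratio; undefined (error) for a zero denominator."""
    if acc_noise_noise <= 0:
        raise ZeroDivisionError("RobustRatio undefined: noise-noise accuracy is zero")
    return acc_noiseless_noise / acc_noise_noise


def evaluate_model(model: SpikingNetwork, X: np.ndarray, y: np.ndarray) -> RunMetrics:
    res = forward_sequence(X, model)
    n_c = model.spec.n_classes
    Y = np.zeros((len(y), n_c))
    Y[np.arange(len(y)), y] = 1.0
    preds = res.predictions
    return RunMetrics(
        accuracy=accuracy(preds, y),
        loss=float(np.mean((res.out_mean - Y) ** 2)),
        confusion=confusion_matrix(preds, y, n_c),
        spike_rate=res.spike_rate,
    )


class DenseBaseline:
    """Matched-width non-spiking comparator: flatten -> tanh hidden -> linear.

    Trained with the same loss (MSE against one-hot) and optimiser (Adam)
    as the spiking models, on the same scaled data.
    """

    def __init__(self, n_inputs: int, n_hidden: int, n_classes: int, seed: int):
        rng = np.random.default_rng([seed, 57])
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(n_inputs), (n_inputs, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), (n_hidden, n_classes))
        self.b2 = np.zeros(n_classes)
        self.n_classes = n_classes

    def _forward(self, Xf: np.ndarray):
        H = np.tanh(Xf @ self.W1 + self.b1)
        return H, H @ self.W2 + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, out = self._forward(X.reshape(len(X), -1))
        return np.argmax(out, axis=1)

    def fit(self, X: np.ndarray, y: np.ndarray, config: LearningConfig) -> None:
        Xf = X.reshape(len(X), -1)
        Y = np.zeros((len(y), self.n_classes))
        Y[np.arange(len(y)), y] = 1.0
        opt = Adam(lr=config.eta_f)
        params = {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}
        for epoch in range(config.epochs):
            opt.lr = config.eta_f * config.lr_at(epoch)
            order = np.random.default_rng([config.seed, 61, epoch]).permutation(len(Xf))
            for start in range(0, len(Xf), config.batch_size):
                idx = order[start:start + config.batch_size]
                H, out = self._forward(Xf[idx])
                err = 2.0 * (out - Y[idx]) / self.n_classes / len(idx)
                dH = (err @ self.W2.T) * (1.0 - H * H)
                grads = {
                    "W2": H.T @ err, "b2": err.sum(axis=0),
                    "W1": Xf[idx].T @ dH, "b1": dH.sum(axis=0),
                }
                opt.step(params, grads)


def _train_snn(model_spec: ModelSpec, X, y, config: LearningConfig, seed: int) -> SpikingNetwork:
    model = init_weights(model_spec, seed)
    fit(model, X, y, dataclasses.replace(config, seed=seed))
    return model


def run_robustness_experiment(
    model_spec: ModelSpec,
    synth_spec: SynthSpec,
    noise_grid: Sequence[float] = (0.0, 0.1, 0.25, 0.5),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    config: Optional[LearningConfig] = None,
    baseline_hidden: Optional[int] = None,
):
    """Run both corruption regimes for the spiking model and the dense baseline.

    For each seed a fresh dataset is generated; for each corruption
    proportion the test set is corrupted (noiseless-noise uses the model
    trained on clean data — trained once per seed — while noise-noise
    retrains on an equally corrupted training set).  Returns a
    ``(snn_report, dense_report)`` pair.
    """
    if any(not (0.0 <= p <= 1.0) for p in noise_grid):
        raise ValueError("noise proportions must lie in [0, 1]")
    config = config or LearningConfig()
    baseline_hidden = baseline_hidden or model_spec.hidden_sizes[0]
    n_seeds, n_p = len(seeds), len(noise_grid)
    acc = {tag: {"nn": np.zeros((n_seeds, n_p)), "ln": np.zeros((n_seeds, n_p))}
           for tag in ("snn", "dense")}

    for si, seed in enumerate(seeds):
        train, test = generate_dataset(dataclasses.replace(synth_spec, seed=synth_spec.seed + seed))
        scalar = fit_scale(train)
        X_tr, y_tr = stack_samples(train, scalar)
        value_range = (0.0, float(max(X_tr.max(), 1.0)))

        clean_snn = _train_snn(model_spec, X_tr, y_tr, config, seed)
        clean_dense = DenseBaseline(X_tr[0].size, baseline_hidden, model_spec.n_classes, seed)
        clean_dense.fit(X_tr, y_tr, dataclasses.replace(config, seed=seed))

        for pi, p in enumerate(noise_grid):
            test_noisy = corrupt_dataset(test, p, value_range, seed=seed * 1000 + pi)
            X_te, y_te = stack_samples(test_noisy, scalar)

            acc["snn"]["ln"][si, pi] = accuracy(forward_sequence(X_te, clean_snn).predictions, y_te)
            acc["dense"]["ln"][si, pi] = accuracy(clean_dense.predict(X_te), y_te)

            if p == 0.0:
                acc["snn"]["nn"][si, pi] = acc["snn"]["ln"][si, pi]
                acc["dense"]["nn"][si, pi] = acc["dense"]["ln"][si, pi]
                continue
            train_noisy = corrupt_dataset(train, p, value_range, seed=seed * 1000 + 500 + pi)
            X_trn, y_trn = stack_samples(train_noisy, scalar)
            noisy_snn = _train_snn(model_spec, X_trn, y_trn, config, seed)
            acc["snn"]["nn"][si, pi] = accuracy(forward_sequence(X_te, noisy_snn).predictions, y_te)
            noisy_dense = DenseBaseline(X_trn[0].size, baseline_hidden, model_spec.n_classes, seed)
            noisy_dense.fit(X_trn, y_trn, dataclasses.replace(config, seed=seed))
            acc["dense"]["nn"][si, pi] = accuracy(noisy_dense.predict(X_te), y_te)

    grid = list(noise_grid)
    return (
        RobustnessReport("snn", grid, acc["snn"]["nn"], acc["snn"]["ln"]),
        RobustnessReport("dense", grid, acc["dense"]["nn"], acc["dense"]["ln"]),
    )


def export_raster(raster: SpikeRaster, path) -> Path:
    """Plain-text event list ``layer,neuron_id,time_ms,channel``, sorted by time."""
    path = Path(path)
    df = pd.DataFrame(raster.sorted_events(), columns=["layer", "neuron_id", "time_ms", "channel"])
    df.to_csv(path, index=False)
    return path


def read_raster(path) -> SpikeRaster:
    df = pd.read_csv(path)
    events = [(int(r.layer), int(r.neuron_id), float(r.time_ms), str(r.channel)) for r in df.itertuples()]
    return SpikeRaster(events)
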