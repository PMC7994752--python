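"""Layered recurrent spiking network: topology, forward pass, checkpoints.

Architecture: an analog (or binary-encoded) input layer, one or more hidden
layers of two-channel adaptive-threshold LIF neurons with masked sparse
recurrent connections *within* each hidden layer, and a non-spiking readout
that accumulates weighted hidden spikes over the simulation window.  The
class score vector is the accumulated readout; prediction is its argmax.

Time is unrolled frame by frame: at step t the feedforward channel receives
frame t through W_f while the recurrent channel receives the layer's own
spike vector from step t-1 through the masked W_r (one recurrent exchange
per feedforward step).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional

import numpy as np

from .dynamics import AdaptParams, NeuronParams, NeuronState, membrane_step
from .encoding import threshold_encode

__all__ = [
    "LayerTopology",
    "TimeConfig",
    "ModelSpec",
    "SpikingNetwork",
    "SpikeRaster",
    "ForwardResult",
    "make_sparse_mask",
    "init_weights",
    "forward_sequence",
    "save_model",
    "load_model",
]


@dataclass
class LayerTopology:
    """Weights of one hidden layer: W_f (pre x post), masked W_r (post x post)."""

    W_f: np.ndarray
    W_r: np.ndarray
    mask: np.ndarray
    density: float


@dataclass(frozen=True)
class TimeConfig:
    """Simulation window: T_ff feedforward steps, T_rec recurrent exchanges.

    The recurrent period advances in lockstep with the feedforward one, so
    T_rec = T_ff by default; T is the total window in ms (T_ff * dt).
    """

    T_ff: int = 39
    T_rec: int = 39
    T: float = 39.0

    def __post_init__(self) -> None:
        if self.T_ff < 1:
            raise ValueError("T_ff must be at least 1")
        if self.T_rec < 0:
            raise ValueError("T_rec must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """Construction-time description of a network.

    ``layer_sizes`` is (input, hidden..., n_classes); ``density`` is the
    recurrent connection fraction shared by all hidden layers.  The two
    ablation switches are independent: ``use_adaptive_threshold`` toggles the
    threshold adaptation (gamma -> 0) and ``use_recurrent`` removes the
    lateral drive entirely.  ``input_mode`` selects analog scaled input
    (default) or pre-thresholded binary spikes.
    """

    layer_sizes: tuple = (39, 500, 10)
    density: float = 0.5
    neuron: NeuronParams = NeuronParams()
    adapt: AdaptParams = AdaptParams()
    time: TimeConfig = TimeConfig()
    use_adaptive_threshold: bool = True
    use_recurrent: bool = True
    input_mode: str = "analog"

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 3:
            raise ValueError("need at least input, one hidden and output layer")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if self.input_mode not in ("analog", "binary"):
            raise ValueError("input_mode must be 'analog' or 'binary'")

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]

    @property
    def hidden_sizes(self) -> tuple:
        return self.layer_sizes[1:-1]


@dataclass
class SpikingNetwork:
    """An initialised model: spec, hidden-layer topologies, readout weights."""

    spec: ModelSpec
    hidden: List[LayerTopology]
    W_out: np.ndarray
    seed: int

    @property
    def neuron_effective(self) -> NeuronParams:
        """Neuron parameters with the adaptation switch applied."""
        if self.spec.use_adaptive_threshold:
            return self.spec.neuron
        return replace(self.spec.neuron, gamma=0.0)

    def copy(self) -> "SpikingNetwork":
        return SpikingNetwork(
            spec=self.spec,
            hidden=[LayerTopology(l.W_f.copy(), l.W_r.copy(), l.mask.copy(), l.density) for l in self.hidden],
            W_out=self.W_out.copy(),
            seed=self.seed,
        )


@dataclass
class SpikeRaster:
    """Spike events of one simulated sample: (layer, neuron_id, time_ms, channel)."""

    events: list  # tuples (layer: int, neuron_id: int, time_ms: float, channel: str)

    def sorted_events(self) -> list:
        return sorted(self.events, key=lambda e: (e[2], e[0], e[1], e[3]))


@dataclass
class ForwardResult:
    """Everything the learning rules and metrics need from one forward pass."""

    scores: np.ndarray      # (B, n_classes) accumulated readout
    out_mean: np.ndarray    # (B, n_classes) time-averaged readout
    traces: list            # per hidden layer: dict of (T, B, n) arrays
    raster: Optional[SpikeRaster]
    spike_count: float      # total hidden spikes in the batch
    n_steps: int
    n_hidden_neurons: int

    @property
    def predictions(self) -> np.ndarray:
        return np.argmax(self.scores, axis=1)

    @property
    def spike_rate(self) -> float:
        """Mean spikes per hidden neuron per step (spike count 0..2 per neuron-step)."""
        B = self.scores.shape[0]
        return float(self.spike_count / (self.n_steps * self.n_hidden_neurons * B))


def make_sparse_mask(n: int, density: float, seed: int) -> np.ndarray:
    """Bernoulli(density) binary mask of shape (n, n); self-connections allowed."""
    if not (0.0 <= density <= 1.0):
        raise ValueError(f"density must lie in [0, 1], got {density}")
    if n < 1:
        raise ValueError("layer width must be at least 1")
    rng = np.random.default_rng(seed)
    return (rng.random((n, n)) < density).astype(float)


def init_weights(spec: ModelSpec, seed: int) -> SpikingNetwork:
    """Zero-mean Gaussian weights with 1/sqrt(fan_in) scale; masked W_r."""
    rng = np.random.default_rng([seed, 7])
    hidden = []
    pre = spec.layer_sizes[0]
    for li, n in enumerate(spec.hidden_sizes):
        W_f = rng.normal(0.0, 1.0 / np.sqrt(pre), size=(pre, n))
        mask = make_sparse_mask(n, spec.density, int(np.random.SeedSequence([seed, 11, li]).generate_state(1)[0] % (2**31)))
        W_r = rng.normal(0.0, 1.0 / np.sqrt(n), size=(n, n)) * mask
        hidden.append(LayerTopology(W_f, W_r, mask, spec.density))
        pre = n
    W_out = rng.normal(0.0, 1.0 / np.sqrt(pre), size=(pre, spec.n_classes))
    return SpikingNetwork(spec=spec, hidden=hidden, W_out=W_out, seed=seed)


def forward_sequence(x: np.ndarray, model: SpikingNetwork, record_raster: bool = False) -> ForwardResult:
    """Unroll the network over a batch of spectrograms.

    ``x`` has shape (bands, frames) or (batch, bands, frames); the frame
    count must not exceed the feedforward window T_ff.  Returns accumulated
    class scores, per-layer traces (pre-reset potentials ``h``, effective
    thresholds ``theta``, spike vectors ``s``, previous-step spikes
    ``s_prev`` and presynaptic drive ``x``) and, optionally for a single
    sample, the spike raster.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("input must be (bands, frames) or (batch, bands, frames)")
    B, n_in, T = x.shape
    spec = model.spec
    if n_in != spec.layer_sizes[0]:
        raise ValueError(f"sample has {n_in} bands but the input layer expects {spec.layer_sizes[0]}")
    if T > spec.time.T_ff:
        raise ValueError(f"sample has {T} frames but the window is T_ff={spec.time.T_ff}")
    if record_raster and B != 1:
        raise ValueError("raster recording requires a single sample")

    params = model.neuron_effective
    adapt = spec.adapt
    dt = params.dt
    recurrent_on = spec.use_recurrent and spec.density > 0.0

    if spec.input_mode == "binary":
        x = threshold_encode(x, params.V_th)

    states = [NeuronState.zeros((B, n), params) for n in spec.hidden_sizes]
    s_prev = [np.zeros((B, n)) for n in spec.hidden_sizes]
    traces = [{k: [] for k in ("x", "h", "theta", "s", "s_prev", "S_f", "S_r")} for _ in spec.hidden_sizes]
    y_acc = np.zeros((B, spec.n_classes))
    events: list = []
    spike_count = 0.0

    for t in range(T):
        t_now = t * dt
        pre = x[:, :, t]
        for li, layer in enumerate(model.hidden):
            ff = pre @ layer.W_f
            rec = s_prev[li] @ layer.W_r if recurrent_on else np.zeros_like(s_prev[li])
            new_state = membrane_step(states[li], ff, rec, params, adapt, t_now)
            s_now = new_state.S_f + new_state.S_r
            tr = traces[li]
            tr["x"].append(pre)
            tr["h"].append(new_state.V_pre)
            tr["theta"].append(new_state.theta)
            tr["s"].append(s_now)
            tr["s_prev"].append(s_prev[li])
            tr["S_f"].append(new_state.S_f)
            tr["S_r"].append(new_state.S_r)
            if record_raster:
                for nid in np.flatnonzero(new_state.S_f[0]):
                    events.append((li, int(nid), t_now, "ff"))
                for nid in np.flatnonzero(new_state.S_r[0]):
                    events.append((li, int(nid), t_now, "rec"))
            spike_count += float(s_now.sum())
            states[li] = new_state
            s_prev[li] = s_now
            pre = s_now
        y_acc = y_acc + pre @ model.W_out

    stacked = [{k: np.stack(v) for k, v in tr.items()} for tr in traces]
    return ForwardResult(
        scores=y_acc,
        out_mean=y_acc / T,
        traces=stacked,
        raster=SpikeRaster(events) if record_raster else None,
        spike_count=spike_count,
        n_steps=T,
        n_hidden_neurons=sum(spec.hidden_sizes),
    )


# --- checkpointing ------------------------------------------------------------

def _spec_to_json(spec: ModelSpec) -> str:
    d = {
        "layer_sizes": list(spec.layer_sizes),
        "density": spec.density,
        "neuron": dataclasses.asdict(spec.neuron),
        "adapt": dataclasses.asdict(spec.adapt),
        "time": dataclasses.asdict(spec.time),
        "use_adaptive_threshold": spec.use_adaptive_threshold,
        "use_recurrent": spec.use_recurrent,
        "input_mode": spec.input_mode,
    }
    return json.dumps(d)


def _spec_from_json(s: str) -> ModelSpec:
    d = json.loads(s)
    return ModelSpec(
        layer_sizes=tuple(d["layer_sizes"]),
        density=d["density"],
        neuron=NeuronParams(**d["neuron"]),
        adapt=AdaptParams(**d["adapt"]),
        time=TimeConfig(**d["time"]),
        use_adaptive_threshold=d["use_adaptive_threshold"],
        use_recurrent=d["use_recurrent"],
        input_mode=d["input_mode"],
    )


def save_model(model: SpikingNetwork, path) -> None:
    """Single-archive checkpoint: weights, masks, params and seed; lossless."""
    arrays = {"W_out": model.W_out}
    for li, layer in enumerate(model.hidden):
        arrays[f"h{li}_W_f"] = layer.W_f
        arrays[f"h{li}_W_r"] = layer.W_r
        arrays[f"h{li}_mask"] = layer.mask
    np.savez(
        path,
        spec_json=np.array(_spec_to_json(model.spec)),
        seed=np.array(model.seed),
        n_hidden_layers=np.array(len(model.hidden)),
        **arrays,
    )


def load_model(path) -> SpikingNetwork:
    with np.load(path, allow_pickle=False) as z:
        spec = _spec_from_json(str(z["spec_json"]))
        n_layers = int(z["n_hidden_layers"])
        hidden = [
            LayerTopology(z[f"h{li}_W_f"], z[f"h{li}_W_r"], z[f"h{li}_mask"], spec.density)
            for li in range(n_layers)
        ]
        return SpikingNetwork(spec=spec, hidden=hidden, W_out=z["W_out"], seed=int(z["seed"]))
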