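# spikeloop

Recurrent spiking neural networks with adaptive firing thresholds, sparse
lateral loops, and global **reward-propagation** learning — a NumPy library
and CLI for researchers studying biologically-plausible alternatives to
backpropagation on sequential (spectrogram-like) classification, with a
built-in noise-robustness protocol.

## The model in brief

Hidden neurons are leaky integrate-and-fire units with two membrane
channels — feedforward `V_f` and recurrent `V_r` — and an adaptive
threshold `a(t)`:

    da/dt = (α − 1) a + β (S_f + S_r),     fire when V_f + V_r ≥ V_th + γ a

so sustained firing raises the threshold toward the equilibrium
`a* = β/(1−α)·S` (0, 1 or 2 for the defaults α = 0.9, β = 0.1).  Recurrent
connections within a hidden layer are restricted by a fixed Bernoulli mask
of chosen density.  Training avoids layer-by-layer error backpropagation:
the repeated one-hot label `RP_t` is projected through a fixed random
matrix `B` directly into each hidden layer, and weights follow the
surrogate-gated error `B·RP_t − h(t)` (boxcar surrogate, width `V_window`).
A truncated pseudo-BP rule is included as the comparator, plus a dense
non-spiking baseline for the robustness contrast

    RobustRatio = Acc(train clean, test noisy) / Acc(train noisy, test noisy).

Licensed speech corpora are not required: a deterministic generator
produces labelled spectrogram-like datasets (smooth per-class band×frame
templates + noise) with controllable difficulty, and a corruption operator
replaces a chosen fraction of entries with uniform noise.

See `docs/methods.md` for the full model, parameter table and design notes.

## Worked example

Generate an easy 4-class synthetic task, train a 39→200→4 network with
reward propagation (50% recurrent density, adaptive thresholds on), and
evaluate:

```bash
spikeloop gen-data --out-dir demo/data --n-classes 4 --samples-per-class 25 \
    --noise-sd 0.05 --seed 0
spikeloop train --data-dir demo/data --out-dir demo/run \
    --hidden 200 --epochs 30 --seed 0
spikeloop eval --model demo/run/model.npz --data-dir demo/data \
    --out-dir demo/eval --raster
```

which prints

```
wrote 100 train / 100 test samples to demo/data
{"final_train_acc": 0.92, "final_test_acc": 0.96, "final_loss": 0.20181924718362682, "epochs": 30, "rule": "reward_propagation"}
accuracy=0.9600 loss=0.200612 spike_rate=0.0126
```

`final_train_acc`/`accuracy` are fractions of correctly identified samples
(train and held-out test); `spike_rate` is mean spikes per hidden neuron
per millisecond step — it falls over training as threshold adaptation
sparsifies the code (see `demo/run/train_log.csv` for the per-epoch
trajectory).  `demo/eval/raster.csv` holds the spike events
(`layer,neuron_id,time_ms,channel`) of the first test sample.

The same pipeline is available as library calls
(`generate_dataset`, `init_weights`, `fit`, `evaluate_model`,
`run_robustness_experiment`); `spikeloop robustness` runs the
noise-noise / noiseless-noise sweep against the dense baseline, and
`spikeloop simulate-neuron` dumps a single-neuron trace as CSV.

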