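# Methods

## Model

Each hidden neuron is a leaky integrate-and-fire (LIF) unit with **two
membrane channels** and an **adaptive firing threshold**.  The feedforward
channel `V_f` integrates input from the previous layer and leaks toward the
resting potential `V_rest`; the recurrent channel `V_r` integrates lateral
spikes from the same hidden layer (through a fixed sparse mask) without
leak.  Per time step of length `dt` (forward Euler):

    C dV_f/dt = -g (V_f - V_rest) (1 - S) + Σ_j W_f[j,i] X_j(t)
    C dV_r/dt =                              Σ_j W_r[j,i] S_j(t-1)

where `S = S_f + S_r ∈ {0,1,2}` is the neuron's spike count on the previous
step (the leak is gated off on the step after a spike, while the reset
holds).  The *total* potential `V = V_f + V_r` is compared against the
adapted threshold

    θ(t) = V_th + γ a(t),        da/dt = (α − 1) a + β (S_f + S_r)

Under constant drive the threshold variable relaxes to the closed-form
equilibrium `a* = β/(1−α) · S`; with the defaults α = 0.9, β = 0.1 that is
0, 1 or 2 for sustained spiking on zero, one or two channels.  A crossing
(`V ≥ θ`, tested with ≥ since exact floating-point equality is measure
zero) resets the crossed channel to `V_reset`, sets its binary flag, and
starts that channel's refractory clock; during the refractory window
`τ_ref` the channel is clamped at `V_reset`, its input discarded, and the
flag is *not* re-raised.

One time step runs two sub-steps, feedforward first then recurrent, so each
channel can fire at most once per step and `S ∈ {0,1,2}` is preserved.  The
recurrent exchange advances in lockstep with the feedforward unrolling:
lateral input at step `t` is the layer's own spike vector from step `t−1`,
which keeps memory linear in the window length.

A note on the leak term: the single-channel membrane equation is sometimes
written with a `+g(V − V_rest)` term, which is anti-leaky (rest would be
unstable).  We implement the conventional decay toward rest; this is the
only reading under which the neuron is "leaky" and silence is a fixed
point.

Because applying an adaptation current `−γa` inside the membrane ODE and
raising the threshold to `V_th + γa` coincide at the crossing condition, we
implement the threshold form only — it avoids counting the same mechanism
twice.

### Readout

The output layer does not spike: per-class scores are the sum over the
window of hidden spike counts weighted by `W_out` (free integration, no
reset), and the prediction is the argmax.  The training loss is the MSE
between the *time-averaged* readout and the one-hot label; an MSE on this
smooth accumulation is better behaved than one on sparse spike counts.

## Learning rules

**Reward propagation.**  The teaching signal `RP_t` is the one-hot label
repeated at every step.  A fixed random feedback matrix `B` (one per hidden
layer, entries uniform on ±1/√n_classes, never trained) projects it into
the layer's state space, giving the per-step error

    Grad_RP(t) = B·RP_t − h(t)

with `h(t)` the layer's pre-reset membrane potential vector (our reading of
the "layer state"; spikes and time-averages are the alternatives).  The
error is gated elementwise by the boxcar surrogate derivative

    ∂S/∂V ≈ 1 if |V − θ| < V_window else 0     (strict inequality)

and turned into weight increments by the outer product with the presynaptic
activity (feedforward) or the previous step's own spikes (recurrent).  The
recurrent error additionally receives a one-step truncated backward flow of
the next step's gated error through `W_r` — minimal recurrent credit
assignment; deeper truncation would couple steps at quadratic cost for
little benefit at 39-step windows.  The update direction is chosen to
descend `‖h − B·RP‖²` to first order.  Since each layer's update depends
only on `(B_l, RP, its own traces)`, hidden layers update independently —
the order-invariance property the tests verify.  The readout is trained by
the local delta rule on the MSE loss.

**Pseudo-BP comparator.**  Identical forward pass; the readout error is
chained down layer-by-layer through `W_out` and `W_f` with the same boxcar
surrogate standing in for the spike derivative, and a depth-1 backward pass
through time via `W_r` at each hidden layer (truncated BPTT, not full
unrolling — full BPTT is out of scope by design).

Both rules feed their gradients to Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
batch size 50, and the recurrent matrix is re-masked after every optimiser
step so the sparseness pattern is an invariant of training, not just of
initialisation.  The learning rate starts at `eta_f` (default 1e-3; `eta_r`
scales the recurrent weights independently) and halves every 100 epochs —
a stepwise schedule with deliberately coarse steps, since the runs in the
test protocol are short.

## Parameters and defaults

| parameter | default | units | role |
|---|---|---|---|
| C | 1.0 | μF/cm² | membrane capacitance |
| g | 0.2 | nS | leak conductance (feedforward channel) |
| V_rest, V_reset | 0.0 | mV | resting / reset potential |
| V_th | 0.5 | mV | base firing threshold |
| τ_ref | 1.0 | ms | per-channel refractory period |
| dt | 1.0 | ms | Euler step (one spectrogram frame per step) |
| γ | 1.0 | – | adaptation coupling (0 disables neuronal plasticity) |
| α, β | 0.9, 0.1 | – | threshold decay / spike drive |
| density | 0.5 | – | fraction of permitted recurrent connections |
| V_window | 0.5 | mV | boxcar surrogate half-width |
| eta_f, eta_r | 1e-3 | – | Adam learning rates (ff / recurrent) |
| batch size | 50 | – | mini-batch size |

The biophysical units are nominal: the model freely mixes conductance-like
and dimensionless quantities, and no unit calibration is attempted — values
are taken as given.  Note that with dt = τ_ref = 1 ms the refractory clamp
is vacuous (a neuron may fire on consecutive steps); tests that exercise
the refractory law therefore use τ_ref ≥ 2 ms.

Learning rates of zero are accepted and freeze the corresponding weights —
useful for ablations — even though ordinary training requires them
positive.

## Input encoding

Spectrograms (bands × frames; 39 × 39 in the reference geometry) are
rescaled by a single dataset-level scalar — by default the training set's
99th-percentile energy maps to 1.0 — and fed frame-by-frame, one frame per
time step.  By default the scaled *analog* values drive the first layer and
spiking happens at the neurons; a model switch (`input_mode="binary"`)
instead thresholds the input against `V_th` first (value > threshold → 1,
strict).

## Synthetic data

The generator emulates the statistical shape of spectrogram classification:
one fixed smooth positive template per class (white noise low-pass filtered
with a Gaussian kernel of σ = side/8, thresholded to the top
`template_sparsity` fraction of cells, peak-normalised), plus i.i.d.
Gaussian within-class perturbation of scale `noise_sd`, clipped at zero
energy.  Smooth (band-limited) templates spread class evidence across
frames, so the recurrent channel has temporal structure to exploit — white
noise templates would make every frame independently decisive.  The "easy"
regime (4 classes, noise_sd = 0.05) is verified separable by a
nearest-template classifier before any network sees it.

What the generator does *not* emulate: variable-length utterances, temporal
warping, correlated (channel or babble) noise, speaker variability, or the
energy statistics of real filterbanks.  Passing tests therefore demonstrate
that the dynamics, learning rules and protocol behave as specified — not
that any particular accuracy transfers to real speech corpora.

The corruption operator replaces a fraction `proportion` of matrix entries
(chosen uniformly without replacement, exactly `round(p·n)` of them) with
uniform draws over the data's value range.  The robustness protocol runs
two regimes per proportion — *noise-noise* (corrupt train and test) and
*noiseless-noise* (corrupt test only) — and reports

    RobustRatio = Acc_noiseless,noise / Acc_noise,noise

undefined (NaN in reports, an error in the scalar helper) where the
denominator is zero.  RobustRatio ≤ 1 is *not* an invariant: training under
noise can help or hurt.  The dense comparator is a matched-width
single-hidden-layer tanh network on the flattened input, trained with the
same Adam/MSE/schedule — a minimal non-spiking stand-in, not a
reproduction of any published baseline.

## Numerical and design choices

- Forward Euler at dt = 1 ms everywhere; the spectrogram frame rate sets
  the clock, so finer integrators would change nothing observable.
- Crossing uses `V ≥ θ`; surrogate and input encodings use strict
  comparisons at their boundaries.
- The sparse mask is pure Bernoulli including the diagonal
  (self-connections are not structurally excluded).
- Weights are zero-mean Gaussian with 1/√fan-in scale; the mask is applied
  at initialisation and after every update.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; identical seeds give bitwise-identical datasets, models
  and training runs.
- Protocol sizes used by the test suite: 200 hidden neurons, 30 epochs and
  100 training samples for the learnability check; 5 seeds for the
  robustness contrast; 20 seeds for the monotonicity and descent checks.
  These sizes make the statistical claims (medians, sign tests) stable
  while keeping the whole suite around a minute of CPU.

## Known limitations

- Descent of the reward-propagation update is first-order and
  surrogate-gated, not a guarantee: spiking discontinuities mean a small
  step can occasionally increase the batch MSE (the suite checks a sign
  test across seeds, not per-seed descent).
- The two-phase schedule (recurrent exchange each feedforward step) is one
  reading of a feedforward/recurrent period split; schedules with separate
  phase lengths would need a different unrolling.
- Only shallow architectures are exercised end-to-end; the layer
  abstraction supports deeper recurrent stacks (and is tested to run), but
  no claim is made about their trainability.
- The per-phoneme scoring used for sentence-level corpora is out of scope;
  accuracy is always per-sample.
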