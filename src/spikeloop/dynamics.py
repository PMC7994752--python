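"""Two-channel adaptive-threshold leaky integrate-and-fire (LIF) dynamics.

Each hidden neuron carries two membrane channels — a feedforward potential
``V_f`` driven by the previous layer and a recurrent potential ``V_r`` driven
by lateral spikes from the same layer — plus an adaptive-threshold variable
``a`` that integrates the neuron's own spiking:

    da/dt = (alpha - 1) * a + beta * (S_f + S_r)

so that under sustained drive ``a`` relaxes to the equilibrium
``a* = beta / (1 - alpha) * (S_f + S_r)`` and the effective firing threshold
rises to ``V_th + gamma * a`` (spike-frequency adaptation).

All state-update functions are vectorised: state fields may be arrays of any
shape (neurons, or batch x neurons) and are updated elementwise with forward
Euler at step ``dt``.  A time step runs two sub-steps — feedforward first,
then recurrent — so a neuron can emit at most one spike per channel per step
and the total spike count ``S = S_f + S_r`` lies in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "NeuronParams",
    "AdaptParams",
    "NeuronState",
    "threshold_step",
    "threshold_equilibrium",
    "effective_threshold",
    "membrane_step",
]

#: sentinel "never spiked" last-spike time (any t_now - NEVER exceeds tau_ref)
NEVER = -np.inf


@dataclass(frozen=True)
class NeuronParams:
    """Scalar constants of the LIF membrane and reset mechanism.

    Defaults are the values used throughout: C = 1 uF/cm^2, g = 0.2 nS,
    V_th = 0.5 mV, tau_ref = 1 ms, dt = 1 ms, gamma = 1 (adaptation coupling).
    """

    C: float = 1.0
    g: float = 0.2
    V_rest: float = 0.0
    V_reset: float = 0.0
    V_th: float = 0.5
    tau_ref: float = 1.0
    dt: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.tau_ref < 0:
            raise ValueError(f"tau_ref must be non-negative, got {self.tau_ref}")
        if self.V_reset > self.V_th:
            raise ValueError("V_reset must not exceed V_th")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")


@dataclass(frozen=True)
class AdaptParams:
    """Adaptive-threshold ODE coefficients: decay ``alpha``, spike drive ``beta``."""

    alpha: float = 0.9
    beta: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1) for stability, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


@dataclass
class NeuronState:
    """Per-neuron dynamic variables (arrays broadcast over any leading shape).

    ``V_pre`` and ``theta`` are diagnostics filled in by :func:`membrane_step`:
    the total potential the neuron reached *before* any reset in the step, and
    the effective threshold it was compared against.  Learning rules gate on
    these rather than the post-reset potentials.
    """

    V_f: np.ndarray
    V_r: np.ndarray
    a: np.ndarray
    S_f: np.ndarray
    S_r: np.ndarray
    t_last_f: np.ndarray
    t_last_r: np.ndarray
    V_pre: Optional[np.ndarray] = field(default=None, repr=False)
    theta: Optional[np.ndarray] = field(default=None, repr=False)

    @classmethod
    def zeros(cls, shape, params: NeuronParams) -> "NeuronState":
        """Resting state: both channels at V_rest, no adaptation, no spike history."""
        z = np.full(shape, float(params.V_rest))
        return cls(
            V_f=z.copy(),
            V_r=z.copy(),
            a=np.zeros(shape),
            S_f=np.zeros(shape),
            S_r=np.zeros(shape),
            t_last_f=np.full(shape, NEVER),
            t_last_r=np.full(shape, NEVER),
        )


def threshold_step(a, spikes_total, adapt: AdaptParams, dt: float):
    """One forward-Euler update of the adaptive-threshold ODE.

    Returns ``a + dt * ((alpha - 1) * a + beta * spikes_total)``.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise FloatingPointError("adaptive threshold variable is non-finite (diverged)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return a + dt * ((adapt.alpha - 1.0) * a + adapt.beta * np.asarray(spikes_total, dtype=float))


def threshold_equilibrium(adapt: AdaptParams, spikes_total):
    """Closed-form fixed point ``a* = beta / (1 - alpha) * spikes_total``.

    Raises if ``alpha >= 1`` (the ODE then has no stable equilibrium).  The
    AdaptParams constructor already enforces alpha < 1; this guard protects
    callers constructing parameters by other means.
    """
    if adapt.alpha >= 1.0:
        raise ValueError("no stable equilibrium for alpha >= 1")
    return adapt.beta / (1.0 - adapt.alpha) * np.asarray(spikes_total, dtype=float)


def effective_threshold(state: NeuronState, params: NeuronParams):
    """Adapted firing threshold ``V_th + gamma * a``."""
    return params.V_th + params.gamma * np.asarray(state.a, dtype=float)


def _integrate_channel(V, current, refractory, leak_gate, params: NeuronParams, leaky: bool):
    """Euler-integrate one channel; refractory entries are clamped at V_reset."""
    if leaky:
        dV = (-params.g * (V - params.V_rest) * leak_gate + current) * (params.dt / params.C)
    else:
        dV = current * (params.dt / params.C)
    return np.where(refractory, params.V_reset, V + dV)


def membrane_step(
    state: NeuronState,
    ff_current,
    rec_current,
    params: NeuronParams,
    adapt: AdaptParams,
    t_now: float,
) -> NeuronState:
    """Advance the two-channel neuron by one time step of length ``dt``.

    The step runs a feedforward sub-step then a recurrent sub-step.  In each:
    a channel within its refractory window is clamped at ``V_reset`` and its
    input discarded; otherwise the channel potential is Euler-integrated (the
    feedforward channel leaks toward ``V_rest``, gated off while the neuron
    spiked on the previous step; the recurrent channel integrates freely).
    The *total* potential ``V_f + V_r`` is compared against the adapted
    threshold ``V_th + gamma * a``; a crossing sets that sub-step's spike
    flag, records the spike time and resets the crossed channel.  Finally the
    adaptive threshold integrates the step's total spike count.
    """
    ff = np.asarray(ff_current, dtype=float)
    rec = np.asarray(rec_current, dtype=float)
    if not (np.all(np.isfinite(ff)) and np.all(np.isfinite(rec))):
        raise FloatingPointError("non-finite input current")
    if t_now < 0:
        raise ValueError("t_now must be non-negative")

    theta = effective_threshold(state, params)
    # leak is suppressed on the step after a spike (reset holds, no decay drive)
    spiked_prev = np.minimum(state.S_f + state.S_r, 1.0)
    leak_gate = 1.0 - spiked_prev

    # --- feedforward sub-step ---
    ref_f = (t_now - state.t_last_f) < params.tau_ref
    V_f = _integrate_channel(state.V_f, ff, ref_f, leak_gate, params, leaky=True)
    V_f_pre = V_f.copy()
    fire_f = (V_f + state.V_r >= theta) & ~ref_f
    S_f = fire_f.astype(float)
    V_f = np.where(fire_f, params.V_reset, V_f)
    t_last_f = np.where(fire_f, t_now, state.t_last_f)

    # --- recurrent sub-step (sees the post-reset feedforward potential) ---
    ref_r = (t_now - state.t_last_r) < params.tau_ref
    V_r = _integrate_channel(state.V_r, rec, ref_r, leak_gate, params, leaky=False)
    V_r_pre = V_r.copy()
    fire_r = (V_f + V_r >= theta) & ~ref_r
    S_r = fire_r.astype(float)
    V_r = np.where(fire_r, params.V_reset, V_r)
    t_last_r = np.where(fire_r, t_now, state.t_last_r)

    a = threshold_step(state.a, S_f + S_r, adapt, params.dt)

    return NeuronState(
        V_f=V_f,
        V_r=V_r,
        a=a,
        S_f=S_f,
        S_r=S_r,
        t_last_f=t_last_f,
        t_last_r=t_last_r,
        V_pre=V_f_pre + V_r_pre,
        theta=theta,
    )
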