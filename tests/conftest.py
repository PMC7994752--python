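import numpy as np
import pytest

from spikeloop import (
    AdaptParams,
    LearningConfig,
    ModelSpec,
    NeuronParams,
    TimeConfig,
    easy_spec,
    fit_scale,
    generate_dataset,
    init_weights,
    stack_samples,
)


@pytest.fixture
def params():
    """Reference neuron constants: C=1, g=0.2, V_th=0.5, tau_ref=1, dt=1, gamma=1."""
    return NeuronParams()


@pytest.fixture
def adapt():
    """Reference adaptation coefficients alpha=0.9, beta=0.1."""
    return AdaptParams()


def small_model(n_in=10, n_hidden=20, n_classes=4, density=0.5, seed=0, T=10, **kwargs):
    spec = ModelSpec(
        layer_sizes=(n_in, n_hidden, n_classes),
        density=density,
        time=TimeConfig(T_ff=T, T_rec=T, T=float(T)),
        **kwargs,
    )
    return init_weights(spec, seed)


@pytest.fixture
def tiny_model():
    return small_model()


@pytest.fixture(scope="session")
def easy_task():
    """The separable 4-class synthetic task, scaled, as (X_train, y_train, X_test, y_test)."""
    spec = easy_spec(seed=0)
    train, test = generate_dataset(spec)
    scalar = fit_scale(train)
    X_tr, y_tr = stack_samples(train, scalar)
    X_te, y_te = stack_samples(test, scalar)
    return X_tr, y_tr, X_te, y_te


@pytest.fixture
def fast_config():
    return LearningConfig(epochs=2, batch_size=20, seed=0)


def random_input_run(model, n_samples=3, seed=0, lo=0.0, hi=1.0):
    """Forward pass on uniform random spectrogram-like input."""
    from spikeloop import forward_sequence

    rng = np.random.default_rng(seed)
    n_in = model.spec.layer_sizes[0]
    T = model.spec.time.T_ff
    X = rng.uniform(lo, hi, (n_samples, n_in, T))
    return forward_sequence(X, model)
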