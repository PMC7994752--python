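"""Synthetic spectrogram-like datasets with controllable difficulty.

Stands in for licensed speech corpora: each class gets a fixed smooth
band x frame energy template (a low-pass-filtered random field, so class
evidence is spread over frames the way formant tracks spread over a
spectrogram), and each sample is its class template plus independent
zero-mean Gaussian perturbation, clipped at zero energy.

Also provides the uniform-noise corruption operator used by the robustness
protocol: a chosen fraction of matrix entries is replaced by independent
uniform draws over the data's value range.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .encoding import SpectrogramSample

__all__ = [
    "SynthSpec",
    "NoiseSpec",
    "generate_dataset",
    "add_uniform_noise",
    "corrupt_dataset",
    "nearest_template_predict",
    "easy_spec",
]


@dataclasses.dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    Defaults mirror the reference task's geometry: 39 bands x 39 frames,
    10 classes.  ``template_sparsity`` is the fraction of band-time cells
    carrying class energy; ``noise_sd`` is the within-class perturbation
    scale relative to a unit template peak.
    """

    n_classes: int = 10
    samples_per_class: int = 25
    n_bands: int = 39
    n_frames: int = 39
    template_sparsity: float = 0.25
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_bands < 1 or self.n_frames < 1:
            raise ValueError("bands and frames must be at least 1")
        if not (0.0 < self.template_sparsity <= 1.0):
            raise ValueError("template_sparsity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Corruption operator parameters: fraction of entries replaced, and seed."""

    proportion: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"proportion must lie in [0, 1], got {self.proportion}")


def make_templates(spec: SynthSpec) -> np.ndarray:
    """One smooth positive template per class, shape (n_classes, bands, frames).

    White noise is low-pass filtered (Gaussian kernel, sigma ~ an eighth of
    the matrix side) and only the top ``template_sparsity`` fraction of cells
    is kept, rescaled to peak 1.
    """
    rng = np.random.default_rng([spec.seed, 101])
    sigma = max(1.0, min(spec.n_bands, spec.n_frames) / 8.0)
    templates = np.empty((spec.n_classes, spec.n_bands, spec.n_frames))
    for c in range(spec.n_classes):
        field = ndimage.gaussian_filter(rng.standard_normal((spec.n_bands, spec.n_frames)), sigma)
        cut = np.quantile(field, 1.0 - spec.template_sparsity)
        tpl = np.clip(field - cut, 0.0, None)
        peak = tpl.max()
        templates[c] = tpl / peak if peak > 0 else tpl
    return templates


def _draw_set(templates: np.ndarray, spec: SynthSpec, rng: np.random.Generator, tag: str):
    samples = []
    for c in range(spec.n_classes):
        for k in range(spec.samples_per_class):
            noise = rng.normal(0.0, spec.noise_sd, templates[c].shape) if spec.noise_sd > 0 else 0.0
            values = np.clip(templates[c] + noise, 0.0, None)
            samples.append(SpectrogramSample(values, c, f"{tag}_c{c}_{k:04d}"))
    return samples


def generate_dataset(spec: SynthSpec):
    """Deterministic ``(train, test)`` sample lists, ``samples_per_class`` each per set."""
    templates = make_templates(spec)
    train = _draw_set(templates, spec, np.random.default_rng([spec.seed, 202]), "train")
    test = _draw_set(templates, spec, np.random.default_rng([spec.seed, 303]), "test")
    return train, test


def add_uniform_noise(sample: SpectrogramSample, noise: NoiseSpec, value_range) -> SpectrogramSample:
    """Replace a fraction of entries with uniform draws on ``[lo, hi]``.

    Exactly ``round(proportion * n_entries)`` entries, chosen uniformly
    without replacement, are overwritten; the label is preserved.
    """
    lo, hi = value_range
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    values = sample.values.copy()
    n = values.size
    k = int(round(noise.proportion * n))
    if k > 0:
        rng = np.random.default_rng(noise.seed)
        idx = rng.choice(n, size=k, replace=False)
        values.ravel()[idx] = rng.uniform(lo, hi, size=k)
    return SpectrogramSample(values, sample.label, sample.sample_id)


def corrupt_dataset(samples, proportion: float, value_range, seed: int):
    """Corrupt every sample, each with its own deterministic sub-seed."""
    return [
        add_uniform_noise(s, NoiseSpec(proportion, seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))), value_range)
        for i, s in enumerate(samples)
    ]


def nearest_template_predict(samples, templates: np.ndarray) -> np.ndarray:
    """Classify by smallest Euclidean distance to a class template.

    A deliberately simple reference classifier: if it is perfect, the task is
    linearly easy; its degradation with noise tracks task difficulty.
    """
    preds = np.empty(len(samples), dtype=int)
    flat = templates.reshape(templates.shape[0], -1)
    for i, s in enumerate(samples):
        d = np.linalg.norm(flat - s.values.ravel()[None, :], axis=1)
        preds[i] = int(np.argmin(d))
    return preds


def easy_spec(seed: int = 0, samples_per_class: int = 25) -> SynthSpec:
    """The easy 4-class regime: low noise, nearest-template separable."""
    return SynthSpec(
        n_classes=4,
        samples_per_class=samples_per_class,
        n_bands=39,
        n_frames=39,
        template_sparsity=0.25,
        noise_sd=0.05,
        seed=seed,
    )
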