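"""Spectrogram input handling and the two-part spike encoding.

Inputs are band x frame energy matrices (e.g. FFT or MFCC spectrograms of
spoken digits: 39 bands x 39 frames in the reference setup).  Encoding has
two parts: (1) the whole dataset is rescaled by a single scalar so energies
land in the neurons' operating range; (2) inside the network, signals become
binary spikes by comparison against a threshold (value > threshold -> 1).
By default the scaled analog values feed the first layer directly and
thresholding happens at the neurons; a model switch selects pre-thresholded
binary input instead.

Datasets on disk are a CSV manifest ``sample_id,path,label`` plus one
whitespace-delimited text matrix per sample (rows = bands, cols = frames).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrogramSample",
    "scale_spectrogram",
    "threshold_encode",
    "fit_scale",
    "stack_samples",
    "save_dataset",
    "load_manifest",
]


@dataclasses.dataclass
class SpectrogramSample:
    """A labelled band x frame energy matrix."""

    values: np.ndarray  # (n_bands, n_frames)
    label: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("sample values must be a bands x frames matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"sample {self.sample_id!r} contains non-finite values")


def scale_spectrogram(sample: SpectrogramSample, scalar: float) -> SpectrogramSample:
    """Multiply every entry by ``scalar``; the label is untouched."""
    if not np.isfinite(scalar):
        raise ValueError("scale factor must be finite")
    return SpectrogramSample(sample.values * scalar, sample.label, sample.sample_id)


def threshold_encode(values: np.ndarray, threshold: float) -> np.ndarray:
    """Binary spike matrix: 1 where value > threshold (strict), else 0."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot threshold-encode non-finite values")
    return (values > threshold).astype(float)


def fit_scale(samples: Sequence[SpectrogramSample], percentile: float = 99.0) -> float:
    """Dataset-level scalar mapping the given energy percentile to 1.0.

    Returns 1.0 for an all-zero dataset (nothing to normalise).
    """
    if not samples:
        raise ValueError("cannot fit a scale on an empty dataset")
    ref = np.percentile(np.concatenate([s.values.ravel() for s in samples]), percentile)
    return 1.0 / ref if ref > 0 else 1.0


def stack_samples(samples: Sequence[SpectrogramSample], scalar: float = 1.0):
    """Stack into ``(X, y)`` arrays: X of shape (n, bands, frames), integer labels."""
    if not samples:
        raise ValueError("empty dataset")
    shapes = {s.values.shape for s in samples}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent sample shapes: {sorted(shapes)}")
    X = np.stack([s.values for s in samples]) * scalar
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


def save_dataset(samples: Iterable[SpectrogramSample], out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write per-sample text matrices plus a ``sample_id,path,label`` manifest.

    Paths in the manifest are relative to the manifest's directory.
    """
    out_dir = Path(out_dir)
    (out_dir / "samples").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        sid = s.sample_id or f"sample{i:05d}"
        rel = f"samples/{sid}.txt"
        np.savetxt(out_dir / rel, s.values)
        rows.append({"sample_id": sid, "path": rel, "label": int(s.label)})
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=["sample_id", "path", "label"]).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path) -> list[SpectrogramSample]:
    """Load a dataset from its manifest, validating shapes and finiteness."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = {"sample_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = manifest_path.parent
    samples = [
        SpectrogramSample(np.loadtxt(base / row.path, ndmin=2), int(row.label), str(row.sample_id))
        for row in df.itertuples()
    ]
    if samples:
        stack_samples(samples)  # shape-consistency check
    return samples
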