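"""Occlusion-based spectral attention scores.

To locate the spectral regions a trained classifier relies on, windows of
the input feature vector are replaced with zeros (sliding window of 13
channels, stride 5) and the change in the model's output is measured:
for each window position the raw attention is the absolute variation of
the true-class probability.  Window-level variations are re-projected to
channels (each channel averages the variations of all windows covering
it), averaged per class over all out-of-fold samples of all folds, and
min-max normalized to [0, 1].

Fold-to-fold stability is quantified as the mean pairwise cosine
similarity between the per-fold class-average attention vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import CrossValidationResult
from .models import TrainedModel

__all__ = [
    "OcclusionConfig",
    "AttentionMap",
    "n_occlusion_windows",
    "occlusion_raw",
    "project_to_channels",
    "aggregate_attention",
    "fold_consistency",
    "compute_attention",
]


@dataclass(frozen=True)
class OcclusionConfig:
    window: int = 13
    stride: int = 5
    fill_value: float = 0.0
    #: what "output variation" is measured on: "true_class" (probability of
    #: the sample's true class), "predicted_class", or "l1" (L1 change of
    #: the whole score vector)
    mode: str = "true_class"

    def __post_init__(self) -> None:
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")
        if self.mode not in ("true_class", "predicted_class", "l1"):
            raise ValueError(f"unknown occlusion mode {self.mode!r}")


def n_occlusion_windows(length: int, config: OcclusionConfig) -> int:
    """Number of window positions: floor((L - window)/stride) + 1."""
    if config.window > length:
        raise ValueError("occlusion window longer than the feature vector")
    return (length - config.window) // config.stride + 1


def occlusion_raw(
    model: TrainedModel,
    features: np.ndarray,
    true_class,
    config: OcclusionConfig | None = None,
) -> np.ndarray:
    """Per-window absolute output variation for one feature vector."""
    config = config or OcclusionConfig()
    x = np.asarray(features, dtype=float).ravel()
    n_win = n_occlusion_windows(x.size, config)
    occluded = np.tile(x, (n_win, 1))
    for p in range(n_win):
        start = p * config.stride
        occluded[p, start : start + config.window] = config.fill_value
    base = model.predict_scores(x[None, :])[0]
    scores = model.predict_scores(occluded)
    if config.mode == "l1":
        return np.abs(scores - base).sum(axis=1)
    if config.mode == "predicted_class":
        j = int(np.argmax(base))
    else:
        try:
            j = model.classes.index(true_class)
        except ValueError as err:
            raise ValueError(f"unknown class {true_class!r}") from err
    return np.abs(scores[:, j] - base[j])


def project_to_channels(
    variations: np.ndarray, length: int, config: OcclusionConfig | None = None
) -> np.ndarray:
    """Window-level variations -> per-channel vector.

    Each channel's value is the mean variation over all windows covering
    it; trailing channels covered by no window inherit the nearest
    window's value.
    """
    config = config or OcclusionConfig()
    variations = np.asarray(variations, dtype=float)
    sums = np.zeros(length)
    counts = np.zeros(length)
    for p, v in enumerate(variations):
        start = p * config.stride
        stop = min(start + config.window, length)
        sums[start:stop] += v
        counts[start:stop] += 1
    out = np.divide(sums, counts, out=np.zeros(length), where=counts > 0)
    uncovered = counts == 0
    if uncovered.any() and variations.size:
        covered_idx = np.flatnonzero(~uncovered)
        for i in np.flatnonzero(uncovered):
            out[i] = out[covered_idx[np.argmin(np.abs(covered_idx - i))]]
    return out


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)  # degenerate constant vector -> all zeros
    return (v - lo) / (hi - lo)


@dataclass
class AttentionMap:
    """Per-class attention scores in [0, 1] with fold provenance."""

    label: str
    scores: np.ndarray  # (n_channels,), min-max normalized
    n_samples: int
    fold_means: dict[int, np.ndarray] = field(default_factory=dict)  # raw, per fold
    boundary_windows: list[int] = field(default_factory=list)


def aggregate_attention(
    channel_vectors: np.ndarray,
    labels,
    folds: np.ndarray,
    class_order,
) -> dict[str, AttentionMap]:
    """Average per-sample channel vectors within class across all
    out-of-fold samples of all folds, then min-max normalize per class."""
    channel_vectors = np.asarray(channel_vectors, dtype=float)
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    maps: dict[str, AttentionMap] = {}
    for cls in class_order:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"no samples for class {cls!r}")
        raw_mean = channel_vectors[mask].mean(axis=0)
        fold_means = {
            int(f): channel_vectors[mask & (folds == f)].mean(axis=0)
            for f in np.unique(folds[mask])
        }
        maps[cls] = AttentionMap(
            label=cls,
            scores=_minmax(raw_mean),
            n_samples=int(mask.sum()),
            fold_means=fold_means,
        )
    return maps


def fold_consistency(fold_vectors: list[np.ndarray] | dict) -> float:
    """Mean pairwise cosine similarity across per-fold attention vectors.

    Zero vectors are excluded (with a warning); requires at least two
    usable vectors.
    """
    if isinstance(fold_vectors, dict):
        fold_vectors = [fold_vectors[k] for k in sorted(fold_vectors)]
    vecs = []
    for v in fold_vectors:
        v = np.asarray(v, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            warnings.warn("zero attention vector excluded from fold consistency",
                          RuntimeWarning)
            continue
        vecs.append(v / norm)
    if len(vecs) < 2:
        raise ValueError("need at least two non-zero fold vectors")
    sims = [
        float(np.dot(vecs[i], vecs[j]))
        for i in range(len(vecs))
        for j in range(i + 1, len(vecs))
    ]
    return float(np.mean(sims))


def compute_attention(
    cv: CrossValidationResult,
    features: np.ndarray,
    config: OcclusionConfig | None = None,
    channel_map: pd.DataFrame | None = None,
) -> tuple[dict[str, AttentionMap], dict[str, float]]:
    """Full out-of-fold attention analysis for a cross-validation run.

    For every sample, the model of the fold that held it out is occluded;
    per-sample channel vectors are aggregated per class and per fold.
    Returns the per-class attention maps and their fold-consistency cosine
    scores.  When a ``channel_map`` is given, windows that straddle a
    spectral-range boundary are recorded in each map's
    ``boundary_windows`` (occlusion operates on the concatenated vector,
    so such windows mix wavenumbers from two ranges).
    """
    config = config or OcclusionConfig()
    if not cv.models:
        raise ValueError("cross-validation result carries no fold models")
    if cv.indices is not None:
        features = np.asarray(features, dtype=float)[cv.indices]
    length = features.shape[1]
    vectors = np.zeros_like(features)
    for fold, model in enumerate(cv.models):
        for i in np.flatnonzero(cv.folds.spectrum_fold == fold):
            raw = occlusion_raw(model, features[i], cv.labels[i], config)
            vectors[i] = project_to_channels(raw, length, config)
    maps = aggregate_attention(vectors, cv.labels, cv.folds.spectrum_fold,
                               cv.class_order)
    # overall map: every out-of-fold sample regardless of class.  For a
    # class whose band amplitude matches the cohort reference, SNV coupling
    # can redistribute that class's attention onto reference bands; the
    # overall map localizes the planted difference robustly.
    maps["ALL"] = AttentionMap(
        label="ALL",
        scores=_minmax(vectors.mean(axis=0)),
        n_samples=vectors.shape[0],
        fold_means={
            int(f): vectors[cv.folds.spectrum_fold == f].mean(axis=0)
            for f in np.unique(cv.folds.spectrum_fold)
        },
    )
    if channel_map is not None:
        ranges = channel_map["range_index"].to_numpy()
        boundary = [
            p
            for p in range(n_occlusion_windows(length, config))
            if len(set(ranges[p * config.stride : p * config.stride + config.window])) > 1
        ]
        for m in maps.values():
            m.boundary_windows = list(boundary)
    consistency = {
        cls: fold_consistency(m.fold_means) for cls, m in maps.items()
    }
    return maps, consistency
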