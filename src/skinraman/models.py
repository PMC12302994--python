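"""Classifiers for preprocessed Raman feature vectors.

Five model kinds are provided, with the hyperparameters fixed by the
study design:

* ``cnn``  — a 1-D convolutional network: three convolution blocks
  (kernel sizes 7, 3, 3; strides 2; feature maps 16, 32, 64), each with
  group normalization (4 groups) and ReLU, then three fully connected
  layers (256, 64, n_classes) with batch normalization and ReLU;
* ``gbm``  — gradient-boosted trees, 100 estimators, max depth 5;
* ``knn``  — k-nearest neighbors, 10 neighbors, Euclidean distance;
* ``mlp``  — multilayer perceptron, hidden layers 32 and 16;
* ``svm``  — support vector machine with an RBF kernel.

The CNN is implemented in numpy (see :mod:`skinraman.nn`); the baselines
are scikit-learn estimators behind the same train/predict surface.  All
models expose per-class probability scores whose rows sum to 1, and the
full train/predict cycle is deterministic given the training seed.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import nn

__all__ = [
    "CNNArchitecture",
    "BaselineSpec",
    "TrainingConfig",
    "TrainedModel",
    "CNNClassifier",
    "build_cnn",
    "build_baseline",
    "train",
    "predict_scores",
    "MODEL_KINDS",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("cnn", "gbm", "knn", "mlp", "svm")

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CNNArchitecture:
    conv_kernels: tuple[int, ...] = (7, 3, 3)
    conv_strides: tuple[int, ...] = (2, 2, 2)
    conv_features: tuple[int, ...] = (16, 32, 64)
    groupnorm_groups: int = 4
    fc_features: tuple[int, int] = (256, 64)  # final layer width = n_classes

    def conv_lengths(self, input_length: int) -> list[int]:
        """Per-block output lengths for valid strided convolutions."""
        lengths = []
        length = input_length
        for k, s in zip(self.conv_kernels, self.conv_strides):
            length = nn.conv_output_length(length, k, s)
            lengths.append(length)
        return lengths


@dataclass
class TrainingConfig:
    """Training regimen for the CNN (the baselines ignore everything but
    ``seed``).  Defaults: cross-entropy loss, Adam at 1e-3, 100 epochs,
    batch size 32."""

    loss: str = "cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class BaselineSpec:
    """One of the four classical ML baselines; ``hyperparams`` overrides
    the fixed defaults (rarely needed)."""

    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("gbm", "knn", "mlp", "svm"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")


def build_baseline(spec: BaselineSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a baseline spec."""
    if spec.kind == "gbm":
        params = dict(max_iter=100, max_depth=5, random_state=seed)
        params.update(spec.hyperparams)
        return HistGradientBoostingClassifier(**params)
    if spec.kind == "knn":
        params = dict(n_neighbors=10, metric="euclidean")
        params.update(spec.hyperparams)
        return KNeighborsClassifier(**params)
    if spec.kind == "mlp":
        params = dict(hidden_layer_sizes=(32, 16), max_iter=500, random_state=seed)
        params.update(spec.hyperparams)
        return MLPClassifier(**params)
    params = dict(kernel="rbf", probability=True, random_state=seed)
    params.update(spec.hyperparams)
    return SVC(**params)


class CNNClassifier:
    """The 1-D CNN, assembled lazily at fit time (weights need the seed)."""

    def __init__(self, n_classes: int, input_length: int,
                 architecture: CNNArchitecture | None = None) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        arch = architecture or CNNArchitecture()
        lengths = arch.conv_lengths(input_length)  # raises if too short
        if lengths[-1] < 1:
            raise ValueError("input too short for the convolution stack")
        self.n_classes = n_classes
        self.input_length = input_length
        self.architecture = arch
        self.net: nn.Sequential | None = None
        self.loss_history: list[float] = []

    def _build(self, rng: np.random.Generator) -> nn.Sequential:
        arch = self.architecture
        layers: list[nn.Layer] = []
        in_ch = 1
        for k, s, f in zip(arch.conv_kernels, arch.conv_strides, arch.conv_features):
            layers += [
                nn.Conv1d(in_ch, f, k, s, rng),
                nn.GroupNorm(arch.groupnorm_groups, f),
                nn.ReLU(),
            ]
            in_ch = f
        layers.append(nn.Flatten())
        flat = arch.conv_features[-1] * arch.conv_lengths(self.input_length)[-1]
        widths = (*arch.fc_features, self.n_classes)
        in_f = flat
        for i, out_f in enumerate(widths):
            layers.append(nn.Linear(in_f, out_f, rng))
            if i < len(widths) - 1:  # hidden FC layers: BN then ReLU
                layers += [nn.BatchNorm(out_f), nn.ReLU()]
            in_f = out_f
        return nn.Sequential(layers)

    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainingConfig) -> "CNNClassifier":
        rng = np.random.default_rng(config.seed)
        self.net = self._build(rng)
        opt = nn.Adam(self.net.params(), lr=config.learning_rate)
        x3 = X[:, None, :]  # (N, 1, L)
        n = X.shape[0]
        self.loss_history = []
        for _ in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = self.net.forward(x3[idx], train=True)
                probs = nn.softmax(logits)
                loss, grad = nn.cross_entropy_grad(probs, y[idx])
                self.net.backward(grad)
                opt.step(self.net.grads())
                epoch_loss += loss * idx.size
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("model is not trained")
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.net.forward(X[start : start + batch_size, None, :], train=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)


def build_cnn(n_classes: int, input_length: int,
              architecture: CNNArchitecture | None = None) -> CNNClassifier:
    """Untrained CNN with the fixed architecture and ``n_classes`` outputs."""
    return CNNClassifier(n_classes, input_length, architecture)


@dataclass
class TrainedModel:
    """Fitted classifier state: the estimator plus the class-label order
    (score columns) and the expected feature length."""

    estimator: object
    classes: tuple
    n_features: int
    kind: str

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return predict_scores(self, X)


def train(
    model,
    train_features: np.ndarray,
    train_labels,
    config: TrainingConfig | None = None,
) -> TrainedModel:
    """Fit a model (CNN instance, ``BaselineSpec`` or kind string).

    Raises if any class of the model's class set is absent from the
    training data or if the features are not finite.  Deterministic given
    ``config.seed``.
    """
    config = config or TrainingConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_channels) matching labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")

    if isinstance(model, str):
        model = (
            build_cnn(len(classes), X.shape[1])
            if model == "cnn"
            else BaselineSpec(model)
        )
    if isinstance(model, CNNClassifier):
        if len(classes) != model.n_classes:
            raise ValueError(
                f"training data has {len(classes)} classes, model expects "
                f"{model.n_classes}"
            )
        y_idx = np.searchsorted(np.array(classes, dtype=y.dtype), y)
        model.fit(X, y_idx.astype(int), config)
        return TrainedModel(model, classes, X.shape[1], "cnn")
    if isinstance(model, BaselineSpec):
        est = build_baseline(model, seed=config.seed)
        with warnings.catch_warnings():
            # sklearn >= 1.9 deprecation chatter for SVC(probability=True)
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(X, y)
        return TrainedModel(est, tuple(est.classes_.tolist()), X.shape[1], model.kind)
    raise TypeError(f"cannot train {type(model).__name__}")


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Per-class probability scores, rows summing to 1, columns ordered as
    ``model.classes``."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match training length "
            f"{model.n_features}"
        )
    scores = model.estimator.predict_proba(X)
    return np.asarray(scores, dtype=float)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a fitted model (versioned pickle)."""
    payload = {"format_version": _MODEL_FORMAT_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    return payload["model"]
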