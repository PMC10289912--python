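"""The serum-SERS 1D-CNN classifier.

Architecture: four feature-extraction blocks, each
``conv (stride 1, same padding) -> batch norm -> ReLU -> max-pool(2, 2)``,
with 16/32/64/128 kernels of width 21/11/5/3, followed by a flatten and
three fully connected layers; FC1 and FC2 are each followed by
``ReLU -> batch norm -> dropout(p=0.7)``. With the default 2046-point input
the feature-map lengths after the four blocks are 1023, 511, 255 and 127,
so the flattened feature vector has 127 x 128 = 16256 entries.

Training uses the RAdam optimiser (learning rate 1e-4, batch size 128) and a
class-weighted cross-entropy loss; the parameter state with the best
validation accuracy over the epoch history is retained. The output head can
report class scores either through a softmax (default training form) or
through a per-class log-sigmoid.

Exposed as a scikit-learn compatible estimator
(:class:`SersCNNClassifier`), so it slots into sklearn pipelines and model
selection; `build_model` / `train` / `predict` are thin functional wrappers
over it that speak :class:`~sersnet.io.SpectrumSet`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .errors import ConfigError, StateError, TrainingError
from .io import SpectrumSet

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SersCNNClassifier",
    "class_weights",
    "build_model",
    "train",
    "predict",
    "block_lengths",
]


@dataclass
class ModelSpec:
    """Architecture description of the 1D-CNN."""

    input_length: int = 2046
    block_channels: tuple[int, ...] = (16, 32, 64, 128)
    block_kernels: tuple[int, ...] = (21, 11, 5, 3)
    fc_sizes: tuple[int, int] = (256, 64)
    dropout_p: float = 0.7
    n_classes: int = 4
    output_activation: str = "log_sigmoid"

    def __post_init__(self) -> None:
        if len(self.block_channels) != len(self.block_kernels):
            raise ConfigError("block_channels and block_kernels length mismatch")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must be in [0, 1)")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.output_activation not in ("log_sigmoid", "softmax"):
            raise ConfigError(f"unknown output_activation {self.output_activation!r}")
        block_lengths(self.input_length, len(self.block_channels))  # validates


@dataclass
class TrainConfig:
    """Optimisation recipe."""

    optimizer: str = "radam"
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 300
    class_weight_mode: str = "inverse_frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "radam":
            raise ConfigError("only the radam optimizer is supported")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


def block_lengths(input_length: int, n_blocks: int = 4) -> list[int]:
    """Feature-map lengths after each conv block (pooling halves, floored)."""
    lengths = []
    L = int(input_length)
    for i in range(n_blocks):
        if L < 2:
            raise ConfigError(
                f"input_length {input_length} too short: block {i + 1} would "
                f"pool a length-{L} map"
            )
        L //= 2
        lengths.append(L)
    return lengths


def class_weights(
    labels: np.ndarray, mode: str = "inverse_frequency", n_classes: int | None = None
) -> np.ndarray:
    """Per-class loss weights from training labels.

    ``inverse_frequency`` (default) weights each class by ``N / n_c``,
    renormalised to mean 1, up-weighting minority classes.
    ``literal_frequency`` is the verbatim ``n_c / N`` convention (which
    up-weights majority classes); ``none`` returns all ones.
    """
    labels = np.asarray(labels, dtype=int)
    n_classes = n_classes or int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    if np.any(counts == 0):
        empty = np.where(counts == 0)[0].tolist()
        raise ValueError(f"classes {empty} have no labels")
    n = counts.sum()
    if mode == "literal_frequency":
        return counts / n
    if mode == "inverse_frequency":
        w = n / counts
        return w / w.mean()
    if mode == "none":
        return np.ones(n_classes)
    raise ConfigError(f"unknown class_weight_mode {mode!r}")


class SersCNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator wrapping the 1D-CNN.

    Parameters mirror :class:`ModelSpec` and :class:`TrainConfig`. ``fit``
    accepts an optional validation split (``X_val``, ``y_val``); when given,
    the retained parameters are those of the epoch with the highest
    validation accuracy, otherwise training accuracy is used for selection.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    history_ : dict
        Per-epoch training loss and validation accuracy.
    best_epoch_ : int
        Epoch (0-based) whose parameters were retained.
    """

    def __init__(
        self,
        block_channels=(16, 32, 64, 128),
        block_kernels=(21, 11, 5, 3),
        fc_sizes=(256, 64),
        dropout_p=0.7,
        output_activation="log_sigmoid",
        learning_rate=1e-4,
        batch_size=128,
        max_epochs=300,
        class_weight_mode="inverse_frequency",
        loss="softmax_ce",
        pad_mode="reflect",
        seed=0,
    ):
        self.block_channels = block_channels
        self.block_kernels = block_kernels
        self.fc_sizes = fc_sizes
        self.dropout_p = dropout_p
        self.output_activation = output_activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.class_weight_mode = class_weight_mode
        self.loss = loss
        self.pad_mode = pad_mode
        self.seed = seed

    # -- construction ------------------------------------------------------

    def _build(self, input_length: int, n_classes: int, rng: np.random.Generator):
        lengths = block_lengths(input_length, len(self.block_channels))
        feats: list[nn.Layer] = []
        c_in = 1
        for c_out, k in zip(self.block_channels, self.block_kernels):
            feats += [
                nn.Conv1d(c_in, c_out, k, rng, pad_mode=self.pad_mode),
                nn.BatchNorm(c_out, conv=True),
                nn.ReLU(),
                nn.MaxPool2(),
            ]
            c_in = c_out
        flat = lengths[-1] * self.block_channels[-1]
        h1, h2 = self.fc_sizes
        head: list[nn.Layer] = [
            nn.Flatten(),
            nn.Linear(flat, h1, rng),
            nn.ReLU(),
            nn.BatchNorm(h1, conv=False),
            nn.Dropout(self.dropout_p),
            nn.Linear(h1, h2, rng),
            nn.ReLU(),
            nn.BatchNorm(h2, conv=False),
            nn.Dropout(self.dropout_p),
            nn.Linear(h2, n_classes, rng),
        ]
        self.features_ = nn.Sequential(feats)
        self.head_ = nn.Sequential(head)
        self.feature_length_ = lengths[-1]
        self.flat_size_ = flat

    def _forward(self, X: np.ndarray, train: bool, rng=None) -> np.ndarray:
        A = self.features_.forward(X[:, None, :].astype(nn.F), train, rng)
        return self.head_.forward(A, train, rng)

    def _logits(self, X: np.ndarray, chunk: int = 256) -> np.ndarray:
        out = [
            self._forward(X[i : i + chunk], train=False)
            for i in range(0, len(X), chunk)
        ]
        return np.concatenate(out, axis=0)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_spectra, n_points)")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least two classes")
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=np.float64)
            yv = np.asarray(y_val)
            lut = {c: i for i, c in enumerate(self.classes_)}
            try:
                yv_idx = np.asarray([lut[c] for c in yv])
            except KeyError as e:
                raise ValueError(f"validation label {e} not seen in training") from e
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], n_classes, rng)
        weights = class_weights(y_idx, self.class_weight_mode, n_classes)
        loss_fn = (
            nn.weighted_cross_entropy
            if self.loss == "softmax_ce"
            else nn.weighted_logsigmoid_nll
        )
        opt = nn.RAdam(self.features_, lr=self.learning_rate)
        opt_head = nn.RAdam(self.head_, lr=self.learning_rate)
        n = len(X)
        history: dict[str, list[float]] = {"loss": [], "val_accuracy": []}
        best_acc, best_state, best_epoch = -np.inf, None, -1
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                A = self.features_.forward(xb[:, None, :].astype(nn.F), True, rng)
                logits = self.head_.forward(A, True, rng)
                loss, dlogits = loss_fn(logits, yb, weights)
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                dA = self.head_.backward(dlogits)
                self.features_.backward(dA)
                opt.step()
                opt_head.step()
                epoch_loss += loss * len(idx)
            history["loss"].append(epoch_loss / n)
            if X_val is not None:
                acc = float(
                    np.mean(self._logits(X_val).argmax(axis=1) == yv_idx)
                )
            else:
                acc = float(np.mean(self._logits(X).argmax(axis=1) == y_idx))
            history["val_accuracy"].append(acc)
            # ties go to the later epoch: among equal-validation states the
            # most-trained one has the larger margins (and the sharper
            # gradient attribution)
            if acc >= best_acc:
                best_acc, best_epoch = acc, epoch
                best_state = {
                    "features": self.features_.state_dict(),
                    "head": self.head_.state_dict(),
                }
        if best_state is not None:
            self.features_.load_state_dict(best_state["features"])
            self.head_.load_state_dict(best_state["head"])
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.class_weights_ = weights
        return self

    def predict_scores(self, X) -> np.ndarray:
        """Per-class scores in [0, 1] under the configured output activation.

        ``log_sigmoid`` reports the exponentiated log-sigmoid (= sigmoid) of
        each logit; ``softmax`` reports softmax probabilities (rows sum to 1).
        """
        check_is_fitted(self, "history_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected spectra of length {self.n_features_in_}, got {X.shape[1]}"
            )
        logits = self._logits(X).astype(np.float64)
        if self.output_activation == "softmax":
            return nn.softmax(logits)
        return 1.0 / (1.0 + np.exp(-logits))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "history_")
        X = np.asarray(X, dtype=np.float64)
        return nn.softmax(self._logits(X).astype(np.float64))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_scores(X).argmax(axis=1)]

    # -- Grad-CAM hooks ----------------------------------------------------

    def feature_maps(self, X) -> np.ndarray:
        """Post-activation feature maps of the last conv block (eval mode)."""
        check_is_fitted(self, "history_")
        X = np.asarray(X, dtype=np.float64)
        return self.features_.forward(X[:, None, :].astype(nn.F), False)

    def head_logits(self, A: np.ndarray) -> np.ndarray:
        """Class logits from last-block feature maps (eval mode).

        The input dtype is preserved: float64 feature maps give float64
        logits (the float32 parameters promote), which finite-difference
        gradient checks rely on.
        """
        return self.head_.forward(np.asarray(A), False)

    def grad_wrt_features(self, A: np.ndarray, class_idx: int) -> np.ndarray:
        """d(logit of class_idx) / d(feature maps), via the head's backprop."""
        logits = self.head_.forward(np.asarray(A), False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_idx] = 1.0
        return self.head_.backward(dlogits)


# -- functional wrappers over SpectrumSet -----------------------------------


def build_model(
    spec: ModelSpec | None = None, cfg: TrainConfig | None = None
) -> SersCNNClassifier:
    """Instantiate an untrained classifier from a spec and training config."""
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    return SersCNNClassifier(
        block_channels=spec.block_channels,
        block_kernels=spec.block_kernels,
        fc_sizes=spec.fc_sizes,
        dropout_p=spec.dropout_p,
        output_activation=spec.output_activation,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        class_weight_mode=cfg.class_weight_mode,
        seed=cfg.seed,
    )


def train(
    clf: SersCNNClassifier, train_set: SpectrumSet, val_set: SpectrumSet | None = None
) -> SersCNNClassifier:
    """Fit on labelled spectra; validation set drives epoch selection."""
    X, y = train_set.intensity_matrix(), train_set.labels()
    if val_set is not None:
        clf.fit(X, y, X_val=val_set.intensity_matrix(), y_val=val_set.labels())
    else:
        clf.fit(X, y)
    return clf


def predict(clf: SersCNNClassifier, s: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    """(scores, argmax class indices) for every spectrum in the set."""
    try:
        check_is_fitted(clf, "history_")
    except Exception as e:
        raise StateError("classifier is not trained") from e
    scores = clf.predict_scores(s.intensity_matrix())
    return scores, scores.argmax(axis=1)
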