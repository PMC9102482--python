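"""One-hidden-layer softmax perceptron for contraction classification.

The network maps the 4 segment features to 4 contraction classes through a
4-node ReLU hidden layer and a softmax output, trained with full-batch
Adam on the categorical cross-entropy of one-hot targets:

    z1 = W1 x + b1,  a1 = max(0, z1)
    z2 = W2 a1 + b2, a2 = softmax(z2)
    L  = -(1/N) sum_j sum_i  y_ij log a2_ij

Everything — forward pass, back-propagation, the Adam update — is
implemented here explicitly so the trained weights are a plain, portable
JSON object.  The model/results split follows the statsmodels convention:
``EmgClassifier`` holds the data and hyper-parameters, ``fit()`` returns a
``ClassifierResults`` carrying weights, loss history and held-out
diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import FEATURE_NAMES, Segment, one_hot
from .synthetic import ContractionClass

EPS_LOG = 1e-12


# ---------------------------------------------------------------------------
# standardization (zero mean, unit population std per feature)


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


def fit_scaler(X: np.ndarray, names=FEATURE_NAMES) -> Scaler:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaler needs a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population std, ddof=0
    bad = np.flatnonzero(std == 0)
    if bad.size:
        labels = [names[i] if i < len(names) else str(i) for i in bad]
        raise ValueError(f"constant feature column(s): {', '.join(labels)}")
    return Scaler(mean=mean, std=std)


# ---------------------------------------------------------------------------
# network parameters and forward/backward passes


@dataclass
class MlpModel:
    """Weights of the 4-4-4 network plus the feature scaler."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    scaler: Scaler | None = None

    def __post_init__(self):
        h, d = self.W1.shape
        o, h2 = self.W2.shape
        if h2 != h or self.b1.shape != (h,) or self.b2.shape != (o,):
            raise ValueError("inconsistent weight shapes")

    @property
    def num_classes(self) -> int:
        return self.W2.shape[0]

    def to_json(self, path) -> None:
        obj = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "scaler": None if self.scaler is None else {
                "mean": self.scaler.mean.tolist(), "std": self.scaler.std.tolist(),
            },
            "class_map": {c.name: c.value for c in ContractionClass},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MlpModel":
        with open(path) as fh:
            obj = json.load(fh)
        scaler = None
        if obj.get("scaler"):
            scaler = Scaler(np.array(obj["scaler"]["mean"]),
                            np.array(obj["scaler"]["std"]))
        return cls(np.array(obj["W1"]), np.array(obj["b1"]),
                   np.array(obj["W2"]), np.array(obj["b2"]), scaler)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mlp_forward(model: MlpModel, x: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) for standardized input(s)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.W1.shape[1]:
        raise ValueError(
            f"input has {x.shape[1]} features, model expects {model.W1.shape[1]}"
        )
    a1 = np.maximum(0.0, x @ model.W1.T + model.b1)
    p = softmax(a1 @ model.W2.T + model.b2)
    return p[0] if single else p


def cross_entropy(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean categorical cross-entropy of one-hot targets, clipped at 1e-12."""
    y = np.atleast_2d(y)
    yhat = np.atleast_2d(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    if np.any((yhat <= 0) & (y > 0)):
        warnings.warn("zero predicted probability for a true class; clipping",
                      stacklevel=2)
    return float(-np.mean(np.sum(y * np.log(np.clip(yhat, EPS_LOG, None)), axis=1)))


def _loss_and_grads(params: dict, X: np.ndarray, Y: np.ndarray):
    """Cross-entropy loss and its analytic gradients for a batch."""
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    N = X.shape[0]
    Z1 = X @ W1.T + b1
    A1 = np.maximum(0.0, Z1)
    P = softmax(A1 @ W2.T + b2)
    loss = float(-np.sum(Y * np.log(np.clip(P, EPS_LOG, None))) / N)
    dZ2 = (P - Y) / N
    dA1 = dZ2 @ W2
    dZ1 = dA1 * (Z1 > 0)
    grads = {
        "W2": dZ2.T @ A1, "b2": dZ2.sum(axis=0),
        "W1": dZ1.T @ X, "b1": dZ1.sum(axis=0),
    }
    return loss, grads, P


# ---------------------------------------------------------------------------
# training configuration and the Adam loop


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 3000
    hidden_nodes: int = 4
    test_fraction: float = 0.20
    validation_fraction: float = 0.10
    seed: int = 42
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    init_scale: float = 0.5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("test_fraction", "validation_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def _split(n: int, cfg: TrainConfig, rng: np.random.Generator):
    """Seeded shuffle split into train / validation / test index arrays."""
    order = rng.permutation(n)
    n_test = int(round(cfg.test_fraction * n))
    test = order[:n_test]
    rest = order[n_test:]
    n_val = int(round(cfg.validation_fraction * rest.size))
    # keras-style validation_split: tail fraction of the training portion
    val = rest[rest.size - n_val :]
    train = rest[: rest.size - n_val]
    return train, val, test


def train_mlp(
    X: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    num_classes: int = 4,
):
    """Train the softmax MLP with full-batch Adam; fully seed-determined.

    Returns (model, history, split) where history has per-epoch
    train/validation loss and accuracy and split carries the index arrays.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("X must be N x D with one label per row")
    rng = np.random.default_rng(cfg.seed)
    i_train, i_val, i_test = _split(X.shape[0], cfg, rng)
    missing = set(range(num_classes)) - set(labels[i_train].tolist())
    if missing:
        names = [ContractionClass(m).name for m in sorted(missing)]
        raise ValueError(f"class(es) absent from the training split: {names}")

    scaler = fit_scaler(X[i_train])
    Xs = scaler.transform(X)
    Y = np.eye(num_classes)[labels]

    d = X.shape[1]
    shapes = {
        "W1": (cfg.hidden_nodes, d), "b1": (cfg.hidden_nodes,),
        "W2": (num_classes, cfg.hidden_nodes), "b2": (num_classes,),
    }
    # uniform init in [-scale, scale): (2*U[0,1) - 1) * scale
    params = {k: (2.0 * rng.random(s) - 1.0) * cfg.init_scale
              for k, s in shapes.items()}
    m = {k: np.zeros(s) for k, s in shapes.items()}
    v = {k: np.zeros(s) for k, s in shapes.items()}

    hist = {k: [] for k in ("loss", "accuracy", "val_loss", "val_accuracy")}
    Xtr, Ytr = Xs[i_train], Y[i_train]
    Xva, Yva = Xs[i_val], Y[i_val]
    for epoch in range(1, cfg.epochs + 1):
        loss, grads, P = _loss_and_grads(params, Xtr, Ytr)
        hist["loss"].append(loss)
        hist["accuracy"].append(
            float(np.mean(P.argmax(axis=1) == Ytr.argmax(axis=1))))
        if Xva.size:
            _, _, Pv = _loss_and_grads(params, Xva, Yva)
            hist["val_loss"].append(cross_entropy(Yva, Pv))
            hist["val_accuracy"].append(
                float(np.mean(Pv.argmax(axis=1) == Yva.argmax(axis=1))))
        for k in params:
            m[k] = cfg.beta1 * m[k] + (1 - cfg.beta1) * grads[k]
            v[k] = cfg.beta2 * v[k] + (1 - cfg.beta2) * grads[k] ** 2
            mhat = m[k] / (1 - cfg.beta1**epoch)
            vhat = v[k] / (1 - cfg.beta2**epoch)
            params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)

    model = MlpModel(params["W1"], params["b1"], params["W2"], params["b2"], scaler)
    history = {k: np.array(vals) for k, vals in hist.items()}
    return model, history, (i_train, i_val, i_test)


def predict_class(model: MlpModel, seg_or_features) -> tuple[ContractionClass, np.ndarray]:
    """Classify one segment (or raw feature vector): argmax class + pulse.

    The pulse is the one-hot vector that feeds the state machine; exact
    probability ties resolve to the lowest class index.
    """
    if model.scaler is None:
        raise ValueError("model has no fitted scaler; train it first")
    feats = (seg_or_features.features
             if isinstance(seg_or_features, Segment) else
             np.asarray(seg_or_features, dtype=float))
    p = mlp_forward(model, model.scaler.transform(feats))
    idx = int(np.argmax(p))
    return ContractionClass(idx), one_hot(idx, model.num_classes)


# ---------------------------------------------------------------------------
# model/results facade


class EmgClassifier:
    """Contraction classifier model, statsmodels-style.

    Built from a feature matrix and integer labels (or from labeled
    segments); ``fit`` trains the MLP and returns a results object.
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels disagree in length")

    @classmethod
    def from_segments(cls, segments: list[Segment]) -> "EmgClassifier":
        if not segments:
            raise ValueError("no segments provided")
        if any(s.label is None for s in segments):
            raise ValueError("all segments must be labeled")
        X = np.vstack([s.features for s in segments])
        y = np.array([s.label.value for s in segments])
        return cls(X, y)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label") -> "EmgClassifier":
        y = df[label_col].to_numpy()
        if y.dtype.kind in "OU":
            y = np.array([ContractionClass[str(s)].value for s in y])
        return cls(df.drop(columns=[label_col]).to_numpy(dtype=float), y)

    def fit(self, cfg: TrainConfig = TrainConfig()) -> "ClassifierResults":
        model, history, split = train_mlp(self.features, self.labels, cfg)
        return ClassifierResults(self, model, history, split, cfg)


class ClassifierResults:
    """Fitted classifier: weights, training history, held-out diagnostics."""

    def __init__(self, parent, model, history, split, cfg):
        self.model_spec = parent
        self.mlp = model
        self.history = history
        self.train_idx, self.val_idx, self.test_idx = split
        self.config = cfg

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Integer class labels for a raw (unstandardized) feature matrix."""
        p = mlp_forward(self.mlp, self.mlp.scaler.transform(np.atleast_2d(X)))
        return np.atleast_2d(p).argmax(axis=1)

    @property
    def test_accuracy(self) -> float:
        X = self.model_spec.features[self.test_idx]
        y = self.model_spec.labels[self.test_idx]
        return float(np.mean(self.predict(X) == y))

    def confusion_matrix(self) -> pd.DataFrame:
        """Held-out confusion matrix, rows = true class, cols = predicted."""
        X = self.model_spec.features[self.test_idx]
        y = self.model_spec.labels[self.test_idx]
        yhat = self.predict(X)
        n = self.mlp.num_classes
        mat = np.zeros((n, n), dtype=int)
        np.add.at(mat, (y, yhat), 1)
        names = [c.name for c in ContractionClass]
        return pd.DataFrame(mat, index=names, columns=names)

    def summary(self) -> str:
        h = self.history
        lines = [
            "EMG contraction classifier (4-4-4 softmax MLP, Adam)",
            "=" * 54,
            f"examples: {self.model_spec.labels.size} "
            f"(train {self.train_idx.size} / val {self.val_idx.size} "
            f"/ test {self.test_idx.size})",
            f"epochs: {self.config.epochs}   lr: {self.config.learning_rate}   "
            f"seed: {self.config.seed}",
            f"final train loss: {h['loss'][-1]:.4f}   "
            f"final val loss: {h['val_loss'][-1]:.4f}" if len(h["val_loss"])
            else f"final train loss: {h['loss'][-1]:.4f}",
            f"held-out accuracy: {self.test_accuracy:.3f}",
            "",
            "confusion matrix (rows true / cols predicted):",
            self.confusion_matrix().to_string(),
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation loss curves over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["loss"], label="train loss")
        if len(self.history["val_loss"]):
            ax.plot(self.history["val_loss"], label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("categorical cross-entropy")
        ax.legend()
        return ax
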