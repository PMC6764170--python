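"""Feature standardization, the 3-layer ANN, and comparison classifiers.

The ANN is a fully connected network with one hidden layer of six ReLU
units and a single sigmoid output, trained with Adam on binary
cross-entropy. Biases enter before the activation (the conventional
``f(Wx + b)``); a ``literal_bias`` flag on the forward pass reproduces the
post-activation variant ``f(Wx) + b`` (with the output clipped to [0, 1])
for comparison. Gradients are hand-coded, so a finite-difference check is
part of the test suite.

The four comparison classifiers (SVM, KNN, random forest, Gaussian naive
Bayes) are scikit-learn estimators behind a common factory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import InsufficientDataError, InvalidParameterError, ZeroVarianceError
from .types import CONTROL, VF

HIDDEN_UNITS = 6  # chosen by the original trial-and-error architecture search


# ---------------------------------------------------------------- standardizer

@dataclass
class Standardizer:
    """Per-feature z-scoring ``z = (x - mu) / s`` with population SDs."""

    mu: np.ndarray
    s: np.ndarray
    feature_names: Optional[Sequence[str]] = None

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.mu) / self.s


def fit_standardizer(train: np.ndarray,
                     feature_names: Optional[Sequence[str]] = None) -> Standardizer:
    """Fit means/SDs on training rows; zero-variance features are rejected."""
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] < 2:
        raise InsufficientDataError("need at least 2 training rows to standardize")
    mu = train.mean(axis=0)
    s = train.std(axis=0)  # population SD, matching the z-score definition
    if np.any(s == 0):
        j = int(np.argmax(s == 0))
        name = feature_names[j] if feature_names else f"column {j}"
        raise ZeroVarianceError(str(name))
    return Standardizer(mu=mu, s=s, feature_names=feature_names)


# ------------------------------------------------------------------------ ANN

def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ANNModel:
    """Weights of the 3-layer network (n inputs -> m hidden -> 1 output)."""

    w1: np.ndarray  # (n, m)
    b1: np.ndarray  # (m,)
    w2: np.ndarray  # (m,)
    b2: float

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]

    def to_json(self) -> str:
        d = {"w1": self.w1.tolist(), "b1": self.b1.tolist(),
             "w2": self.w2.tolist(), "b2": self.b2}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        d = json.loads(text)
        return cls(w1=np.asarray(d["w1"]), b1=np.asarray(d["b1"]),
                   w2=np.asarray(d["w2"]), b2=float(d["b2"]))


def init_model(n_inputs: int, n_hidden: int = HIDDEN_UNITS,
               seed: int = 0, scale: float = 0.2) -> ANNModel:
    """Seeded small-uniform weight initialization."""
    rng = np.random.default_rng(seed)
    return ANNModel(
        w1=rng.uniform(-scale, scale, size=(n_inputs, n_hidden)),
        b1=np.zeros(n_hidden),
        w2=rng.uniform(-scale, scale, size=n_hidden),
        b2=0.0)


def ann_forward(model: ANNModel, x: np.ndarray,
                literal_bias: bool = False) -> np.ndarray:
    """Probability of the VF class for one vector or a (rows, n) matrix.

    ``literal_bias=True`` adds biases after the activations
    (``y = f(X) + b``) and clips the output into [0, 1].
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_inputs:
        raise InvalidParameterError(
            f"expected {model.n_inputs} features, got {X.shape[1]}")
    if literal_bias:
        h = relu(X @ model.w1) + model.b1
        p = np.clip(sigmoid(h @ model.w2) + model.b2, 0.0, 1.0)
    else:
        h = relu(X @ model.w1 + model.b1)
        p = sigmoid(h @ model.w2 + model.b2)
    return float(p[0]) if single else p


def bce_loss_and_grads(model: ANNModel, X: np.ndarray, y: np.ndarray
                       ) -> tuple:
    """Mean binary cross-entropy and its gradients w.r.t. all parameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    z1 = X @ model.w1 + model.b1           # (B, m)
    h = relu(z1)
    z2 = h @ model.w2 + model.b2           # (B,)
    p = sigmoid(z2)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    B = X.shape[0]
    dz2 = (p - y) / B                      # (B,)
    g_w2 = h.T @ dz2
    g_b2 = float(np.sum(dz2))
    dh = np.outer(dz2, model.w2)           # (B, m)
    dz1 = dh * (z1 > 0)
    g_w1 = X.T @ dz1
    g_b1 = dz1.sum(axis=0)
    return loss, {"w1": g_w1, "b1": g_b1, "w2": g_w2, "b2": g_b2}


@dataclass
class TrainConfig:
    """Adam / binary-cross-entropy training hyperparameters."""

    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 8
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be positive")


def ann_train(X: np.ndarray, y: np.ndarray,
              config: Optional[TrainConfig] = None,
              n_hidden: int = HIDDEN_UNITS) -> ANNModel:
    """Train the network with Adam on mini-batched binary cross-entropy.

    ``y`` holds 0/1 labels (1 = VF). Raises on single-class data. Same
    data + same config (seed included) give bit-identical weights.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise InvalidParameterError("training data contains a single class")
    rng = np.random.default_rng(config.seed)
    model = init_model(X.shape[1], n_hidden, seed=config.seed)
    params = {"w1": model.w1, "b1": model.b1, "w2": model.w2,
              "b2": np.asarray(model.b2)}
    m_t = {k: np.zeros_like(v) for k, v in params.items()}
    v_t = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    n = X.shape[0]
    bs = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, grads = bce_loss_and_grads(model, X[idx], y[idx])
            step += 1
            for k in params:
                g = np.asarray(grads[k])
                m_t[k] = config.beta1 * m_t[k] + (1 - config.beta1) * g
                v_t[k] = config.beta2 * v_t[k] + (1 - config.beta2) * g * g
                m_hat = m_t[k] / (1 - config.beta1 ** step)
                v_hat = v_t[k] / (1 - config.beta2 ** step)
                params[k] = params[k] - config.learning_rate * m_hat / (
                    np.sqrt(v_hat) + config.eps)
            model = ANNModel(w1=params["w1"], b1=params["b1"],
                             w2=params["w2"], b2=float(params["b2"]))
    return model


def predict_label(probability: float, threshold: float = 0.5) -> str:
    """VF iff ``probability >= threshold`` (ties go to VF)."""
    if not 0 <= probability <= 1:
        raise InvalidParameterError("probability must lie in [0, 1]")
    return VF if probability >= threshold else CONTROL


# ------------------------------------------------------- sklearn-style facade

class ANNClassifier:
    """scikit-learn-style wrapper so the ANN plugs into the CV harness."""

    def __init__(self, config: Optional[TrainConfig] = None,
                 n_hidden: int = HIDDEN_UNITS):
        self.config = config or TrainConfig()
        self.n_hidden = n_hidden
        self.model: Optional[ANNModel] = None

    def fit(self, X, y):
        self.model = ann_train(X, y, config=self.config, n_hidden=self.n_hidden)
        return self

    def predict_proba(self, X):
        p = np.atleast_1d(ann_forward(self.model, X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


ALGORITHMS = ("ANN", "SVM", "KNN", "RF", "NB")


def build_classifier(algorithm: str, seed: int = 0,
                     ann_config: Optional[TrainConfig] = None):
    """Factory for the five classifiers, seeded where stochastic.

    Comparison classifiers use the scikit-learn defaults (recorded in the
    run manifest); SVM is fit with ``probability=True`` so every model
    exposes ``predict_proba`` for ROC analysis.
    """
    algorithm = algorithm.upper()
    if algorithm == "ANN":
        cfg = ann_config or TrainConfig(seed=seed)
        return ANNClassifier(config=cfg)
    if algorithm == "SVM":
        # probability calibration so the SVM exposes predict_proba like
        # the other models (Platt scaling over internal CV)
        return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    if algorithm == "KNN":
        return KNeighborsClassifier()
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "NB":
        return GaussianNB()
    raise InvalidParameterError(
        f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def classifier_hyperparameters(algorithm: str) -> Dict:
    """The hyperparameters actually used, for the run manifest."""
    clf = build_classifier(algorithm, seed=0)
    if isinstance(clf, ANNClassifier):
        return {"hidden_units": clf.n_hidden, **asdict(clf.config)}
    return {k: v for k, v in clf.get_params(deep=True).items()
            if isinstance(v, (int, float, str, bool, type(None)))}
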