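"""Gait-phase classifiers: RBF soft-margin SVM, Fisher LDA, and ELM.

The SVM kernel is parameterised as K(z, z') = exp(-||z - z'||^2 / g^2);
``g`` is the kernel *width*, related to the more common gamma by
gamma = 1 / g^2.  Hyperparameter searches in this package (see
``emgait.abc_opt``) operate on (C, g) over [0.01, 100]^2 in this
parameterisation.  The dual quadratic program itself is delegated to a
standard soft-margin solver (libsvm via scikit-learn); multiclass
decisions use one-vs-one pairwise voting with ties broken towards the
lower class id.

LDA maximises the generalized Rayleigh quotient of between- to
within-class scatter and classifies by nearest projected class centroid.
The extreme learning machine is a single-hidden-layer network with random
(seeded) input weights and least-squares output weights obtained from the
Moore–Penrose pseudoinverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.svm import SVC

__all__ = [
    "MinMaxNormalizer",
    "SVMModel",
    "LDAModel",
    "ELMModel",
    "train_svm",
    "predict_svm",
    "train_lda",
    "predict_lda",
    "train_elm",
    "predict_elm",
    "save_model",
    "load_model",
]


@dataclass
class MinMaxNormalizer:
    """Affine map of each column onto [-1, 1] using training min/max."""

    mins: np.ndarray
    spans: np.ndarray  # max - min, constant columns get span 0

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxNormalizer":
        mins = x.min(axis=0)
        spans = x.max(axis=0) - mins
        return cls(mins, spans)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 2.0 * (x - self.mins) / self.spans - 1.0
        out[:, self.spans <= 0] = 0.0
        return out


# ---------------------------------------------------------------------------
# SVM


@dataclass
class SVMModel:
    C: float
    g: float
    svc: SVC
    normalizer: MinMaxNormalizer
    classes: np.ndarray

    @property
    def gamma(self) -> float:
        """scikit-learn's kernel coefficient equivalent to this g."""
        return 1.0 / self.g**2

    def dual_coefficients(self) -> np.ndarray:
        """alpha_i * y_i per support vector (rows: class-pair functions)."""
        return self.svc.dual_coef_


def train_svm(features: np.ndarray, labels: np.ndarray,
              C: float = 1.0, g: float = 1.0) -> SVMModel:
    """Fit a one-vs-one soft-margin RBF SVM at penalty C and kernel width g.

    Features are normalized to [-1, 1] per column with training
    statistics; the same map is applied at prediction time.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if C <= 0 or g <= 0:
        raise ValueError("C and g must be positive")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train an SVM")
    norm = MinMaxNormalizer.fit(x)
    svc = SVC(C=C, kernel="rbf", gamma=1.0 / g**2, decision_function_shape="ovo")
    svc.fit(norm(x), y)
    return SVMModel(C, g, svc, norm, classes)


def predict_svm(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """One-vs-one majority vote; tied vote counts go to the lower class id."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.normalizer.mins.size:
        raise ValueError(
            f"feature dimension {x.shape} does not match training dimension "
            f"{model.normalizer.mins.size}"
        )
    dec = model.svc.decision_function(model.normalizer(x))
    if dec.ndim == 1:
        # binary: libsvm reports one function with positive values meaning
        # the second class; flip so positive favours the pair's first class
        # as in the multiclass one-vs-one columns
        dec = -dec[:, None]
    k = model.classes.size
    votes = np.zeros((x.shape[0], k))
    col = 0
    for i in range(k):
        for j in range(i + 1, k):
            pos = dec[:, col] > 0
            votes[pos, i] += 1
            votes[~pos, j] += 1
            col += 1
    return model.classes[np.argmax(votes, axis=1)]  # argmax ties -> lower id


# ---------------------------------------------------------------------------
# LDA


@dataclass
class LDAModel:
    projection: np.ndarray  # (n_features, r)
    class_means_projected: np.ndarray  # (n_classes, r)
    classes: np.ndarray
    priors: np.ndarray
    s_b: np.ndarray = field(repr=False, default=None)
    s_w: np.ndarray = field(repr=False, default=None)


def train_lda(features: np.ndarray, labels: np.ndarray,
              ridge: float = 1e-8) -> LDAModel:
    """Fisher discriminant: W = leading eigenvectors of S_w^-1 S_b.

    S_b is the scatter of class means about the overall mean of class
    means (class-size weighted); S_w is the pooled within-class scatter.
    A small ridge keeps S_w positive definite when features are
    collinear.  Classification is by nearest projected class mean.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if x.shape[0] < classes.size:
        raise ValueError("fewer samples than classes")
    n, p = x.shape
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    counts = np.array([(y == c).sum() for c in classes])
    grand = means.mean(axis=0)  # unweighted mean of class means
    s_b = np.zeros((p, p))
    s_w = np.zeros((p, p))
    for mi, ni, c in zip(means, counts, classes):
        d = (mi - grand)[:, None]
        s_b += (ni / n) * (d @ d.T)
        xc = x[y == c] - mi
        s_w += xc.T @ xc / n
    s_w_reg = s_w + ridge * np.trace(s_w) / max(p, 1) * np.eye(p) + 1e-12 * np.eye(p)
    eigvals, eigvecs = scipy.linalg.eigh(s_b, s_w_reg)
    order = np.argsort(eigvals)[::-1]
    r = min(classes.size - 1, p)
    w = eigvecs[:, order[:r]]
    return LDAModel(w, means @ w, classes, counts / n, s_b, s_w)


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    proj = x @ model.projection
    d2 = ((proj[:, None, :] - model.class_means_projected[None]) ** 2).sum(axis=2)
    return model.classes[np.argmin(d2, axis=1)]


def lda_objective(model: LDAModel, direction: np.ndarray) -> float:
    """Generalized Rayleigh quotient w'S_b w / w'S_w w for a direction."""
    w = np.asarray(direction, dtype=float)
    denom = float(w @ model.s_w @ w)
    return float(w @ model.s_b @ w) / denom if denom > 0 else np.inf


# ---------------------------------------------------------------------------
# ELM


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class ELMModel:
    input_weights: np.ndarray  # (n_features, L)
    biases: np.ndarray  # (L,)
    output_weights: np.ndarray  # (L, n_classes)
    classes: np.ndarray
    hidden_size: int


def _elm_hidden(model_w: np.ndarray, biases: np.ndarray, x: np.ndarray) -> np.ndarray:
    return _sigmoid(x @ model_w + biases)


def train_elm(features: np.ndarray, labels: np.ndarray,
              hidden_size: int = 100, seed: int = 0) -> ELMModel:
    """Random-hidden-layer network solved by least squares.

    Input weights and biases are drawn uniform on [-1, 1] from ``seed``;
    with one-hot targets T the output weights are beta = pinv(H) @ T,
    the minimum-norm least-squares solution of H beta = T.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1, 1, size=(x.shape[1], hidden_size))
    b = rng.uniform(-1, 1, size=hidden_size)
    h = _elm_hidden(w, b, x)
    if np.allclose(h.std(axis=0), 0):
        warnings.warn("degenerate hidden layer (constant activations)")
    t = (y[:, None] == classes[None, :]).astype(float)
    beta = np.linalg.pinv(h) @ t
    return ELMModel(w, b, beta, classes, hidden_size)


def predict_elm(model: ELMModel, features: np.ndarray) -> np.ndarray:
    h = _elm_hidden(model.input_weights, model.biases,
                    np.asarray(features, dtype=float))
    return model.classes[np.argmax(h @ model.output_weights, axis=1)]


def elm_training_loss(model: ELMModel, features: np.ndarray,
                      labels: np.ndarray) -> float:
    """Sum-of-squares loss ||H beta - T||_F^2 on the given data."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    h = _elm_hidden(model.input_weights, model.biases, x)
    t = (y[:, None] == model.classes[None, :]).astype(float)
    return float(np.sum((h @ model.output_weights - t) ** 2))


# ---------------------------------------------------------------------------
# serialization


@dataclass
class SerializedSVM:
    """Portable RBF-SVM: support vectors, dual coefficients and biases.

    Predictions evaluate the pairwise decision functions
    f_ij(z) = sum_sv alpha*y*K(z, sv) + b directly, so a stored model does
    not depend on the solver that produced it.
    """

    C: float
    g: float
    classes: np.ndarray
    normalizer: MinMaxNormalizer
    support_vectors: np.ndarray  # (n_sv, p), normalized space
    n_support: np.ndarray  # SVs per class
    dual_coef: np.ndarray  # (n_classes - 1, n_sv)
    intercepts: np.ndarray  # one per class pair, (i, j) with i < j


def _serialize_svm(model: SVMModel) -> SerializedSVM:
    svc = model.svc
    return SerializedSVM(model.C, model.g, model.classes, model.normalizer,
                         svc.support_vectors_, svc.n_support_,
                         svc.dual_coef_, svc.intercept_)


def _pairwise_decisions(m: SerializedSVM, x: np.ndarray) -> np.ndarray:
    """Evaluate every one-vs-one decision function at the given (raw) rows."""
    z = m.normalizer(np.asarray(x, dtype=float))
    gamma = 1.0 / m.g**2
    d2 = ((z[:, None, :] - m.support_vectors[None, :, :]) ** 2).sum(axis=2)
    kernel = np.exp(-gamma * d2)  # (n, n_sv)
    starts = np.concatenate([[0], np.cumsum(m.n_support)])
    k = m.classes.size
    cols = []
    pair = 0
    for i in range(k):
        for j in range(i + 1, k):
            sv_i = slice(starts[i], starts[i + 1])
            sv_j = slice(starts[j], starts[j + 1])
            dec = (kernel[:, sv_i] @ m.dual_coef[j - 1, sv_i]
                   + kernel[:, sv_j] @ m.dual_coef[i, sv_j]
                   + m.intercepts[pair])
            cols.append(dec)
            pair += 1
    return np.stack(cols, axis=1)


def predict_serialized_svm(m: SerializedSVM, x: np.ndarray) -> np.ndarray:
    dec = _pairwise_decisions(m, x)
    k = m.classes.size
    votes = np.zeros((dec.shape[0], k))
    col = 0
    for i in range(k):
        for j in range(i + 1, k):
            pos = dec[:, col] > 0
            votes[pos, i] += 1
            votes[~pos, j] += 1
            col += 1
    return m.classes[np.argmax(votes, axis=1)]


def save_model(model, path) -> None:
    """Serialize an SVM/LDA/ELM model to JSON (arrays as nested lists)."""
    import json
    from pathlib import Path

    def arr(a):
        return np.asarray(a).tolist()

    if isinstance(model, SVMModel):
        s = _serialize_svm(model)
        payload = {
            "kind": "svm", "C": s.C, "g": s.g, "classes": arr(s.classes),
            "norm_mins": arr(s.normalizer.mins), "norm_spans": arr(s.normalizer.spans),
            "support_vectors": arr(s.support_vectors),
            "n_support": arr(s.n_support), "dual_coef": arr(s.dual_coef),
            "intercepts": arr(s.intercepts),
        }
    elif isinstance(model, LDAModel):
        payload = {
            "kind": "lda", "projection": arr(model.projection),
            "class_means_projected": arr(model.class_means_projected),
            "classes": arr(model.classes), "priors": arr(model.priors),
            "s_b": arr(model.s_b), "s_w": arr(model.s_w),
        }
    elif isinstance(model, ELMModel):
        payload = {
            "kind": "elm", "input_weights": arr(model.input_weights),
            "biases": arr(model.biases),
            "output_weights": arr(model.output_weights),
            "classes": arr(model.classes), "hidden_size": model.hidden_size,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load a model written by :func:`save_model`.

    SVMs come back as :class:`SerializedSVM` (predict with
    :func:`predict_serialized_svm`); LDA and ELM round-trip to their
    native model classes.
    """
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    kind = d.pop("kind")
    if kind == "svm":
        return SerializedSVM(
            d["C"], d["g"], np.asarray(d["classes"]),
            MinMaxNormalizer(np.asarray(d["norm_mins"]),
                             np.asarray(d["norm_spans"])),
            np.asarray(d["support_vectors"]), np.asarray(d["n_support"]),
            np.asarray(d["dual_coef"]), np.asarray(d["intercepts"]),
        )
    if kind == "lda":
        return LDAModel(np.asarray(d["projection"]),
                        np.asarray(d["class_means_projected"]),
                        np.asarray(d["classes"]), np.asarray(d["priors"]),
                        np.asarray(d["s_b"]), np.asarray(d["s_w"]))
    if kind == "elm":
        return ELMModel(np.asarray(d["input_weights"]), np.asarray(d["biases"]),
                        np.asarray(d["output_weights"]),
                        np.asarray(d["classes"]), d["hidden_size"])
    raise ValueError(f"unknown model kind: {kind!r}")
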