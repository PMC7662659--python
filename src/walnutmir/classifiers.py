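"""Five classifiers behind a uniform fit/predict contract.

* **ELM** — single hidden layer with seeded random input weights and a
  sigmoid activation; output weights solved in closed form by
  pseudoinverse against one-hot targets.  ``parameter='auto'`` sweeps the
  hidden-layer size from 1 to the training-set size and keeps the model
  with the smallest training error (smallest size on ties).
* **RF** — bootstrap-aggregated CART trees with per-split random feature
  subsets of size ceil(sqrt(p)); prediction is a majority vote over trees
  with the lowest-index label winning ties.
* **RBF** — Gaussian radial-basis hidden layer around seeded k-means
  centers (spread defaults to the median pairwise center distance),
  linear output weights by pseudoinverse, argmax decision.
* **PLS-DA** — PLS regression of one-hot targets; argmax decision, plus
  the classical |yhat - y| < 0.5 acceptance flag per response column.
* **BPNN** — one sigmoid hidden layer trained by full-batch gradient
  descent on mean squared error (learning rate 0.6, at most 1000 epochs,
  stop when MSE <= 1e-5).

The 0.5-threshold decision rule of PLS-DA/BPNN is two-class in spirit;
with more classes the threshold flags are still computed but the label is
assigned by argmax so accuracy is always well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.cluster import KMeans
from sklearn.tree import DecisionTreeClassifier

from . import pls_core

__all__ = ["ClassifierSpec", "ClassifierModel", "fit_classifier",
           "fit_elm", "fit_rf", "fit_rbf", "fit_plsda", "fit_bpnn",
           "predict", "threshold_accept"]

KINDS = ("ELM", "RF", "RBF", "PLSDA", "BPNN")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    parameter: int | str = 10  # hidden nodes / trees / latent variables; 'auto' for ELM
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.parameter != "auto" and int(self.parameter) < 1:
            raise ValueError("parameter must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class ClassifierModel:
    spec: ClassifierSpec
    class_labels: list
    state: dict[str, Any]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Continuous per-class outputs (not defined for RF)."""
        return _forward(self, np.asarray(X, dtype=float))

    # -- JSON persistence (weight-based kinds only) ----------------------
    def to_json(self, path: str | Path) -> None:
        if self.spec.kind == "RF":
            raise NotImplementedError(
                "RF models hold sklearn trees; persist them with joblib")
        ser = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in self.state.items()}
        Path(path).write_text(json.dumps({
            "spec": {"kind": self.spec.kind, "parameter": self.spec.parameter,
                     "threshold": self.spec.threshold, "seed": self.spec.seed},
            "class_labels": list(map(str, self.class_labels)),
            "state": ser}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        state = {k: (np.asarray(v) if isinstance(v, list) else v)
                 for k, v in d["state"].items()}
        return cls(spec=ClassifierSpec(**d["spec"]),
                   class_labels=d["class_labels"], state=state)


# ---------------------------------------------------------------------------
# helpers

def _one_hot(labels: np.ndarray) -> tuple[list, np.ndarray]:
    classes = sorted(set(map(str, labels)))
    idx = {c: i for i, c in enumerate(classes)}
    T = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        T[i, idx[str(l)]] = 1.0
    return classes, T


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _check_dims(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    p = model.state["n_features"]
    if X.shape[1] != p:
        raise ValueError(f"X has {X.shape[1]} variables; model expects {p}")
    return X


# ---------------------------------------------------------------------------
# ELM

def _elm_once(X, T, n_hidden, seed, activation):
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    W = rng.uniform(-1.0, 1.0, size=(p, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    Z = X @ W + b
    H = _sigmoid(Z) if activation == "sigmoid" else Z
    beta = np.linalg.pinv(H) @ T
    return W, b, beta, H


def fit_elm(X: np.ndarray, labels: np.ndarray, n_hidden: int | str = "auto",
            seed: int = 0, activation: str = "sigmoid") -> ClassifierModel:
    X = np.asarray(X, dtype=float)
    classes, T = _one_hot(labels)
    n = X.shape[0]
    if n_hidden == "auto":
        best = None  # (err, h, W, b, beta)
        for h in range(1, n + 1):
            W, b, beta, H = _elm_once(X, T, h, seed, activation)
            pred = np.argmax(H @ beta, axis=1)
            err = float(np.mean(pred != np.argmax(T, axis=1)))
            if best is None or err < best[0] - 1e-15:
                best = (err, h, W, b, beta)
        _, h, W, b, beta = best
    else:
        h = int(n_hidden)
        if not 1 <= h <= n:
            raise ValueError(f"n_hidden must lie in [1, {n}]")
        W, b, beta, _ = _elm_once(X, T, h, seed, activation)
    spec = ClassifierSpec(kind="ELM", parameter=h, seed=seed)
    return ClassifierModel(spec=spec, class_labels=classes, state={
        "n_features": X.shape[1], "W": W, "b": b, "beta": beta,
        "activation": activation})


# ---------------------------------------------------------------------------
# RF (sklearn CART trees, majority vote with lowest-index tie-break)

def fit_rf(X: np.ndarray, labels: np.ndarray, n_trees: int = 40,
           seed: int = 0) -> ClassifierModel:
    X = np.asarray(X, dtype=float)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    classes, _ = _one_hot(labels)
    y = np.array([classes.index(str(l)) for l in labels])
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees = []
    for i in range(n_trees):
        boot = rng.integers(n, size=n)
        t = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(2 ** 31 - 1)))
        t.fit(X[boot], y[boot])
        trees.append(t)
    spec = ClassifierSpec(kind="RF", parameter=n_trees, seed=seed)
    return ClassifierModel(spec=spec, class_labels=classes, state={
        "n_features": X.shape[1], "trees": trees, "n_classes": len(classes)})


def _rf_votes(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    k = model.state["n_classes"]
    votes = np.zeros((X.shape[0], k), dtype=int)
    for t in model.state["trees"]:
        pred = t.predict(X).astype(int)
        # a tree only knows the classes present in its bootstrap
        votes[np.arange(X.shape[0]), pred] += 1
    return votes


# ---------------------------------------------------------------------------
# RBF network

def fit_rbf(X: np.ndarray, labels: np.ndarray, n_centers: int = 10,
            spread: float | None = None, seed: int = 0) -> ClassifierModel:
    X = np.asarray(X, dtype=float)
    classes, T = _one_hot(labels)
    n = X.shape[0]
    if not 1 <= n_centers <= n:
        raise ValueError(f"n_centers must lie in [1, {n}]")
    if n_centers == n:
        centers = X.copy()
    else:
        km = KMeans(n_clusters=n_centers, random_state=seed, n_init=10)
        km.fit(X)
        centers = km.cluster_centers_
    if spread is None:
        if n_centers > 1:
            d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2)
                        .sum(-1))
            spread = float(np.median(d[np.triu_indices(n_centers, k=1)]))
        else:
            spread = float(np.median(np.linalg.norm(X - centers[0], axis=1)))
        spread = max(spread, 1e-12)
    G = _rbf_design(X, centers, spread)
    Wout = np.linalg.pinv(np.hstack([G, np.ones((n, 1))])) @ T
    spec = ClassifierSpec(kind="RBF", parameter=n_centers, seed=seed)
    return ClassifierModel(spec=spec, class_labels=classes, state={
        "n_features": X.shape[1], "centers": centers, "spread": spread,
        "Wout": Wout})


def _rbf_design(X, centers, spread):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * spread ** 2))


# ---------------------------------------------------------------------------
# PLS-DA

def fit_plsda(X: np.ndarray, labels: np.ndarray, n_LV: int = 10,
              threshold: float = 0.5) -> ClassifierModel:
    X = np.asarray(X, dtype=float)
    classes, T = _one_hot(labels)
    m = pls_core.fit_pls(X, T, n_LV)
    spec = ClassifierSpec(kind="PLSDA", parameter=n_LV, threshold=threshold)
    return ClassifierModel(spec=spec, class_labels=classes, state={
        "n_features": X.shape[1], "coefficients": m.coefficients,
        "x_mean": m.x_mean, "y_mean": m.y_mean})


def threshold_accept(yhat: np.ndarray, T: np.ndarray,
                     threshold: float = 0.5) -> np.ndarray:
    """Per-column acceptance flag |yhat_k - y_k| < threshold."""
    return np.abs(np.asarray(yhat) - np.asarray(T)) < threshold


# ---------------------------------------------------------------------------
# BPNN

def fit_bpnn(X: np.ndarray, labels: np.ndarray, n_hidden: int = 10,
             lr: float = 0.6, epochs: int = 1000, goal: float = 1e-5,
             seed: int = 0, threshold: float = 0.5) -> ClassifierModel:
    X = np.asarray(X, dtype=float)
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    classes, T = _one_hot(labels)
    # min-max scale inputs to [-1, 1] (the usual feed-forward-net default;
    # raw absorbance ranges train far too slowly at a fixed learning rate)
    x_lo = X.min(axis=0)
    x_hi = X.max(axis=0)
    span = np.where(x_hi > x_lo, x_hi - x_lo, 1.0)
    X = 2.0 * (X - x_lo) / span - 1.0
    rng = np.random.default_rng(seed)
    p, k = X.shape[1], len(classes)
    W1 = rng.uniform(-0.5, 0.5, size=(p, n_hidden))
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden)
    W2 = rng.uniform(-0.5, 0.5, size=(n_hidden, k))
    b2 = rng.uniform(-0.5, 0.5, size=k)
    n = X.shape[0]
    for _ in range(epochs):
        H = _sigmoid(X @ W1 + b1)
        O = _sigmoid(H @ W2 + b2)
        E = O - T
        mse = float(np.mean(E ** 2))
        if mse <= goal:
            break
        if mse > 1e3:
            raise RuntimeError("BPNN training diverged; lower the learning rate")
        dO = 2.0 * E * O * (1 - O) / (n * k)
        dH = (dO @ W2.T) * H * (1 - H)
        W2 -= lr * (H.T @ dO)
        b2 -= lr * dO.sum(axis=0)
        W1 -= lr * (X.T @ dH)
        b1 -= lr * dH.sum(axis=0)
    spec = ClassifierSpec(kind="BPNN", parameter=n_hidden,
                          threshold=threshold, seed=seed)
    return ClassifierModel(spec=spec, class_labels=classes, state={
        "n_features": p, "W1": W1, "b1": b1, "W2": W2, "b2": b2,
        "x_lo": x_lo, "x_span": span})


# ---------------------------------------------------------------------------
# uniform surface

def fit_classifier(X: np.ndarray, labels: np.ndarray,
                   spec: ClassifierSpec) -> ClassifierModel:
    """Dispatch on ``spec.kind`` with the spec's headline parameter."""
    if spec.kind == "ELM":
        return fit_elm(X, labels, n_hidden=spec.parameter, seed=spec.seed)
    if spec.kind == "RF":
        return fit_rf(X, labels, n_trees=int(spec.parameter), seed=spec.seed)
    if spec.kind == "RBF":
        return fit_rbf(X, labels, n_centers=int(spec.parameter), seed=spec.seed)
    if spec.kind == "PLSDA":
        return fit_plsda(X, labels, n_LV=int(spec.parameter),
                         threshold=spec.threshold)
    if spec.kind == "BPNN":
        return fit_bpnn(X, labels, n_hidden=int(spec.parameter),
                        seed=spec.seed, threshold=spec.threshold)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def _forward(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    s = model.state
    kind = model.spec.kind
    if kind == "ELM":
        Z = X @ s["W"] + s["b"]
        H = _sigmoid(Z) if s["activation"] == "sigmoid" else Z
        return H @ s["beta"]
    if kind == "RBF":
        G = _rbf_design(X, s["centers"], s["spread"])
        return np.hstack([G, np.ones((X.shape[0], 1))]) @ s["Wout"]
    if kind == "PLSDA":
        return (X - s["x_mean"]) @ s["coefficients"] + s["y_mean"]
    if kind == "BPNN":
        Xs = 2.0 * (X - s["x_lo"]) / s["x_span"] - 1.0
        H = _sigmoid(Xs @ s["W1"] + s["b1"])
        return _sigmoid(H @ s["W2"] + s["b2"])
    if kind == "RF":
        return _rf_votes(model, X).astype(float)
    raise ValueError(kind)


def predict(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels; always drawn from the training label set."""
    X = _check_dims(model, X)
    scores = _forward(model, X)
    # argmax with lowest-index tie-break (np.argmax breaks ties that way)
    idx = np.argmax(scores, axis=1)
    return np.asarray([model.class_labels[i] for i in idx], dtype=object)
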