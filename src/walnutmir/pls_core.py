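"""Latent-variable PLS regression (NIPALS) with cross-validation.

This engine serves three masters: the RMSECV fitness inside GA-PLS, the
fold-wise coefficient stability inside UVE, and PLS-DA classification.
NIPALS extracts components sequentially, which makes the per-component
regression coefficients nested: ``B_a = B_{a-1} + r_a q_a^T`` where ``r_a``
is the a-th column of the weight rotation ``R = W (P^T W)^{-1}``.  Cross-
validation exploits this to score every component count from a single fit
per fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict", "cross_validate"]

_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray   # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    x_scores: np.ndarray    # T, (n, A)
    y_loadings: np.ndarray  # Q, (q, A)
    coefficients: np.ndarray  # B, (p, q): centered X -> centered Y
    x_mean: np.ndarray
    y_mean: np.ndarray

    def to_json(self, path: str | Path) -> None:
        d = {k: np.asarray(getattr(self, k)).tolist()
             for k in ("x_weights", "x_loadings", "x_scores", "y_loadings",
                       "coefficients", "x_mean", "y_mean")}
        d["n_components"] = self.n_components
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(n_components=d["n_components"],
                   **{k: np.asarray(d[k]) for k in d if k != "n_components"})


@dataclass
class CVResult:
    rmsecv_by_A: np.ndarray
    best_A: int
    fold_scheme: str


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _nipals(Xc: np.ndarray, Yc: np.ndarray, A: int):
    """Sequential PLS2 extraction on centered matrices; returns W, P, Q, T.

    Components are extracted one at a time with NIPALS-style deflation.
    The inner relation — the NIPALS power iteration's fixed point, i.e.
    the leading left singular vector of X^T Y — is solved exactly through
    the (q x q) eigenproblem of (Y^T X)(X^T Y), which is equivalent to
    iterating to convergence but deterministic and fast for the small
    response dimensions used here.  Stops early (returning fewer columns)
    if either residual vanishes.
    """
    n, p = Xc.shape
    q = Yc.shape[1]
    X = Xc.copy()
    Y = Yc.copy()
    W = np.empty((p, A))
    P = np.empty((p, A))
    Q = np.empty((q, A))
    T = np.empty((n, A))
    for a in range(A):
        C = Y.T @ X  # (q, p)
        cn = np.linalg.norm(C)
        if cn < 1e-13 or not np.any(np.abs(X) > 1e-13):
            return W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
        if q == 1:
            w = C[0]
        else:
            G = C @ C.T  # (q, q)
            evals, evecs = np.linalg.eigh(G)
            w = C.T @ evecs[:, -1]
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            return W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
        w = w / nw
        # sign convention: align with the dominant coefficient of w
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = X @ w
        tt = t @ t
        if tt < 1e-300:
            return W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
        qv = (Y.T @ t) / tt
        pv = (X.T @ t) / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
        X = X - np.outer(t, pv)
        Y = Y - np.outer(t, qv)
    return W, P, Q, T


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """B = W (P^T W)^{-1} Q^T (P^T W is upper triangular for NIPALS)."""
    A = W.shape[1]
    if A == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    M = P.T @ W
    R = np.linalg.solve(M.T, W.T).T  # W @ inv(M), via triangular-ish solve
    return R @ Q.T


def fit_pls(X: np.ndarray, Y: np.ndarray, A: int) -> PLSModel:
    """Fit a PLS regression with ``A`` latent variables by NIPALS."""
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(
            f"A={A} out of range [1, {min(n - 1, p)}] for X of shape {X.shape}")
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    Xc = X - xm
    Yc = Y - ym
    if not np.any(np.abs(Yc) > 1e-13):
        raise ValueError("degenerate response: Y is constant")
    if not np.any(np.abs(Xc) > 1e-13):
        raise ValueError("X is constant after centering")
    W, P, Q, T = _nipals(Xc, Yc, A)
    B = _coefficients(W, P, Q)
    return PLSModel(n_components=W.shape[1], x_weights=W, x_loadings=P,
                    x_scores=T, y_loadings=Q, coefficients=B,
                    x_mean=xm, y_mean=ym)


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """yhat = (X - x_mean) B + y_mean."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1]} variables; model was trained on "
            f"{model.x_mean.size}")
    return (X - model.x_mean) @ model.coefficients + model.y_mean


# ---------------------------------------------------------------------------
# cross-validation

def make_folds(n: int, fold_scheme: str | tuple = "leave_one_out"):
    """Fold index arrays.  k-fold uses interleaved assignment (i % k) so an
    input ordered by class is spread evenly across folds."""
    if fold_scheme in ("leave_one_out", "loo"):
        return [np.array([i]) for i in range(n)]
    if isinstance(fold_scheme, tuple) and fold_scheme[0] == "k_fold":
        k = int(fold_scheme[1])
        if k < 2:
            raise ValueError("k_fold needs k >= 2")
        idx = np.arange(n)
        return [idx[idx % k == i] for i in range(min(k, n))]
    raise ValueError(f"unknown fold scheme {fold_scheme!r}")


def _cv_press(X: np.ndarray, Y: np.ndarray, A_max: int, folds) -> np.ndarray:
    """Sum of squared held-out errors per component count (len A_max).

    Component counts that exceed a fold's admissible maximum reuse the
    largest admissible model for that fold.
    """
    n = X.shape[0]
    press = np.zeros(A_max)
    for te in folds:
        mask = np.ones(n, dtype=bool)
        mask[te] = False
        Xtr, Ytr = X[mask], Y[mask]
        xm = Xtr.mean(axis=0)
        ym = Ytr.mean(axis=0)
        Ytr_c = Ytr - ym
        if np.any(np.all(np.abs(Ytr_c) < 1e-13, axis=0)):
            warnings.warn("a CV fold lost an entire class (constant dummy "
                          "column); continuing", RuntimeWarning, stacklevel=2)
        a_cap = min(A_max, Xtr.shape[0] - 1, X.shape[1])
        W, P, Q, _ = _nipals(Xtr - xm, Ytr_c, a_cap)
        got = W.shape[1]
        Xte_c = X[te] - xm
        resid = Y[te] - ym  # running residual: y - yhat_a
        M = P.T @ W
        R = np.linalg.solve(M.T, W.T).T if got else np.empty((X.shape[1], 0))
        for a in range(A_max):
            if a < got:
                resid = resid - np.outer(Xte_c @ R[:, a], Q[:, a])
            press[a] += float(np.einsum("ij,ij->", resid, resid))
    return press


def cross_validate(X: np.ndarray, Y: np.ndarray, A_max: int,
                   fold_scheme: str | tuple = "leave_one_out") -> CVResult:
    """RMSECV for A = 1..A_max; best_A = argmin with smallest-A tie-break."""
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    folds = make_folds(X.shape[0], fold_scheme)
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    press = _cv_press(X, Y, A_max, folds)
    rmsecv = np.sqrt(press / (X.shape[0] * Y.shape[1]))
    best = int(np.nonzero(rmsecv <= rmsecv.min() + 1e-12)[0][0]) + 1
    name = fold_scheme if isinstance(fold_scheme, str) else \
        f"k_fold({fold_scheme[1]})"
    return CVResult(rmsecv_by_A=rmsecv, best_A=best, fold_scheme=name)
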