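"""Shared multivariate machinery: PCA, SIMPLS, cross-validation splitters.

These are the numerical primitives the classifiers are built from.  PCA is
a mean-centered SVD with a fixed sign convention; PLS is the SIMPLS
algorithm (deterministic, no deflation of X), regressing spectra against
class-indicator responses.  Four splitters are provided: contiguous block,
venetian blind, random subset and leave-one-out; all are deterministic
given (n, scheme, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PcaModel",
    "PlsModel",
    "CvScheme",
    "pca_fit",
    "pca_project",
    "pls_fit",
    "pls_predict",
    "cv_split",
    "select_ncomp",
]

CvMethod = Literal["contiguous_block", "venetian_blind", "random_subset", "loo"]


@dataclass(frozen=True)
class PcaModel:
    mean: np.ndarray          # (p,)
    loadings: np.ndarray      # (a, p), row-orthonormal
    variances: np.ndarray     # (a,), score variances sigma^2/(n-1)
    all_eigenvalues: np.ndarray  # full spectrum, for residual statistics
    n_train: int

    @property
    def a(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class PlsModel:
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray       # (p, a) X-weights R (x_c @ R = scores)
    x_loadings: np.ndarray    # (p, a)
    y_loadings: np.ndarray    # (g, a)
    coef: np.ndarray          # (p, g) regression coefficients

    @property
    def a(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class CvScheme:
    method: CvMethod
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in (
            "contiguous_block", "venetian_blind", "random_subset", "loo"
        ):
            raise ValueError(f"unknown CV method {self.method!r}")
        if self.method != "loo" and self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(X: np.ndarray, a: int) -> PcaModel:
    """Mean-centered SVD PCA keeping ``a`` components.

    Sign convention: each loading's largest-magnitude element is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= a <= min(n - 1, p)):
        raise ValueError(f"a={a} out of range [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if p > 1.5 * n:
        # Gram-matrix route: eigh of the n x n kernel is much cheaper than
        # an SVD of the wide matrix and yields the same decomposition.
        w, U = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        U = U[:, order]
        s = np.sqrt(w)
        keep = min(n, p)
        s = s[:keep]
        safe = np.where(s > 1e-12, s, 1.0)
        Vt = (Xc.T @ U[:, :keep] / safe).T
    else:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    V = Vt[:a]
    flip = np.sign(V[np.arange(a), np.argmax(np.abs(V), axis=1)])
    V = V * flip[:, None]
    return PcaModel(
        mean=mean, loadings=V, variances=eig[:a],
        all_eigenvalues=eig, n_train=n,
    )


def pca_project(m: PcaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project spectra: scores, Hotelling T^2 and residual Q per row.

    T^2 = sum_a t_a^2 / variance_a (Mahalanobis distance in score space);
    Q = squared norm of the residual orthogonal to the model subspace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.mean.size:
        raise ValueError(
            f"data has {X.shape[1]} points, model expects {m.mean.size}"
        )
    Xc = X - m.mean
    t = Xc @ m.loadings.T
    t2 = np.sum(t**2 / m.variances, axis=1)
    resid = Xc - t @ m.loadings
    q = np.sum(resid**2, axis=1)
    return t, t2, q


# ---------------------------------------------------------------------------
# SIMPLS partial least squares
# ---------------------------------------------------------------------------

def pls_fit(X: np.ndarray, Y: np.ndarray, a: int) -> PlsModel:
    """SIMPLS regression of X (spectra) on Y (class indicators).

    Produces ``a`` latent variables with mutually orthogonal scores and a
    linear prediction operator Yhat = (X - x_mean) @ coef + y_mean.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    g = Y.shape[1]
    if a < 1:
        raise ValueError("a must be >= 1")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("X has zero variance; nothing to model")
    if g > 1 and np.any(Y.sum(axis=0) == n):
        raise ValueError("single-class indicator matrix: no between-class variance")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if np.allclose(Yc, 0):
        raise ValueError("response has zero variance")

    S = Xc.T @ Yc                      # (p, g) covariance to deflate
    R = np.zeros((p, a))               # X-weights
    T = np.zeros((n, a))               # scores
    P = np.zeros((p, a))               # X-loadings
    Q = np.zeros((g, a))               # Y-loadings
    V = np.zeros((p, a))               # orthonormal basis of P
    for i in range(a):
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] < 1e-14:
            raise ValueError(
                f"rank exhausted at {i} latent variables (requested {a})"
            )
        r = U[:, 0]
        t = Xc @ r
        t -= t.mean()
        normt = np.linalg.norm(t)
        t /= normt
        r /= normt
        pvec = Xc.T @ t
        qvec = Yc.T @ t
        v = pvec.copy()
        if i > 0:
            v -= V[:, :i] @ (V[:, :i].T @ pvec)
        v /= np.linalg.norm(v)
        S = S - v[:, None] @ (v[None, :] @ S)
        R[:, i], T[:, i], P[:, i], Q[:, i], V[:, i] = r, t, pvec, qvec, v
    coef = R @ Q.T
    return PlsModel(
        x_mean=x_mean, y_mean=y_mean, weights=R,
        x_loadings=P, y_loadings=Q, coef=coef,
    )


def pls_predict(m: PlsModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - m.x_mean) @ m.coef + m.y_mean


def pls_scores(m: PlsModel, X: np.ndarray) -> np.ndarray:
    """Latent-variable scores of (possibly new) spectra."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - m.x_mean) @ m.weights


# ---------------------------------------------------------------------------
# Cross-validation splitters
# ---------------------------------------------------------------------------

def cv_split(n: int, scheme: CvScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition ``range(n)`` into (train, test) folds.

    contiguous_block: fold j tests indices [floor(jn/k), floor((j+1)n/k));
    venetian_blind: fold j tests indices congruent to j mod k;
    random_subset: seeded permutation, then contiguous blocks;
    loo: n singleton test folds.
    """
    idx = np.arange(n)
    if scheme.method == "loo":
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    k = scheme.n_splits
    if k > n:
        raise ValueError(f"n_splits={k} exceeds n={n}")
    folds: list[np.ndarray] = []
    if scheme.method == "contiguous_block":
        folds = [idx[(j * n) // k : ((j + 1) * n) // k] for j in range(k)]
    elif scheme.method == "venetian_blind":
        folds = [idx[j::k] for j in range(k)]
    elif scheme.method == "random_subset":
        perm = np.random.default_rng(scheme.seed).permutation(n)
        folds = [np.sort(perm[(j * n) // k : ((j + 1) * n) // k]) for j in range(k)]
    return [(np.setdiff1d(idx, f), f) for f in folds]


# ---------------------------------------------------------------------------
# Latent-variable count selection
# ---------------------------------------------------------------------------

def select_ncomp(
    X: np.ndarray,
    Y: np.ndarray,
    scheme: CvScheme,
    max_a: int,
    criterion: Literal["rmsecv", "classification_error"] = "rmsecv",
) -> tuple[int, np.ndarray]:
    """Pick the PLS latent-variable count by cross-validation.

    Evaluates a = 1..max_a under ``scheme`` and returns the smallest a
    whose mean CV criterion is within one standard error (across folds) of
    the global minimum, together with the full criterion curve.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if max_a < 1:
        raise ValueError("max_a must be >= 1")
    folds = cv_split(n, scheme)
    per_fold = np.full((max_a, len(folds)), np.nan)
    for a in range(1, max_a + 1):
        for j, (tr, te) in enumerate(folds):
            try:
                m = pls_fit(X[tr], Y[tr], a)
            except ValueError:
                continue  # rank exhausted in this fold
            pred = pls_predict(m, X[te])
            if criterion == "rmsecv":
                per_fold[a - 1, j] = np.sqrt(np.mean((pred - Y[te]) ** 2))
            else:
                per_fold[a - 1, j] = np.mean(
                    np.argmax(pred, axis=1) != np.argmax(Y[te], axis=1)
                )
    curve = np.nanmean(per_fold, axis=1)
    best = int(np.nanargmin(curve))
    se = np.nanstd(per_fold[best], ddof=1) / np.sqrt(
        np.sum(~np.isnan(per_fold[best]))
    )
    ok = np.flatnonzero(curve <= curve[best] + se)
    return int(ok[0]) + 1, curve
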