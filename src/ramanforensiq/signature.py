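"""Multi-dimensional spectroscopic signatures of single body fluids.

A fluid's signature is the set of non-negative component spectra resolved
from multi-spot measurements of its dry traces, augmented with two fixed
baseline terms — a horizontal line and a tilted line standing in for the
fluorescence background.  Non-negative linear combinations of these basis
spectra fit any spectrum of that fluid; the fit quality (SSE, R-square,
RMSE) quantifies how well an unknown spectrum is explained by the
signature.

The pipeline is: estimate how many independent spectral sources the data
matrix carries (significant factor analysis, via Malinowski's indicator
function), resolve that many non-negative components by alternating least
squares, then append the baseline pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, lsq_linear, nnls

from .spectral_core import FitQuality, SpectralDataset, Spectrum

__all__ = [
    "Signature",
    "SfaReport",
    "AlsResult",
    "sfa_rank",
    "als_decompose",
    "build_signature",
    "fit_signature",
]

#: Signature ranks used for the three fluids: the number of chemical
#: components each fluid's spectra are resolved into.
DEFAULT_RANKS = {"semen": 3, "blood": 2, "saliva": 3}


@dataclass(frozen=True)
class SfaReport:
    """Significant-factor-analysis summary of a spectrum matrix."""

    eigenvalues: np.ndarray   # descending variances of the centered data
    indicator: np.ndarray     # Malinowski IND(k), k = 1..kmax
    rank_estimate: int
    cumvar: np.ndarray        # cumulative explained-variance fractions


@dataclass(frozen=True)
class AlsResult:
    concentrations: np.ndarray   # (n_spectra, k), >= 0
    components: np.ndarray       # (k, n_points), >= 0, each max-normalized
    residual_history: np.ndarray  # lack-of-fit per iteration
    converged: bool


@dataclass(frozen=True)
class Signature:
    """Resolved components of one fluid plus the two baseline spectra."""

    fluid: str
    wavenumbers: np.ndarray
    components: np.ndarray       # (k, n_points)

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def baseline(self) -> np.ndarray:
        """Constant (all-ones) and tilted (0 -> 1 ramp) baseline spectra."""
        w = self.wavenumbers
        ramp = (w - w[0]) / (w[-1] - w[0])
        return np.vstack([np.ones_like(w), ramp])

    @property
    def basis(self) -> np.ndarray:
        """All k + 2 basis spectra: components then baseline pair."""
        return np.vstack([self.components, self.baseline])

    def to_json(self, path: str) -> None:
        payload = {
            "fluid": self.fluid,
            "wavenumbers": self.wavenumbers.tolist(),
            "components": self.components.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "Signature":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            fluid=payload["fluid"],
            wavenumbers=np.asarray(payload["wavenumbers"], float),
            components=np.asarray(payload["components"], float),
        )


# ---------------------------------------------------------------------------
# Significant factor analysis
# ---------------------------------------------------------------------------

def sfa_rank(d: SpectralDataset | np.ndarray, max_k: int = 10) -> SfaReport:
    """Estimate the number of independent spectral sources in a matrix.

    Eigenvalues are those of the covariance of the mean-centered spectra.
    Malinowski's indicator IND(k) = RE(k) / (c - k)^2 with the real error
    RE(k) = sqrt(sum_{j>k} lambda_j / (r (c - k))), where c is the smaller
    and r the larger matrix dimension (the indicator's standard convention;
    a spectrum matrix is wider than it is tall, so c is the spectrum
    count).  The estimated rank minimizes IND, clipped to [1, max_k].  On
    noisy data IND is known to be unstable, so the cumulative explained
    variance is reported alongside and the signature ranks are fixed per
    fluid in practice.
    """
    X = d.matrix if isinstance(d, SpectralDataset) else np.asarray(d, float)
    n_rows, n_cols = X.shape
    if n_rows < 3:
        raise ValueError("SFA needs at least 3 spectra")
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    eig = np.zeros(n_cols)
    eig[: s.size] = s**2 / (n_rows - 1)
    total = eig.sum()
    cumvar = np.cumsum(eig) / total if total > 0 else np.zeros(n_cols)
    c = min(n_rows, n_cols)
    r = max(n_rows, n_cols)
    kmax = c - 1
    ind = np.empty(kmax)
    for k in range(1, kmax + 1):
        re_k = np.sqrt(max(eig[k:].sum(), 0.0) / (r * (c - k)))
        ind[k - 1] = re_k / (c - k) ** 2
    # IND can dive spuriously as k approaches c, so the minimum is searched
    # within the caller's plausible-rank window [1, max_k].
    window = ind[: min(max_k, kmax)]
    rank = int(np.argmin(window)) + 1
    return SfaReport(
        eigenvalues=eig, indicator=ind, rank_estimate=rank, cumvar=cumvar
    )


# ---------------------------------------------------------------------------
# Non-negative alternating least squares
# ---------------------------------------------------------------------------

def _purest_rows(X: np.ndarray, k: int) -> np.ndarray:
    """Pick k mutually dissimilar rows: iteratively maximize the residual
    norm against the span of rows already picked.  Deterministic."""
    norms = np.linalg.norm(X, axis=1)
    picked = [int(np.argmax(norms))]
    for _ in range(1, k):
        Q, _ = np.linalg.qr(X[picked].T)  # (p, len(picked))
        resid = X - (X @ Q) @ Q.T
        rn = np.linalg.norm(resid, axis=1)
        rn[picked] = -1.0
        picked.append(int(np.argmax(rn)))
    return X[picked].copy()


def _lack_of_fit(X: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    resid = X - C @ S
    return float(np.sqrt(np.sum(resid**2) / np.sum(X**2)))


def _max_contrast(S: np.ndarray, C: np.ndarray, n_pass: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an ALS solution to its maximum-contrast representative.

    Non-negative bilinear factorizations are only determined up to a
    rotation; this selects the conventional representative in which each
    component has had the largest possible multiple of every other
    component subtracted while staying non-negative (a small linear
    program per component).  The product C @ S — and hence the fit — is
    preserved, and both factors stay non-negative.
    """
    S = S.copy()
    C = C.copy()
    k = S.shape[0]
    if k == 1:
        return S, C
    for _ in range(n_pass):
        moved = 0.0
        for i in range(k):
            others = [j for j in range(k) if j != i]
            res = linprog(
                c=-np.ones(len(others)),
                A_ub=S[others].T,
                b_ub=S[i],
                bounds=[(0, None)] * len(others),
                method="highs",
            )
            if res.success and res.x.max() > 1e-10:
                S[i] = np.clip(S[i] - res.x @ S[others], 0.0, None)
                for beta, j in zip(res.x, others):
                    C[:, j] += beta * C[:, i]
                moved += float(res.x.sum())
        if moved < 1e-10:
            break
    return S, C


def als_decompose(
    d: SpectralDataset | np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
    contrast: bool = True,
) -> AlsResult:
    """Resolve a spectrum matrix into k non-negative components by ALS.

    Alternates exact non-negative least squares for the concentration and
    spectral factors (each subproblem solved by active-set NNLS per row /
    column), starting from the k most mutually dissimilar rows of the
    data.  Stops when the relative change of the lack-of-fit drops below
    ``tol``, the fit becomes numerically exact, or ``max_iter`` is
    reached.  The converged solution is rotated to its maximum-contrast
    representative (see :func:`_max_contrast`) unless ``contrast=False``;
    components are then max-normalized, with the compensating scale moved
    into the concentrations.
    """
    X = d.matrix if isinstance(d, SpectralDataset) else np.asarray(d, float)
    n, p = X.shape
    if not (1 <= k < min(n, p)):
        raise ValueError(f"k={k} out of range [1, {min(n, p) - 1}]")
    if not np.any(X):
        raise ValueError("all-zero data cannot be decomposed")
    S = np.clip(init if init is not None else _purest_rows(X, k), 0.0, None)
    # Guard against an all-zero initial component.
    for j in range(k):
        if not np.any(S[j]):
            S[j] = np.abs(X).mean(axis=0)
    C = np.zeros((n, k))
    history: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        # Fix S, solve rows of C >= 0.
        A = S.T  # (p, k)
        for i in range(n):
            C[i], _ = nnls(A, X[i])
        # Fix C, solve columns of S >= 0.
        for j in range(p):
            S[:, j], _ = nnls(C, X[:, j])
        lof = _lack_of_fit(X, C, S)
        history.append(lof)
        if lof < 1e-7 or prev - lof < tol * max(prev, 1e-12):
            converged = True
            break
        prev = lof
    if contrast:
        S, C = _max_contrast(S, C)
    # Max-normalize components, pushing scale into concentrations.
    scale = S.max(axis=1)
    scale[scale == 0] = 1.0
    S = S / scale[:, None]
    C = C * scale[None, :]
    return AlsResult(
        concentrations=C,
        components=S,
        residual_history=np.asarray(history),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Signature assembly and fitting
# ---------------------------------------------------------------------------

def build_signature(
    fluid: str, als: AlsResult, wavenumbers: np.ndarray
) -> Signature:
    """Wrap resolved components into a Signature (baseline pair appended)."""
    return Signature(
        fluid=fluid,
        wavenumbers=np.asarray(wavenumbers, float),
        components=als.components.copy(),
    )


def fit_signature(s: Spectrum, sig: Signature) -> tuple[np.ndarray, FitQuality]:
    """Fit one spectrum by the signature basis.

    Component weights are constrained non-negative; the two baseline
    weights are unconstrained.  Returns the k + 2 weights and the fit
    quality computed on the full residual.
    """
    if s.wavenumbers.size != sig.wavenumbers.size or not np.allclose(
        s.wavenumbers, sig.wavenumbers
    ):
        raise ValueError("spectrum is not on the signature's wavenumber grid")
    A = sig.basis.T  # (p, k+2)
    k = sig.k
    lb = np.r_[np.zeros(k), -np.inf, -np.inf]
    ub = np.full(k + 2, np.inf)
    res = lsq_linear(A, s.intensities, bounds=(lb, ub), method="bvls")
    weights = res.x
    residual = s.intensities - A @ weights
    return weights, FitQuality.from_residual(s.intensities, residual)


def fit_dataset(
    d: SpectralDataset, sig: Signature
) -> tuple[np.ndarray, list[FitQuality]]:
    """Row-wise :func:`fit_signature`; returns stacked weights and qualities."""
    weights, quals = [], []
    for i in range(d.n_spectra):
        w, q = fit_signature(d.spectrum(i), sig)
        weights.append(w)
        quals.append(q)
    return np.vstack(weights), quals
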