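"""Classification engines for body-fluid spectra: SIMCA, LDA family, PLS-DA.

SIMCA models each fluid class by its own PCA and judges membership by
Hotelling's T^2 (distance within the model plane) and the Q residual
(distance off the plane) against confidence limits; an unknown is assigned
to the nearest class in the reduced distance sqrt((T^2/T^2_lim)^2 +
(Q/Q_lim)^2).  The LDA family operates on compressed scores (PCA or PLS)
and includes Fisher LDA, naive Bayes, per-class-covariance (quadratic) and
pooled-Mahalanobis variants.  PLS-DA regresses spectra on class-indicator
columns and assigns by the largest predicted indicator.

Compression is always refit inside each cross-validation fold, so no
information about held-out spectra leaks into the model.  Class priors are
equal everywhere: the class imbalance of the training campaign reflects
sampling effort, not prevalence.  Argmax ties break toward the first class
in canonical order (blood < saliva < semen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .chemometrics import (
    CvScheme,
    PcaModel,
    PlsModel,
    cv_split,
    pca_fit,
    pca_project,
    pls_fit,
    pls_predict,
    pls_scores,
    select_ncomp,
)
from .spectral_core import SpectralDataset

__all__ = [
    "SimcaModel",
    "SimcaAssignment",
    "LdaModel",
    "PlsdaModel",
    "ClassMetrics",
    "classification_metrics",
    "simca_train",
    "simca_classify",
    "lda_train",
    "lda_predict",
    "lda_loo",
    "gaussian_family_predict",
    "plsda_train",
    "plsda_predict",
    "plsda_evaluate",
    "classify_unknowns",
]

#: PCA scores fed to the LDA family retain this much variance by default...
DEFAULT_PCA_VARIANCE = 0.99
#: ...capped at this many scores.
MAX_PCA_SCORES = 20


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMetrics:
    """Confusion counts and per-class figures of merit.

    sensitivity: predicted-in-class / actually-in-class;
    specificity: predicted-not-in-class / actually-not-in-class;
    classification error: mean of the two miss rates;
    rmse: root mean squared error of the class-indicator prediction
    (RMSEC on calibration, RMSECV under cross-validation), when available.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray            # (g, g), rows actual, cols predicted
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    class_error: dict[str, float]
    rmse: dict[str, float] | None = None

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": dict(self.sensitivity),
            "specificity": dict(self.specificity),
            "class_error": dict(self.class_error),
        }
        if self.rmse is not None:
            d["rmse"] = dict(self.rmse)
        return d


def classification_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str],
    indicator_pred: np.ndarray | None = None,
) -> ClassMetrics:
    """Confusion matrix plus per-class sensitivity / specificity / error.

    ``indicator_pred`` (n x g predicted indicator values) enables the
    per-class indicator RMSE column.
    """
    classes = tuple(classes)
    g = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    y_true = list(y_true)
    y_pred = list(y_pred)
    conf = np.zeros((g, g), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[pos[t], pos[p]] += 1
    sens, spec, cerr = {}, {}, {}
    for c in classes:
        i = pos[c]
        in_c = conf[i].sum()
        not_c = conf.sum() - in_c
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        tn = not_c - fp
        sens[c] = tp / in_c if in_c else np.nan
        spec[c] = tn / not_c if not_c else np.nan
        cerr[c] = ((1 - sens[c]) + (1 - spec[c])) / 2.0
    rmse = None
    if indicator_pred is not None:
        Y = np.zeros((len(y_true), g))
        for r, t in enumerate(y_true):
            Y[r, pos[t]] = 1.0
        rmse = {
            c: float(np.sqrt(np.mean((indicator_pred[:, pos[c]] - Y[:, pos[c]]) ** 2)))
            for c in classes
        }
    return ClassMetrics(classes, conf, sens, spec, cerr, rmse)


# ---------------------------------------------------------------------------
# Compression shared by the LDA family
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for i, c in enumerate(classes):
        Y[np.asarray(labels) == c, i] = 1.0
    return Y


def _fit_compressor(
    X: np.ndarray,
    labels: np.ndarray,
    classes: Sequence[str],
    method: Literal["pca", "pls"],
    a: int | None,
):
    """Fit PCA or PLS compression on training data; return transform fn."""
    if method == "pca":
        amax = min(X.shape[0] - 1, X.shape[1], MAX_PCA_SCORES)
        m = pca_fit(X, amax if a is None else a)
        if a is None:
            cum = np.cumsum(m.all_eigenvalues) / m.all_eigenvalues.sum()
            a = min(int(np.searchsorted(cum, DEFAULT_PCA_VARIANCE) + 1), amax)
            m = PcaModel(
                mean=m.mean, loadings=m.loadings[:a], variances=m.variances[:a],
                all_eigenvalues=m.all_eigenvalues, n_train=m.n_train,
            )
        return lambda Z: (np.atleast_2d(Z) - m.mean) @ m.loadings.T
    elif method == "pls":
        if a is None:
            a = min(10, X.shape[0] - 1, X.shape[1])
        m = pls_fit(X, _one_hot(labels, classes), a)
        return lambda Z: pls_scores(m, Z)
    raise ValueError(f"unknown compression {method!r}")


# ---------------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimcaSubmodel:
    pca: PcaModel
    t2_limit: float
    q_limit: float


@dataclass(frozen=True)
class SimcaModel:
    classes: tuple[str, ...]
    submodels: dict[str, SimcaSubmodel]
    alpha: float


@dataclass(frozen=True)
class SimcaAssignment:
    distances: dict[str, float]   # reduced distance to each class model
    nearest_class: str
    in_class: dict[str, bool]     # reduced distance <= sqrt(2)


def _t2_limit(a: int, n: int, alpha: float) -> float:
    return a * (n - 1) / (n - a) * stats.f.ppf(alpha, a, n - a)


def _q_limit(discarded: np.ndarray, alpha: float) -> float:
    """Jackson-Mudholkar confidence limit on the Q residual.

    Falls back to the Box chi-square moment approximation when the
    Jackson-Mudholkar expression degenerates (e.g. nearly noise-free
    classes with vanishing discarded eigenvalues).
    """
    discarded = discarded[discarded > 0]
    if discarded.size == 0:
        return 1e-12
    th1 = discarded.sum()
    th2 = (discarded**2).sum()
    th3 = (discarded**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    ca = stats.norm.ppf(alpha)
    if h0 > 1e-6:
        inner = ca * np.sqrt(2 * th2 * h0**2) / th1 + 1 + th2 * h0 * (h0 - 1) / th1**2
        if inner > 0:
            return float(th1 * inner ** (1.0 / h0))
    gm = th2 / th1
    hm = th1**2 / th2
    return float(gm * stats.chi2.ppf(alpha, hm))


def simca_train(
    d: SpectralDataset,
    a_per_class: int | dict[str, int] = 3,
    alpha: float = 0.95,
) -> SimcaModel:
    """One PCA class model per fluid with T^2 and Q limits at level alpha."""
    classes = tuple(d.classes)
    submodels: dict[str, SimcaSubmodel] = {}
    for c in classes:
        a = a_per_class[c] if isinstance(a_per_class, dict) else int(a_per_class)
        Xc = d.matrix[d.labels == c]
        n = Xc.shape[0]
        if n < a + 1:
            raise ValueError(
                f"class {c!r} has {n} spectra; needs at least {a + 1} for a={a}"
            )
        pca = pca_fit(Xc, a)
        submodels[c] = SimcaSubmodel(
            pca=pca,
            t2_limit=_t2_limit(a, n, alpha),
            q_limit=_q_limit(pca.all_eigenvalues[a:], alpha),
        )
    return SimcaModel(classes=classes, submodels=submodels, alpha=alpha)


def simca_classify(
    m: SimcaModel, d: SpectralDataset
) -> tuple[list[SimcaAssignment], ClassMetrics | None]:
    """Assign every spectrum to the nearest class model.

    The reduced distance to class c is sqrt((T^2/T^2_lim)^2 + (Q/Q_lim)^2);
    a spectrum is inside class c when that distance is <= sqrt(2).  Metrics
    are computed when the dataset carries known (non-"unknown") labels.
    """
    first = next(iter(m.submodels.values()))
    if d.n_points != first.pca.mean.size:
        raise ValueError("dataset grid does not match the SIMCA model")
    per_class = {}
    for c in m.classes:
        sub = m.submodels[c]
        _, t2, q = pca_project(sub.pca, d.matrix)
        per_class[c] = np.sqrt((t2 / sub.t2_limit) ** 2 + (q / sub.q_limit) ** 2)
    dist_matrix = np.column_stack([per_class[c] for c in m.classes])
    nearest = np.argmin(dist_matrix, axis=1)
    assignments = [
        SimcaAssignment(
            distances={c: float(per_class[c][i]) for c in m.classes},
            nearest_class=m.classes[nearest[i]],
            in_class={
                c: bool(per_class[c][i] <= np.sqrt(2.0)) for c in m.classes
            },
        )
        for i in range(d.n_spectra)
    ]
    metrics = None
    if set(d.labels) <= set(m.classes):
        metrics = classification_metrics(
            d.labels, [a.nearest_class for a in assignments], m.classes
        )
    return assignments, metrics


# ---------------------------------------------------------------------------
# LDA family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdaModel:
    classes: tuple[str, ...]
    means: np.ndarray            # (g, a) class means in score space
    pooled_cov: np.ndarray       # (a, a)
    pooled_inv: np.ndarray
    priors: np.ndarray           # equal by construction


def lda_train(scores: np.ndarray, labels: Sequence[str],
              classes: Sequence[str] | None = None) -> LdaModel:
    """Fisher LDA on (compressed) scores: class means + pooled covariance.

    A singular pooled covariance is ridge-regularized once with
    1e-8 * trace / dim on the diagonal; if still singular, that's an error.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = sorted(set(labels))
    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    g, a = len(classes), X.shape[1]
    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((a, a))
    for i, c in enumerate(classes):
        Xc = X[labels == c] - means[i]
        pooled += Xc.T @ Xc
    pooled /= max(X.shape[0] - g, 1)
    try:
        pooled_inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(pooled) / a
        pooled = pooled + ridge * np.eye(a)
        try:
            pooled_inv = np.linalg.inv(pooled)
        except np.linalg.LinAlgError as exc:
            raise ValueError("pooled covariance singular even after ridge") from exc
    priors = np.full(g, 1.0 / g)
    return LdaModel(classes, means, pooled, pooled_inv, priors)


def lda_discriminants(m: LdaModel, X: np.ndarray) -> np.ndarray:
    """delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c, per class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = m.pooled_inv @ m.means.T                   # (a, g)
    lin = X @ A
    const = -0.5 * np.sum(m.means * A.T, axis=1) + np.log(m.priors)
    return lin + const


def lda_predict(m: LdaModel, X: np.ndarray) -> list[str]:
    delta = lda_discriminants(m, X)
    return [m.classes[i] for i in np.argmax(delta, axis=1)]


def lda_loo(
    d: SpectralDataset,
    compression: Literal["pca", "pls"] = "pca",
    a: int | None = None,
) -> tuple[list[str], ClassMetrics]:
    """Leave-one-out LDA: every spectrum predicted by a model trained on
    the rest, with compression refit on each training set."""
    classes = tuple(d.classes)
    if d.n_spectra < len(classes) + 1:
        raise ValueError("too few spectra for leave-one-out LDA")
    preds: list[str] = []
    idx = np.arange(d.n_spectra)
    for i in idx:
        tr = np.delete(idx, i)
        transform = _fit_compressor(
            d.matrix[tr], d.labels[tr], classes, compression, a
        )
        model = lda_train(transform(d.matrix[tr]), d.labels[tr], classes)
        preds.append(lda_predict(model, transform(d.matrix[i]))[0])
    return preds, classification_metrics(d.labels, preds, classes)


def _gaussian_rule(
    variant: Literal["naive_bayes", "stratified_covariance", "mahalanobis"],
    Xtr: np.ndarray,
    ytr: np.ndarray,
    classes: tuple[str, ...],
):
    """Build the per-variant scoring rule; returns predict(X) -> labels."""
    g = len(classes)
    means = np.vstack([Xtr[ytr == c].mean(axis=0) for c in classes])
    if variant == "naive_bayes":
        var = np.vstack(
            [Xtr[ytr == c].var(axis=0, ddof=1) for c in classes]
        )
        var = np.maximum(var, 1e-12)

        def predict(X):
            X = np.atleast_2d(X)
            ll = np.empty((X.shape[0], g))
            for i in range(g):
                z = (X - means[i]) ** 2 / var[i]
                ll[:, i] = -0.5 * (z.sum(axis=1) + np.log(var[i]).sum())
            return [classes[i] for i in np.argmax(ll, axis=1)]

        return predict
    if variant == "stratified_covariance":
        covs, logdets, invs = [], [], []
        dim = Xtr.shape[1]
        for c in classes:
            Xc = Xtr[ytr == c]
            cov = np.cov(Xc, rowvar=False, ddof=1)
            cov = np.atleast_2d(cov) + 1e-8 * np.trace(np.atleast_2d(cov)) / dim * np.eye(dim)
            covs.append(cov)
            sign, logdet = np.linalg.slogdet(cov)
            logdets.append(logdet)
            invs.append(np.linalg.inv(cov))

        def predict(X):
            X = np.atleast_2d(X)
            ll = np.empty((X.shape[0], g))
            for i in range(g):
                Z = X - means[i]
                ll[:, i] = -0.5 * (np.sum(Z @ invs[i] * Z, axis=1) + logdets[i])
            return [classes[i] for i in np.argmax(ll, axis=1)]

        return predict
    if variant == "mahalanobis":
        lm = lda_train(Xtr, ytr, classes)

        def predict(X):
            X = np.atleast_2d(X)
            d2 = np.empty((X.shape[0], g))
            for i in range(g):
                Z = X - lm.means[i]
                d2[:, i] = np.sum(Z @ lm.pooled_inv * Z, axis=1)
            return [classes[i] for i in np.argmin(d2, axis=1)]

        return predict
    raise ValueError(f"unknown variant {variant!r}")


def gaussian_family_predict(
    d: SpectralDataset,
    variant: Literal["naive_bayes", "stratified_covariance", "mahalanobis"],
    compression: Literal["pca", "pls"] = "pca",
    a: int | None = None,
) -> tuple[list[str], ClassMetrics]:
    """LDA-family variants evaluated under leave-one-out.

    naive_bayes fits per-class diagonal Gaussians; stratified_covariance
    fits per-class full covariances (a quadratic rule); mahalanobis assigns
    to the class with the smallest pooled-covariance Mahalanobis distance.
    """
    classes = tuple(d.classes)
    preds: list[str] = []
    idx = np.arange(d.n_spectra)
    for i in idx:
        tr = np.delete(idx, i)
        transform = _fit_compressor(
            d.matrix[tr], d.labels[tr], classes, compression, a
        )
        rule = _gaussian_rule(
            variant, transform(d.matrix[tr]), d.labels[tr], classes
        )
        preds.append(rule(transform(d.matrix[i]))[0])
    return preds, classification_metrics(d.labels, preds, classes)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlsdaModel:
    classes: tuple[str, ...]
    pls: PlsModel
    a: int
    selection_curve: np.ndarray | None = None


def plsda_train(
    d: SpectralDataset,
    a: int | None = None,
    scheme: CvScheme | None = None,
    max_a: int = 10,
) -> PlsdaModel:
    """PLS-DA: regress spectra on one-hot class indicators.

    When ``a`` is None the latent-variable count is selected by
    cross-validated RMSECV under ``scheme`` (venetian blind, 10 folds by
    default) with the one-standard-error rule.  Prediction is argmax over
    predicted indicator values; rows need not sum to one.
    """
    classes = tuple(d.classes)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Y = _one_hot(d.labels, classes)
    curve = None
    if a is None:
        if scheme is None:
            scheme = CvScheme("venetian_blind", n_splits=min(10, d.n_spectra))
        max_a = min(max_a, d.n_spectra - 2, d.n_points)
        a, curve = select_ncomp(d.matrix, Y, scheme, max_a)
    pls = pls_fit(d.matrix, Y, a)
    return PlsdaModel(classes=classes, pls=pls, a=a, selection_curve=curve)


def plsda_predict(m: PlsdaModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    pred = pls_predict(m.pls, X)
    labels = [m.classes[i] for i in np.argmax(pred, axis=1)]
    return labels, pred


def plsda_evaluate(
    m: PlsdaModel, d: SpectralDataset, scheme: CvScheme | None = None
) -> tuple[ClassMetrics, ClassMetrics]:
    """Calibration (self-prediction) and cross-validated metrics.

    CV refits the PLS model (same latent-variable count) inside every
    training fold and predicts the held-out fold; the per-class RMSE
    column is RMSEC for calibration and RMSECV for cross-validation.
    """
    if scheme is None:
        scheme = CvScheme("venetian_blind", n_splits=min(10, d.n_spectra))
    classes = m.classes
    Y = _one_hot(d.labels, classes)
    cal_labels, cal_pred = plsda_predict(m, d.matrix)
    cal = classification_metrics(d.labels, cal_labels, classes, cal_pred)
    cv_pred = np.zeros_like(Y)
    for tr, te in cv_split(d.n_spectra, scheme):
        sub = pls_fit(d.matrix[tr], Y[tr], m.a)
        cv_pred[te] = pls_predict(sub, d.matrix[te])
    cv_labels = [classes[i] for i in np.argmax(cv_pred, axis=1)]
    cv = classification_metrics(d.labels, cv_labels, classes, cv_pred)
    return cal, cv


# ---------------------------------------------------------------------------
# Consensus classification of unknowns
# ---------------------------------------------------------------------------

def classify_unknowns(
    models: dict[str, object], d_unknown: SpectralDataset
) -> list[dict]:
    """Have every trained engine vote on each unknown spectrum.

    ``models`` maps engine names to trained models: a SimcaModel, a
    PlsdaModel, or an (LdaModel, transform) pair whose transform compresses
    raw spectra to the LDA score space.  Returns one record per spectrum
    with the per-engine votes, the majority consensus ("ambiguous" when no
    strict majority exists) and a unanimity flag.
    """
    votes: dict[str, list[str]] = {}
    for name, model in models.items():
        if isinstance(model, SimcaModel):
            assignments, _ = simca_classify(model, d_unknown)
            votes[name] = [a.nearest_class for a in assignments]
        elif isinstance(model, PlsdaModel):
            votes[name] = plsda_predict(model, d_unknown.matrix)[0]
        elif isinstance(model, tuple) and isinstance(model[0], LdaModel):
            lda, transform = model
            votes[name] = lda_predict(lda, transform(d_unknown.matrix))
        else:
            raise TypeError(f"engine {name!r} has unsupported model type")
    records = []
    names = list(votes)
    for i in range(d_unknown.n_spectra):
        row = {name: votes[name][i] for name in names}
        consensus, unanimous = consensus_vote(row)
        records.append(
            {"votes": row, "consensus": consensus, "unanimous": unanimous}
        )
    return records


def consensus_vote(votes: dict[str, str]) -> tuple[str, bool]:
    """Majority consensus over per-engine votes.

    Returns (label, unanimous); the label is "ambiguous" when no class
    holds a strict majority.
    """
    counts: dict[str, int] = {}
    for v in votes.values():
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.items(), key=lambda kv: kv[1])
    consensus = best[0] if best[1] > len(votes) / 2 else "ambiguous"
    return consensus, len(counts) == 1
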