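"""Qualitative models: PLS-DA, SIMCA and LDA on PCA scores.

Three complementary approaches assign a packaged-sausage spectrum to a
commercial category (Black / Red / White):

* **PLS-DA** — a PLS2 regression onto a 0/1 class-indicator (dummy)
  matrix; a sample is assigned to the class with the largest predicted
  indicator value.
* **SIMCA** — one PCA model per class; membership requires both the
  orthogonal residual (S-distance, judged by an F-test at ``alpha``)
  and the leverage to be within the class model's limits.  A sample can
  belong to one, several or none of the classes; multiple memberships
  are resolved by the smallest combined normalized distance
  sqrt((s/s0)^2 + (h/h_bar)^2).
* **LDA** — linear discriminant analysis on the scores of a shared PCA
  compression (smallest A reaching ``variance_threshold`` cumulative
  explained variance), classifying by minimum Mahalanobis distance to
  the class mean under the pooled within-class covariance, equal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ibernir.latent_core import PCAModel, PLSModel, fit_pca, fit_pls, pca_project, pls_predict
from ibernir.spectra_io import CATEGORIES

_TIE_RTOL = 1e-9


def encode_dummy(
    labels: Sequence[str], classes: Sequence[str] = CATEGORIES
) -> np.ndarray:
    """One-hot 0/1 indicator matrix over ``classes`` (declared order)."""
    index = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"unknown label {lab!r}; classes are {list(classes)}")
        Y[i, index[lab]] = 1.0
    return Y


@dataclass
class ClassAssignment:
    """Per-sample predictions with continuous per-class scores.

    ``predicted`` entries are class names, or None for a SIMCA sample
    accepted by no class model.  ``scores`` is n x K (meaning depends on
    the method: predicted dummy value, combined SIMCA distance, or
    Mahalanobis distance).  ``memberships`` is SIMCA-only.
    """

    classes: tuple[str, ...]
    predicted: list[str | None]
    scores: np.ndarray
    ambiguous: np.ndarray
    memberships: list[tuple[str, ...]] | None = None


def _argbest(values: np.ndarray, largest: bool) -> tuple[int, bool]:
    best = np.max(values) if largest else np.min(values)
    tol = _TIE_RTOL * max(1.0, abs(best))
    hits = np.nonzero(np.abs(values - best) <= tol)[0]
    return int(hits[0]), len(hits) > 1


# ----------------------------------------------------------------------
# PLS-DA
# ----------------------------------------------------------------------

@dataclass
class PLSDAModel:
    pls: PLSModel
    classes: tuple[str, ...]
    A: int


def fit_plsda(
    X: np.ndarray,
    labels: Sequence[str],
    A: int,
    classes: Sequence[str] = CATEGORIES,
) -> PLSDAModel:
    present = set(labels)
    if len(present) < 2:
        raise ValueError("PLS-DA needs at least two classes in training data")
    classes = tuple(c for c in classes if c in present) if present != set(classes) else tuple(classes)
    Y = encode_dummy(labels, classes)
    return PLSDAModel(pls=fit_pls(np.asarray(X, float), Y, A), classes=classes, A=A)


def predict_plsda(model: PLSDAModel, X: np.ndarray) -> ClassAssignment:
    """Assign each sample to the class with the largest predicted dummy
    value; exact ties go to the first class in declared order and are
    flagged ambiguous."""
    yhat = pls_predict(model.pls, X, model.A)
    predicted, amb = [], []
    for row in yhat:
        k, tie = _argbest(row, largest=True)
        predicted.append(model.classes[k])
        amb.append(tie)
    return ClassAssignment(model.classes, predicted, yhat, np.asarray(amb))


# ----------------------------------------------------------------------
# SIMCA
# ----------------------------------------------------------------------

@dataclass
class SIMCAClassModel:
    pca: PCAModel
    s0: float          # pooled residual scale of the class model
    f_crit: float      # critical value for (s/s0)^2
    leverage_limit: float
    mean_leverage: float
    dof_sample: float  # moment-matched residual degrees of freedom


@dataclass
class SIMCAModel:
    classes: tuple[str, ...]
    submodels: Mapping[str, SIMCAClassModel] = field(default_factory=dict)
    alpha: float = 0.05


def fit_simca(
    X: np.ndarray,
    labels: Sequence[str],
    per_class_A: Mapping[str, int] | int,
    alpha: float = 0.05,
    classes: Sequence[str] = CATEGORIES,
    leverage_multiplier: float = 3.0,
) -> SIMCAModel:
    """Fit one PCA model per class with class-specific component counts.

    The class residual scale s0 is the root mean squared (leverage-
    corrected) training S-distance.  Adjacent NIR wavelengths are
    strongly correlated, so the nominal p - A residual dimensions
    vastly overstate the independent information per sample; instead
    the critical value for the residual ratio (s/s0)^2 comes from the
    null distribution of the residual quadratic form itself — a
    weighted sum of chi-square(1) variables whose weights are the
    training residual covariance eigenvalues — evaluated by a
    deterministic Monte Carlo quantile at level ``alpha``.  This keeps
    the nominal in-class acceptance rate near 1 - alpha regardless of
    how uneven the residual spectrum is.  The leverage limit is
    ``leverage_multiplier`` times the model's average leverage.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    model = SIMCAModel(classes=tuple(classes), alpha=alpha)
    submodels: dict[str, SIMCAClassModel] = {}
    for cls in classes:
        rows = np.nonzero(labels == cls)[0]
        A = per_class_A if isinstance(per_class_A, int) else per_class_A[cls]
        if len(rows) < A + 2:
            raise ValueError(
                f"class {cls!r} has {len(rows)} samples; needs >= {A + 2}"
            )
        Xk = X[rows]
        n_k, p = Xk.shape
        pca = fit_pca(Xk, A)
        scores_k, s_dist, h = pca_project(pca, Xk)
        # leverage-corrected residual matrix: training residuals are
        # deflated by the fit, new-sample residuals are not
        E = (Xk - pca.mean) - scores_k @ pca.loadings.T
        E = E / np.sqrt(1.0 - np.clip(h, 0.0, 0.9))[:, None]
        # eigenvalues of the residual covariance via the Gram matrix
        lam = np.linalg.eigvalsh(E @ E.T / (n_k - 1))
        lam = lam[lam > 1e-12 * lam.max()]
        m = float(np.sum(lam))  # expected squared S-distance of a new sample
        s0 = float(np.sqrt(m))
        # null of (s/s0)^2: weighted chi-square(1) mixture, MC quantile
        rng = np.random.default_rng(1234 + len(submodels))
        draws = (rng.standard_normal((4000, lam.size)) ** 2) @ lam
        f_crit = float(np.quantile(draws, 1 - alpha) / m)
        nu = 2.0 * m**2 / float(2.0 * np.sum(lam**2))  # effective dof (reported)
        h_bar = (1.0 + A) / n_k
        submodels[cls] = SIMCAClassModel(
            pca=pca,
            s0=s0,
            f_crit=f_crit,
            leverage_limit=leverage_multiplier * h_bar,
            mean_leverage=h_bar,
            dof_sample=nu,
        )
    model.submodels = submodels
    return model


def classify_simca(model: SIMCAModel, X: np.ndarray) -> ClassAssignment:
    """Class-model each sample: member of every class whose S-distance
    F-ratio and leverage are within limits; multi-members resolved by
    the smallest combined normalized distance; no membership -> None."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    K = len(model.classes)
    f_ratio = np.empty((n, K))
    combined = np.empty((n, K))
    member = np.zeros((n, K), dtype=bool)
    for k, cls in enumerate(model.classes):
        sub = model.submodels[cls]
        _, s_dist, lev = pca_project(sub.pca, X)
        f_ratio[:, k] = (s_dist / sub.s0) ** 2
        combined[:, k] = np.sqrt(
            (s_dist / sub.s0) ** 2 + (lev / sub.mean_leverage) ** 2
        )
        member[:, k] = (f_ratio[:, k] <= sub.f_crit) & (lev <= sub.leverage_limit)
    predicted: list[str | None] = []
    amb = np.zeros(n, dtype=bool)
    memberships: list[tuple[str, ...]] = []
    for i in range(n):
        ks = np.nonzero(member[i])[0]
        memberships.append(tuple(model.classes[k] for k in ks))
        if ks.size == 0:
            predicted.append(None)
        elif ks.size == 1:
            predicted.append(model.classes[ks[0]])
        else:
            j, tie = _argbest(combined[i, ks], largest=False)
            predicted.append(model.classes[ks[j]])
            amb[i] = tie
    return ClassAssignment(model.classes, predicted, combined, amb, memberships)


# ----------------------------------------------------------------------
# LDA on PCA scores
# ----------------------------------------------------------------------

@dataclass
class LDAModel:
    pca: PCAModel
    classes: tuple[str, ...]
    class_means: np.ndarray       # K x A score-space centroids
    pooled_cov: np.ndarray        # A x A within-class covariance
    _chol: np.ndarray | None = None


def fit_lda(
    X: np.ndarray,
    labels: Sequence[str],
    variance_threshold: float = 0.99,
    classes: Sequence[str] = CATEGORIES,
) -> LDAModel:
    """PCA compression followed by Mahalanobis-distance LDA.

    The compression keeps the smallest number of components whose
    cumulative explained variance reaches ``variance_threshold``,
    capped at n - K - 1 so the pooled within-class covariance stays
    invertible; if it is still singular the dimension is reduced
    further with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in classes if np.any(labels == c)]
    if len(present) < 2:
        raise ValueError("LDA needs at least two classes")
    n, p = X.shape
    K = len(present)
    cap = min(n - K - 1, n - 1, p)
    if cap < 1:
        raise ValueError("too few samples for LDA compression")
    # grow the decomposition until the variance threshold is reached
    A_try = min(15, cap)
    while True:
        pca = fit_pca(X, A_try)
        cum = np.cumsum(pca.explained_variance_ratio)
        if cum[-1] >= variance_threshold or A_try >= cap or pca.A < A_try:
            break
        A_try = min(2 * A_try, cap)
    hits = np.nonzero(cum >= variance_threshold)[0]
    A = int(hits[0]) + 1 if hits.size else pca.A
    while A >= 1:
        sub = PCAModel(
            mean=pca.mean,
            loadings=pca.loadings[:, :A],
            scores=pca.scores[:, :A],
            explained_variance=pca.explained_variance[:A],
            total_variance=pca.total_variance,
            n_train=pca.n_train,
        )
        T = sub.scores
        means = np.vstack([T[labels == c].mean(axis=0) for c in present])
        S = np.zeros((A, A))
        for k, c in enumerate(present):
            D = T[labels == c] - means[k]
            S += D.T @ D
        S /= n - K
        try:
            chol = np.linalg.cholesky(S)
            return LDAModel(sub, tuple(present), means, S, chol)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular pooled covariance at A={A}; reducing dimension",
                stacklevel=2,
            )
            A -= 1
    raise ValueError("pooled covariance singular at every dimension")


def classify_lda(model: LDAModel, X: np.ndarray) -> ClassAssignment:
    """Assign to the class with minimum Mahalanobis distance in the
    compressed score space (equal priors); exact ties go to the first
    class in declared order with an ambiguity flag."""
    scores, _, _ = pca_project(model.pca, X)
    diffs = scores[:, None, :] - model.class_means[None, :, :]  # n x K x A
    sol = np.linalg.solve(
        model.pooled_cov, diffs.reshape(-1, diffs.shape[-1]).T
    ).T.reshape(diffs.shape)
    d2 = np.sum(diffs * sol, axis=2)
    predicted, amb = [], []
    for row in d2:
        k, tie = _argbest(row, largest=False)
        predicted.append(model.classes[k])
        amb.append(tie)
    return ClassAssignment(model.classes, predicted, d2, np.asarray(amb))
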