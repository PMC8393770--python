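"""PCA and PLS latent-variable engines shared by every downstream stage.

Both decompositions use the NIPALS algorithm on mean-centered data:
PCA for spectral exploration, outlier screening, SIMCA class models and
LDA compression; PLS (PLS1 for single-trait regression, PLS2 for the
dummy-matrix response of PLS-DA) for the quantitative and discriminant
models.  Leave-one-out cross-validation refits the model — including
re-centering — inside every fold and feeds the SECV-based rule used to
pick the number of latent variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_NIPALS_TOL = 1e-24  # on |t_new - t|^2 / |t_new|^2, i.e. ~1e-12 relative
_NIPALS_MAXITER = 3000


@dataclass
class PCAModel:
    """Mean-centered principal component model.

    loadings are orthonormal columns (p x A); scores = (X - mean) @ loadings;
    explained_variance is per-component score variance (non-increasing) and
    total_variance the trace of the covariance of the training data.
    """

    mean: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    total_variance: float
    n_train: int

    @property
    def A(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance


def _fix_sign(loading: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-magnitude loading entry positive
    j = int(np.argmax(np.abs(loading)))
    if loading[j] < 0:
        return -loading, -score
    return loading, score


def fit_pca(X: np.ndarray, A: int) -> PCAModel:
    """NIPALS PCA with ``A`` components on the mean-centered matrix.

    Stops early (with a warning) if the residual collapses before ``A``
    components, i.e. the data has lower rank.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} out of range for {n}x{p} matrix")
    mean = X.mean(axis=0)
    E = X - mean
    total_var = float(np.sum(E**2) / (n - 1))
    scale = float(np.sum(E**2))
    loadings, scores, evar = [], [], []
    for _ in range(A):
        rss = float(np.sum(E**2))
        if rss <= 1e-12 * max(scale, 1.0):
            warnings.warn(
                f"rank deficiency: stopping at {len(loadings)} of {A} components",
                stacklevel=2,
            )
            break
        t = E[:, int(np.argmax(np.sum(E**2, axis=0)))].copy()
        if np.allclose(t, 0):
            t = E[:, 0].copy()
        for _ in range(_NIPALS_MAXITER):
            w = E.T @ t / (t @ t)
            w /= np.linalg.norm(w)
            t_new = E @ w
            if np.sum((t_new - t) ** 2) <= _NIPALS_TOL * np.sum(t_new**2):
                t = t_new
                break
            t = t_new
        w, t = _fix_sign(w, t)
        E = E - np.outer(t, w)
        loadings.append(w)
        scores.append(t)
        evar.append(float(t @ t) / (n - 1))
    return PCAModel(
        mean=mean,
        loadings=np.column_stack(loadings),
        scores=np.column_stack(scores),
        explained_variance=np.asarray(evar),
        total_variance=total_var,
        n_train=n,
    )


def pca_project(
    model: PCAModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project samples onto a fitted PCA model.

    Returns ``(scores, s_distance, leverage)`` per sample: the orthogonal
    residual root-sum-square (S-distance, the distance of the sample to
    the model plane) and the leverage ``1/n_train + sum_a t_a^2 /
    (training score sum of squares)`` (the distance to the model centre).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError("column count does not match model")
    E = X - model.mean
    scores = E @ model.loadings
    resid = E - scores @ model.loadings.T
    s_dist = np.sqrt(np.sum(resid**2, axis=1))
    ss_train = np.sum(model.scores**2, axis=0)
    leverage = 1.0 / model.n_train + np.sum(scores**2 / ss_train, axis=1)
    return scores, s_dist, leverage


@dataclass
class PLSModel:
    """NIPALS PLS decomposition (PLS1 or PLS2) of mean-centered X and Y.

    W are X weights, P X loadings, Q Y loadings, T the X scores; the
    regression coefficients for any a <= A are W_a (P_a' W_a)^-1 Q_a'.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray

    @property
    def A(self) -> int:
        return self.W.shape[1]

    def coef(self, a: int | None = None) -> np.ndarray:
        """Regression coefficient matrix B using the first ``a`` LVs."""
        a = self.A if a is None else a
        if not 1 <= a <= self.A:
            raise ValueError(f"a={a} out of range (1..{self.A})")
        Wa, Pa, Qa = self.W[:, :a], self.P[:, :a], self.Q[:, :a]
        return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def fit_pls(X: np.ndarray, Y: np.ndarray, A: int) -> PLSModel:
    """NIPALS PLS with ``A`` latent variables.

    Single-column Y uses the non-iterative PLS1 recursion; multi-column
    Y (e.g. the class dummy matrix) the iterative PLS2 one.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} out of range for {n}x{p} matrix")
    if np.any(Y.std(axis=0) <= 1e-12 * (1 + np.abs(Y.mean(axis=0)))):
        raise ValueError("zero-variance response column")
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    Ws, Ps, Qs, Ts = [], [], [], []
    for _ in range(A):
        if Y.shape[1] == 1:
            w = E.T @ F[:, 0]
        else:
            u = F[:, int(np.argmax(np.sum(F**2, axis=0)))].copy()
            for _ in range(_NIPALS_MAXITER):
                w = E.T @ u / (u @ u)
                w /= np.linalg.norm(w)
                t = E @ w
                q = F.T @ t / (t @ t)
                u_new = F @ q / (q @ q)
                if np.sum((u_new - u) ** 2) <= _NIPALS_TOL * np.sum(u_new**2):
                    break
                u = u_new
        nw = np.linalg.norm(w)
        if nw <= 1e-14:
            warnings.warn("X residual exhausted; returning fewer LVs", stacklevel=2)
            break
        w = w / nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 1e-14:
            break
        pvec = E.T @ t / tt
        q = F.T @ t / tt
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, q)
        Ws.append(w)
        Ps.append(pvec)
        Qs.append(q)
        Ts.append(t)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        W=np.column_stack(Ws),
        P=np.column_stack(Ps),
        Q=np.column_stack(Qs),
        T=np.column_stack(Ts),
    )


def pls_predict(model: PLSModel, X: np.ndarray, a: int | None = None) -> np.ndarray:
    """Predict responses with the first ``a`` latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.x_mean) @ model.coef(a) + model.y_mean


@dataclass
class CVResult:
    """Leave-one-out cross-validation curves over 1..A_max latent variables.

    ``predictions`` has shape (n, A_max, m); the RMSECV / 1-VR / SECV
    curves have shape (A_max, m) (m response columns).  ``pooled_secv``
    aggregates SECV across responses by the root mean square, which is
    what multi-response component selection uses.
    """

    predictions: np.ndarray
    rmsecv: np.ndarray
    one_minus_vr: np.ndarray
    secv: np.ndarray

    @property
    def A_max(self) -> int:
        return self.predictions.shape[1]

    @property
    def pooled_secv(self) -> np.ndarray:
        return np.sqrt(np.mean(self.secv**2, axis=1))


def loo_cv(X: np.ndarray, Y: np.ndarray, A_max: int) -> CVResult:
    """Leave-one-out full cross-validation of a PLS model.

    For every sample, the model (including centering) is refit on the
    remaining n-1 samples and the held-out sample predicted with every
    number of latent variables up to ``A_max``.  RMSECV(a) is the root
    mean square CV residual, 1-VR(a) = 1 - SS_cv(a)/SS_tot the
    cross-validated coefficient of determination, and SECV(a) the
    bias-corrected (n-1 denominator) standard deviation of the CV
    residuals.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    if A_max > n - 2:
        raise ValueError("A_max exceeds n - 2")
    preds = np.empty((n, A_max, m))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = fit_pls(X[mask], Y[mask], A_max)
        for a in range(1, sub.A + 1):
            preds[i, a - 1] = pls_predict(sub, X[i], a)[0]
        for a in range(sub.A + 1, A_max + 1):  # rank-deficient fold
            preds[i, a - 1] = preds[i, sub.A - 1]
    resid = preds - Y[:, None, :]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    one_minus_vr = 1.0 - np.sum(resid**2, axis=0) / ss_tot
    secv = np.std(resid, axis=0, ddof=1)
    return CVResult(preds, rmsecv, one_minus_vr, secv)


def select_components(cv: CVResult | np.ndarray, tol: float = 0.02) -> int:
    """Pick the number of latent variables from the SECV curve.

    Returns the smallest a whose SECV is within ``tol`` (relative) of
    the curve minimum — the point after which the cross-validation
    error "no longer decreases substantially".
    """
    curve = cv.pooled_secv if isinstance(cv, CVResult) else np.asarray(cv, dtype=float)
    if curve.size == 0:
        raise ValueError("empty SECV curve")
    best = float(np.min(curve))
    ok = np.nonzero(curve <= (1.0 + tol) * best)[0]
    return int(ok[0]) + 1
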