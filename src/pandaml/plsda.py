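"""Partial least squares discriminant analysis (PLS-DA).

Fits NIPALS PLS2 against one-hot dummy-coded class labels, exposes the
model quality metrics used in chemometrics (R2Y on training data, Q2 under
stratified cross-validation, a label-permutation test), 95% score-space
confidence ellipses, and a Mahalanobis-distance classifier operating in the
retained component space.

Conventions: X is column-centered (optionally unit-scaled) before fitting;
weights ``W`` are unit-norm; scores ``T = X W (P'W)^-1``; deflation is the
standard regression mode (X and Y both deflated by the X-scores). This is
the layout shared by the common chemometrics references, so scores and
loadings are comparable, up to column sign, with other NIPALS codes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PlsModel",
    "ModelQuality",
    "ConfidenceEllipse",
    "fit_pls",
    "project",
    "r2y",
    "q2",
    "permutation_test",
    "confidence_ellipse",
    "mahalanobis_classify",
]


def dummy_code(y, class_levels=None):
    """One-hot indicator matrix for labels ``y`` given ordered class levels."""
    y = np.asarray(y)
    if class_levels is None:
        class_levels = sorted(set(y.tolist()))
    Y = np.zeros((len(y), len(class_levels)))
    index = {c: k for k, c in enumerate(class_levels)}
    for i, lab in enumerate(y):
        if lab not in index:
            raise ValueError(f"label {lab!r} not among class levels {class_levels}")
        Y[i, index[lab]] = 1.0
    return Y, list(class_levels)


@dataclass
class PlsModel:
    """Fitted NIPALS PLS2 model with class geometry for classification."""

    n_components: int
    x_weights: np.ndarray      # W, features x components, unit columns
    x_loadings: np.ndarray     # P, features x components
    y_loadings: np.ndarray     # Q, classes x components
    x_rotations: np.ndarray    # R = W (P'W)^-1, features x components
    scores: np.ndarray         # T, training samples x components
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    class_levels: list
    class_centroids: dict      # class -> mean score vector
    class_cov: np.ndarray      # pooled within-class score covariance (+ridge)
    ridge: float = 0.0

    @property
    def n_classes(self) -> int:
        return len(self.class_levels)


@dataclass
class ModelQuality:
    r2y: float
    q2: float
    permutation_p: float | None = None
    n_permutations: int = 0
    permuted_stats: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ConfidenceEllipse:
    """Score-plane ellipse at squared Mahalanobis radius chi2.ppf(level, 2)."""

    center: np.ndarray
    covariance: np.ndarray
    level: float = 0.95

    @property
    def squared_radius(self) -> float:
        override = getattr(self, "_radius_override", None)
        if override is not None:
            return float(override)
        return float(stats.chi2.ppf(self.level, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.covariance)
        md2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return md2 <= self.squared_radius


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _nipals_pls2(X, Y, n_components, tol=1e-10, max_iter=500):
    """Core NIPALS on pre-centered X, Y. Returns W, P, Q, T (and the number
    of components actually extracted, which may be capped on degeneracy)."""
    n, p = X.shape
    m = Y.shape[1]
    Xr, Yr = X.copy(), Y.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    extracted = 0
    eps = np.finfo(float).eps
    for a in range(n_components):
        if np.linalg.norm(Xr) < 1e3 * eps or np.linalg.norm(Yr) < 1e3 * eps:
            logger.warning("residual matrix degenerate; capping at %d components",
                           extracted)
            break
        u = Yr[:, np.argmax(np.var(Yr, axis=0))].copy()
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xr.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w < 1e3 * eps:
                break
            w /= norm_w
            t_new = Xr @ w
            q = Yr.T @ t_new / (t_new @ t_new)
            u = Yr @ q / (q @ q)
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt < 1e3 * eps:
            logger.warning("score norm vanished; capping at %d components", extracted)
            break
        p_load = Xr.T @ t / tt
        q = Yr.T @ t / tt
        Xr -= np.outer(t, p_load)
        Yr -= np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
        extracted += 1
    return (W[:, :extracted], P[:, :extracted], Q[:, :extracted],
            T[:, :extracted], extracted)


def fit_pls(X, y, n_components: int = 8, scale: bool = False,
            ridge_scale: float = 1e-6) -> PlsModel:
    """Fit NIPALS PLS2 of column-centered X against dummy-coded class labels.

    Parameters
    ----------
    X : (n_samples, n_features) fully-observed matrix.
    y : class labels, >=2 classes with >=2 samples each.
    n_components : number of latent components (default 8).
    scale : also divide columns by their sd (default False; upstream
        autoscaling normally handles this).
    ridge_scale : relative ridge added to the pooled score covariance,
        lambda = ridge_scale * trace(cov) / n_components.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X must be fully observed (impute first)")
    y = np.asarray(y)
    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    if counts.min() < 2:
        small = levels[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    n, p = X.shape
    cap = min(n - 1, p)
    if n_components > cap:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)={cap}")
    Y, class_levels = dummy_code(y)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Xc = (X - x_mean) / x_sd
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W, P, Q, T, extracted = _nipals_pls2(Xc, Yc, n_components)
    if extracted == 0:
        raise ValueError("no PLS components could be extracted (X constant?)")
    R = W @ np.linalg.inv(P.T @ W)

    centroids = {c: T[y == c].mean(axis=0) for c in class_levels}
    pooled = np.zeros((extracted, extracted))
    for c in class_levels:
        D = T[y == c] - centroids[c]
        pooled += D.T @ D
    pooled /= max(n - len(class_levels), 1)
    lam = ridge_scale * np.trace(pooled) / extracted
    pooled += lam * np.eye(extracted)

    return PlsModel(
        n_components=extracted, x_weights=W, x_loadings=P, y_loadings=Q,
        x_rotations=R, scores=T, x_mean=x_mean, x_sd=x_sd, y_mean=y_mean,
        class_levels=class_levels, class_centroids=centroids,
        class_cov=pooled, ridge=lam)


def project(model: PlsModel, X_new) -> np.ndarray:
    """Project new samples into the model's score space."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"feature count {X_new.shape[1]} does not match model "
            f"({model.x_mean.shape[0]})")
    return (X_new - model.x_mean) / model.x_sd @ model.x_rotations


def predict_dummy(model: PlsModel, X) -> np.ndarray:
    """Reconstructed dummy-class matrix from the retained components."""
    return project(model, X) @ model.y_loadings.T + model.y_mean


def r2y(model: PlsModel, X, y) -> float:
    """Fraction of dummy-class variance explained: 1 - SS_res / SS_tot."""
    Y, _ = dummy_code(y, model.class_levels)
    Yhat = predict_dummy(model, X)
    ss_res = float(((Y - Yhat) ** 2).sum())
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("labels have zero variance")
    return 1.0 - ss_res / ss_tot


def q2(X, y, n_components: int = 8, folds: int = 7, seed: int = 0,
       scale: bool = False) -> float:
    """Cross-validated predictive ability 1 - PRESS / SS_tot.

    Folds are stratified by class and the assignment is seeded. Within each
    fold the model (centering included) is refit on the training portion
    only; test-sample dummy vectors are predicted and pooled into PRESS.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ValueError("smallest class too small for any stratified CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    ss_tot = 0.0
    levels = sorted(set(y.tolist()))
    for train_idx, test_idx in skf.split(X, y):
        if len(set(y[train_idx])) < len(levels):
            raise ValueError("a class is absent from a training fold")
        ncomp = min(n_components, len(train_idx) - 1, X.shape[1])
        model = fit_pls(X[train_idx], y[train_idx], n_components=ncomp,
                        scale=scale)
        Y_test, _ = dummy_code(y[test_idx], model.class_levels)
        Yhat = predict_dummy(model, X[test_idx])
        press += float(((Y_test - Yhat) ** 2).sum())
        ss_tot += float(((Y_test - model.y_mean) ** 2).sum())
    return 1.0 - press / ss_tot


def permutation_test(X, y, n_components: int = 8, n_perm: int = 999,
                     seed: int = 0, statistic: str = "q2",
                     folds: int = 7) -> ModelQuality:
    """Label-permutation test of PLS-DA model quality.

    Recomputes the chosen statistic (Q2 by default, R2Y optional) under
    ``n_perm`` random relabelings; p = (1 + #{perm >= observed}) / (n_perm + 1),
    so the smallest attainable p is 1 / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("q2", "r2"):
        raise ValueError("statistic must be 'q2' or 'r2'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def stat(labels, stat_seed):
        if statistic == "q2":
            return q2(X, labels, n_components=n_components, folds=folds,
                      seed=stat_seed)
        model = fit_pls(X, labels, n_components=n_components)
        return r2y(model, X, labels)

    observed = stat(y, seed)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y)
        while len(set(perm.tolist())) < 2:  # pragma: no cover - permutation keeps counts
            perm = rng.permutation(y)
        try:
            perm_stats[b] = stat(perm, seed + 1 + b)
        except ValueError:
            perm_stats[b] = -np.inf
    p = (1 + int((perm_stats >= observed).sum())) / (n_perm + 1)
    model = fit_pls(X, y, n_components=min(n_components, X.shape[0] - 1,
                                           X.shape[1]))
    return ModelQuality(r2y=r2y(model, X, y),
                        q2=observed if statistic == "q2" else np.nan,
                        permutation_p=p, n_permutations=n_perm,
                        permuted_stats=perm_stats)


def confidence_ellipse(scores_2d, level: float = 0.95,
                       radius: str = "chi2") -> ConfidenceEllipse:
    """Confidence ellipse for a cloud of 2-D scores.

    ``radius='chi2'`` (default) uses the chi-square quantile with 2 df;
    ``radius='f'`` uses the Hotelling small-sample F version.
    """
    S = np.asarray(scores_2d, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores_2d must be an n x 2 matrix")
    if S.shape[0] < 3:
        raise ValueError("need at least 3 points for a covariance ellipse")
    ell = ConfidenceEllipse(center=S.mean(axis=0), covariance=np.cov(S.T, ddof=1),
                            level=level)
    if radius == "f":
        n = S.shape[0]
        ell._radius_override = 2 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    return ell


def mahalanobis_classify(model: PlsModel, X_new, scores: np.ndarray | None = None):
    """Classify samples by Mahalanobis distance to class centroids in score
    space, with the pooled (ridge-regularized) score covariance.

    Returns ``(labels, distances)`` where ``distances`` is samples x classes
    in the order of ``model.class_levels``. Ties break by class order.
    """
    T = project(model, X_new) if scores is None else np.atleast_2d(scores)
    try:
        inv = np.linalg.inv(model.class_cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled score covariance is singular even after "
                         "ridge regularization") from exc
    # explicit per-sample quadratic form: the score space is small (<=
    # n_components dims) so this is cheap and bit-reproducible
    dists = np.empty((T.shape[0], model.n_classes))
    for i in range(T.shape[0]):
        for k, c in enumerate(model.class_levels):
            d = T[i] - model.class_centroids[c]
            dists[i, k] = np.sqrt(float(d @ inv @ d))
    labels = [model.class_levels[k] for k in dists.argmin(axis=1)]
    return labels, dists


def classify_proba(model: PlsModel, X_new) -> np.ndarray:
    """Soft class memberships from Mahalanobis distances.

    Probabilities are softmax(-d^2/2), i.e. Gaussian class likelihoods with
    the shared pooled covariance and equal priors; used for AUC/loss
    evaluation of the PLS-DA classifier workflow.
    """
    _, dists = mahalanobis_classify(model, X_new)
    log_lik = -0.5 * dists ** 2
    log_lik -= log_lik.max(axis=1, keepdims=True)
    p = np.exp(log_lik)
    return p / p.sum(axis=1, keepdims=True)
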