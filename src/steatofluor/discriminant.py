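"""PCA reduction and quadratic discriminant classification.

The classification chain for one excitation wavelength:

1. PCA on the matrix of normalized spectra (rows = observations); the first
   six principal components are retained, with a warning when they explain
   less than 90% of the variance.
2. Box's M likelihood-ratio test of covariance equality across groups gates
   the linear vs quadratic discriminant choice; unequal covariances (the
   usual outcome on these spectra) recommend QDA.
3. QDA with class-specific Gaussian densities yields labels and posterior
   probabilities; performance is reported both in-sample (classification) and
   by leave-one-out cross-validation, as paired confusion matrices.
4. A two-dimensional canonical plane (eigenvectors of W^-1 B, scaled to unit
   pooled within-class variance) visualizes the three groups, with decision
   boundaries rasterized by classifying every node of a grid spanning the
   observed canonical scores.

All estimators are implemented directly from the matrix formulas; scikit-learn
serves only as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "QDAModel",
    "ConfusionMatrix",
    "BoxMResult",
    "CanonicalPlane",
    "pca_fit",
    "covariance_equality_test",
    "qda_fit",
    "qda_predict",
    "classify",
    "loocv",
    "confusion_rates",
    "canonical_plane",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    mean: np.ndarray  # (p,)
    loadings: np.ndarray  # (k, p), orthonormal rows
    explained_variance_fraction: np.ndarray  # (k,)
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.loadings.T


def pca_fit(X: np.ndarray, n_components: int = 6, variance_floor: float = 0.90) -> PCAModel:
    """Principal components of mean-centered rows via singular value decomposition.

    Component signs are fixed so each loading's largest-magnitude entry is
    positive, making the decomposition deterministic.  A warning is issued
    when the kept components explain less than ``variance_floor`` of the
    total variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (observations x wavelengths)")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least two observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2  # proportional to component variances
    rank = int(np.sum(var > var[0] * 1e-12)) if var.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds the data rank {rank}")
    total = var.sum()
    fractions = var[:n_components] / total
    loadings = Vt[:n_components]
    # deterministic sign convention
    flip = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    explained = float(fractions.sum())
    if explained < variance_floor:
        warnings.warn(
            f"first {n_components} components explain {100 * explained:.1f}% of the "
            f"variance, below the {100 * variance_floor:.0f}% floor",
            stacklevel=2,
        )
    return PCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance_fraction=fractions,
        n_components=n_components,
    )


# ---------------------------------------------------------------------------
# Covariance homogeneity (Box's M)


@dataclass
class BoxMResult:
    statistic: float  # chi-square approximated statistic
    m_statistic: float  # uncorrected -2 log likelihood ratio
    df: int
    p_value: float
    recommendation: str  # "QDA" if covariances differ, else "LDA"


def covariance_equality_test(
    scores_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> BoxMResult:
    """Box's M test of equal group covariance matrices.

    Uses the standard chi-square approximation; a p-value below ``alpha``
    rejects homogeneity and recommends the quadratic discriminant.
    """
    groups = list(scores_by_group)
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    mats = [np.atleast_2d(np.asarray(scores_by_group[g], dtype=float)) for g in groups]
    p = mats[0].shape[1]
    ns = np.array([m.shape[0] for m in mats])
    if np.any(ns <= p):
        small = [g for g, n in zip(groups, ns) if n <= p]
        raise ValueError(f"groups {small} have too few observations for dimension {p}")
    k = len(groups)
    N = int(ns.sum())
    covs = [np.cov(m, rowvar=False, ddof=1) for m in mats]
    pooled = sum((n - 1) * S for n, S in zip(ns, covs)) / (N - k)
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance matrix is singular")
    m_stat = (N - k) * logdet_pooled
    for n, S in zip(ns, covs):
        sign_i, logdet_i = np.linalg.slogdet(S)
        if sign_i <= 0:
            raise np.linalg.LinAlgError("a group covariance matrix is singular")
        m_stat -= (n - 1) * logdet_i
    c1 = (
        (2 * p**2 + 3 * p - 1)
        / (6.0 * (p + 1) * (k - 1))
        * (np.sum(1.0 / (ns - 1)) - 1.0 / (N - k))
    )
    statistic = m_stat * (1.0 - c1)
    df = p * (p + 1) * (k - 1) // 2
    p_value = float(stats.chi2.sf(statistic, df))
    return BoxMResult(
        statistic=float(statistic),
        m_statistic=float(m_stat),
        df=df,
        p_value=p_value,
        recommendation="QDA" if p_value < alpha else "LDA",
    )


# ---------------------------------------------------------------------------
# QDA


@dataclass
class QDAModel:
    labels: list[str]
    priors: np.ndarray  # (k,), sums to 1
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    log_dets: np.ndarray = field(init=False)
    _cholesky: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        self._cholesky = []
        log_dets = []
        for lab, S in zip(self.labels, self.covariances):
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError:
                # exact singularity only: tiny ridge, with a logged warning
                ridge = 1e-10 * np.trace(S)
                logger.warning("covariance of group %s is singular; adding ridge %.3e", lab, ridge)
                try:
                    L = np.linalg.cholesky(S + ridge * np.eye(S.shape[0]))
                except np.linalg.LinAlgError as exc:
                    raise np.linalg.LinAlgError(
                        f"covariance matrix of group {lab!r} is singular"
                    ) from exc
            self._cholesky.append(L)
            log_dets.append(2.0 * np.sum(np.log(np.diag(L))))
        self.log_dets = np.array(log_dets)

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def qda_fit(scores_by_group: dict[str, np.ndarray], priors: str = "empirical") -> QDAModel:
    """Class means, sample covariances (n-1 denominator) and priors.

    ``priors`` is ``"empirical"`` (class frequencies) or ``"uniform"``.
    """
    labels = list(scores_by_group)
    mats = [np.atleast_2d(np.asarray(scores_by_group[g], dtype=float)) for g in labels]
    d = mats[0].shape[1]
    ns = np.array([m.shape[0] for m in mats])
    for g, m in zip(labels, mats):
        if m.shape[0] <= d:
            raise ValueError(
                f"group {g!r} has {m.shape[0]} observations, not enough for an "
                f"invertible {d}x{d} covariance"
            )
    if priors == "empirical":
        pri = ns / ns.sum()
    elif priors == "uniform":
        pri = np.full(len(labels), 1.0 / len(labels))
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")
    means = np.stack([m.mean(axis=0) for m in mats])
    covs = np.stack([np.cov(m, rowvar=False, ddof=1).reshape(d, d) for m in mats])
    return QDAModel(labels=labels, priors=pri, means=means, covariances=covs)


def _log_discriminants(model: QDAModel, X: np.ndarray) -> np.ndarray:
    """d_k(x) = ln pi_k - 1/2 ln|S_k| - 1/2 (x-mu_k)' S_k^-1 (x-mu_k), shape (n, k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.dim:
        raise ValueError(f"score dimension {X.shape[1]} does not match model dimension {model.dim}")
    out = np.empty((X.shape[0], len(model.labels)))
    with np.errstate(divide="ignore"):
        log_priors = np.log(model.priors)
    for k, (mu, L) in enumerate(zip(model.means, model._cholesky)):
        z = linalg.solve_triangular(L, (X - mu).T, lower=True)
        maha = np.sum(z**2, axis=0)
        out[:, k] = log_priors[k] - 0.5 * model.log_dets[k] - 0.5 * maha
    return out


def qda_predict(model: QDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and posterior probabilities for score vectors.

    Posteriors are the softmax of the log discriminants (Bayes' rule for
    Gaussian class densities).  Exact ties in the argmax go to the
    lexicographically first label and are logged.
    """
    d = _log_discriminants(model, X)
    shifted = d - d.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posteriors = expd / expd.sum(axis=1, keepdims=True)
    order = np.argsort(model.labels)  # lexicographic preference among exact ties
    best = np.full(d.shape[0], -1)
    best_val = np.full(d.shape[0], -np.inf)
    tie_seen = False
    for k in order:
        col = d[:, k]
        better = col > best_val
        ties = col == best_val
        if np.any(ties):
            tie_seen = True
        best = np.where(better, k, best)
        best_val = np.where(better, col, best_val)
    if tie_seen:
        logger.info("tied discriminants encountered; broke ties toward the first label alphabetically")
    labels = np.array([model.labels[k] for k in best])
    return labels, posteriors


# ---------------------------------------------------------------------------
# Confusion matrices, classification and LOOCV


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # (k, k) actual x predicted
    scheme: str  # "classification" or "cross-validation"

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _confusion(labels: list[str], actual: np.ndarray, predicted: np.ndarray, scheme: str) -> ConfusionMatrix:
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts, scheme=scheme)


def classify(model: QDAModel, X: np.ndarray, y: np.ndarray) -> ConfusionMatrix:
    """In-sample confusion matrix of a fitted model (all observations as training data)."""
    pred, _ = qda_predict(model, X)
    return _confusion(model.labels, np.asarray(y), pred, "classification")


def loocv(
    X: np.ndarray, y: np.ndarray, priors: str = "empirical", return_posteriors: bool = False
):
    """Leave-one-out cross-validation of the QDA classifier.

    Each observation is predicted by a model refit on all others; the PCA
    projection producing ``X`` is treated as fixed.  Deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    labels = list(dict.fromkeys(y))
    d = X.shape[1]
    for lab in labels:
        if np.sum(y == lab) - 1 <= d:
            raise ValueError(
                f"group {lab!r} would retain <= {d} observations after deletion; "
                "covariance would be singular"
            )
    preds = np.empty(y.shape, dtype=object)
    posts = np.zeros((len(y), len(labels)))
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        model = qda_fit({lab: X[keep & (y == lab)] for lab in labels}, priors=priors)
        p_lab, p_post = qda_predict(model, X[i : i + 1])
        preds[i] = p_lab[0]
        posts[i] = p_post[0]
    cm = _confusion(labels, y, preds, "cross-validation")
    if return_posteriors:
        return cm, posts
    return cm


def confusion_rates(cm: ConfusionMatrix) -> dict:
    """Success and error percentages, with the total error under both definitions.

    ``total_error_pct_pooled`` is misclassifications over the overall number
    of observations; ``total_error_pct_unweighted`` is the plain mean of the
    per-group error rates.  Both appear in published summaries, so both are
    reported and labelled.
    """
    rows = cm.row_totals()
    if np.any(rows == 0):
        empty = [lab for lab, r in zip(cm.labels, rows) if r == 0]
        raise ValueError(f"groups {empty} have no observations")
    diag = np.diag(cm.counts)
    success = 100.0 * diag / rows
    error = 100.0 - success
    pooled_error = 100.0 * (cm.n - diag.sum()) / cm.n
    return {
        "scheme": cm.scheme,
        "per_group": {
            lab: {"success_pct": float(s), "error_pct": float(e)}
            for lab, s, e in zip(cm.labels, success, error)
        },
        "total_error_pct_pooled": float(pooled_error),
        "total_error_pct_unweighted": float(error.mean()),
        "total_success_pct_pooled": float(100.0 - pooled_error),
    }


# ---------------------------------------------------------------------------
# Canonical plane


@dataclass
class CanonicalPlane:
    labels: list[str]
    axes: np.ndarray  # (d, 2) canonical directions in PC space
    eigenvalues: np.ndarray  # (2,) between/within variance ratios
    scores: np.ndarray  # (n, 2)
    observation_labels: np.ndarray
    centroids: np.ndarray  # (k, 2)
    grid_x: np.ndarray
    grid_y: np.ndarray
    raster: np.ndarray  # (ny, nx) indices into labels


def canonical_plane(
    X: np.ndarray,
    y: np.ndarray,
    grid_resolution: int = 400,
    margin: float = 0.10,
    priors: str = "empirical",
) -> CanonicalPlane:
    """Two-dimensional canonical discriminant plane with QDA decision raster.

    The axes are the leading eigenvectors of ``W^-1 B`` (within/between
    scatter), scaled so the pooled within-class variance of each canonical
    score is one.  Three groups yield exactly two canonical variables.  A QDA
    refit on the 2-D canonical scores classifies every node of a
    ``grid_resolution`` x ``grid_resolution`` grid spanning the observed
    scores plus a ``margin`` fraction on each side.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    labels = list(dict.fromkeys(y))
    k = len(labels)
    if k < 2:
        raise ValueError("canonical analysis needs at least two groups")
    n, d = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((d, d))
    B = np.zeros((d, d))
    mus = []
    for lab in labels:
        Xi = X[y == lab]
        mu = Xi.mean(axis=0)
        mus.append(mu)
        W += (Xi - mu).T @ (Xi - mu)
        B += Xi.shape[0] * np.outer(mu - grand, mu - grand)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("pooled within-class scatter is singular") from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(2, k - 1) if k > 2 else 1
    n_axes = 2 if k >= 3 else k - 1
    idx = order[:n_axes]
    A = evecs[:, idx]
    lam = evals[idx]
    # scale to unit pooled within-class variance: a' (W/(n-k)) a = 1
    for j in range(A.shape[1]):
        scale = float(A[:, j] @ (W / (n - k)) @ A[:, j])
        A[:, j] /= np.sqrt(scale)
        # deterministic orientation
        if A[np.argmax(np.abs(A[:, j])), j] < 0:
            A[:, j] = -A[:, j]
    if A.shape[1] == 1:  # pad a null second axis for a degenerate 2-group call
        A = np.hstack([A, np.zeros((d, 1))])
        lam = np.append(lam, 0.0)
    scores = (X - grand) @ A
    centroids = np.stack([(mu - grand) @ A for mu in mus])

    model = qda_fit({lab: scores[y == lab] for lab in labels}, priors=priors)
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    gx = np.linspace(lo[0] - margin * span[0], hi[0] + margin * span[0], grid_resolution)
    gy = np.linspace(lo[1] - margin * span[1], hi[1] + margin * span[1], grid_resolution)
    XX, YY = np.meshgrid(gx, gy)
    nodes = np.column_stack([XX.ravel(), YY.ravel()])
    pred, _ = qda_predict(model, nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    raster = np.array([index[p] for p in pred]).reshape(grid_resolution, grid_resolution)
    return CanonicalPlane(
        labels=labels,
        axes=A,
        eigenvalues=np.asarray(lam),
        scores=scores,
        observation_labels=y,
        centroids=centroids,
        grid_x=gx,
        grid_y=gy,
        raster=raster,
    )
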