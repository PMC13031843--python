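"""Communication-subspace analyses.

Reduced-rank regression on top of ridge regression, cross-validated
performance-by-rank curves with the one-SEM rank rule, principal-angle
subspace similarity, spatial/temporal degeneracy, and ablation of predictive
dimensions.

Conventions
-----------
* ``X`` is ``t x p`` source activity, ``Y`` is ``t x q`` target activity.
* Ridge: ``B_ridge = (X'X + lambda I)^-1 X'Y`` with ``lambda`` selected by
  k-fold cross-validation over a log-spaced grid.
* RRR: ``V`` holds the top-``m`` principal directions of the ridge-predicted
  targets ``Yhat = X B_ridge``; ``B_rrr = B_ridge V V'`` and the predictive
  dimensions are the columns of ``B_bar = B_ridge V``.
* Prediction performance is ``1 - cvl`` where ``cvl`` is the mean
  cross-validated normalized squared error (per-target SSE / SS_tot,
  averaged over targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 10))


# ---------------------------------------------------------------------------
# ridge regression
# ---------------------------------------------------------------------------


@dataclass
class RidgeFit:
    B_ridge: np.ndarray
    lam: float
    cv_table: dict = field(default_factory=dict)  # lambda -> mean cv loss


def _ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    p = X.shape[1]
    G = X.T @ X + lam * np.eye(p)
    if lam == 0.0:
        if np.linalg.matrix_rank(X) < p:
            raise np.linalg.LinAlgError(
                "X is rank-deficient; ridge with lambda=0 is singular"
            )
        return np.linalg.solve(G, X.T @ Y)
    return np.linalg.solve(G, X.T @ Y)


def _nse(Y_true: np.ndarray, Y_pred: np.ndarray, y_ref: np.ndarray) -> float:
    """Normalized squared error: per-column SSE / SS_tot, averaged over columns.

    ``y_ref`` is the per-column reference mean (from the training fold).
    """
    sse = ((Y_true - Y_pred) ** 2).sum(axis=0)
    sst = ((Y_true - y_ref) ** 2).sum(axis=0)
    sst = np.where(sst <= 0, np.nan, sst)
    return float(np.nanmean(sse / sst))


def _folds(t: int, n_folds: int):
    if t < n_folds:
        raise ValueError(f"fewer samples ({t}) than folds ({n_folds})")
    return list(KFold(n_splits=n_folds, shuffle=False).split(np.arange(t)))


def ridge_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
) -> RidgeFit:
    """Cross-validated ridge regression.

    ``lambda_grid`` may be a scalar to skip selection. Passing ``0`` with a
    rank-deficient ``X`` raises a singularity error.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    if np.isscalar(lambda_grid):
        lam = float(lambda_grid)
        return RidgeFit(B_ridge=_ridge_solve(X, Y, lam), lam=lam)
    grid = [float(l) for l in lambda_grid]
    splits = _folds(X.shape[0], folds)
    table: dict[float, float] = {}
    for lam in grid:
        losses = []
        for tr, te in splits:
            B = _ridge_solve(X[tr], Y[tr], lam)
            losses.append(_nse(Y[te], X[te] @ B, Y[tr].mean(axis=0)))
        table[lam] = float(np.mean(losses))
    lam = min(grid, key=lambda l: table[l])
    return RidgeFit(B_ridge=_ridge_solve(X, Y, lam), lam=lam, cv_table=table)


# ---------------------------------------------------------------------------
# reduced-rank regression
# ---------------------------------------------------------------------------


@dataclass
class RRRFit:
    V: np.ndarray  # q x m, orthonormal
    B_bar: np.ndarray  # p x m predictive dimensions
    B_rrr: np.ndarray  # p x q
    rank: int
    lam: float
    perf_by_rank: dict = field(default_factory=dict)  # rank -> (perf, sem)
    optimal_rank: int | None = None


def rrr_fit(
    X: np.ndarray,
    Y: np.ndarray,
    m: int,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    ridge: RidgeFit | None = None,
) -> RRRFit:
    """Rank-``m`` reduced-rank regression on top of a ridge fit.

    ``V`` contains the top-``m`` right singular vectors of the ridge
    prediction ``X B_ridge``; ``m = q`` reproduces the ridge fit exactly and
    ``m = 0`` yields the zero predictor.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    q = Y.shape[1] if Y.ndim == 2 else 1
    if not 0 <= m <= q:
        raise ValueError(f"rank m={m} must lie in [0, q={q}]")
    if ridge is None:
        ridge = ridge_fit(X, Y, lambda_grid=lambda_grid, folds=folds)
    B = ridge.B_ridge
    if m == 0:
        return RRRFit(
            V=np.zeros((q, 0)),
            B_bar=np.zeros((X.shape[1], 0)),
            B_rrr=np.zeros_like(B),
            rank=0,
            lam=ridge.lam,
        )
    Yhat = X @ B
    _, _, Vt = np.linalg.svd(Yhat, full_matrices=False)
    V = Vt[:m].T
    B_bar = B @ V
    return RRRFit(V=V, B_bar=B_bar, B_rrr=B_bar @ V.T, rank=m, lam=ridge.lam)


def performance_curve(
    X: np.ndarray,
    Y: np.ndarray,
    ranks=range(1, 11),
    folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> RRRFit:
    """Cross-validated performance-by-rank curve with the one-SEM rank rule.

    For each fold the ridge and the principal directions are fit on the
    training split at the regularizer selected once on the full data; each
    rank's performance ``1 - nse`` is evaluated on the test split. The
    optimal rank is the smallest whose mean performance lies within one SEM
    of the peak. Returns the full-data RRR fit at the optimal rank with the
    curve attached.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ranks = [int(r) for r in ranks]
    ridge = ridge_fit(X, Y, lambda_grid=lambda_grid, folds=folds)
    splits = _folds(X.shape[0], folds)
    perf = np.zeros((len(ranks), len(splits)))
    for f, (tr, te) in enumerate(splits):
        B = _ridge_solve(X[tr], Y[tr], ridge.lam)
        _, _, Vt = np.linalg.svd(X[tr] @ B, full_matrices=False)
        ybar = Y[tr].mean(axis=0)
        for i, r in enumerate(ranks):
            V = Vt[:r].T
            pred = X[te] @ (B @ V) @ V.T
            perf[i, f] = 1.0 - _nse(Y[te], pred, ybar)
    mean = perf.mean(axis=1)
    sem = perf.std(axis=1, ddof=1) / np.sqrt(perf.shape[1])
    peak = int(np.argmax(mean))
    threshold = mean[peak] - sem[peak]
    optimal = next(r for r, mu in zip(ranks, mean) if mu >= threshold)
    fit = rrr_fit(X, Y, m=optimal, ridge=ridge)
    fit.perf_by_rank = {
        r: (float(mu), float(s)) for r, mu, s in zip(ranks, mean, sem)
    }
    fit.optimal_rank = optimal
    return fit


# ---------------------------------------------------------------------------
# subspace similarity
# ---------------------------------------------------------------------------


def _orthonormalize(basis: np.ndarray) -> np.ndarray:
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if basis.shape[1] == 0:
        raise ValueError("zero-dimensional basis")
    Q, R = np.linalg.qr(basis)
    keep = np.abs(np.diag(R)) > 1e-12 * max(basis.shape)
    if not np.any(keep):
        raise ValueError("basis has no linearly independent columns")
    return Q[:, keep]


def subspace_similarity(
    basis_a: np.ndarray, basis_b: np.ndarray, angle: str = "largest"
) -> float:
    """Cosine of the principal angle between two subspaces, in [0, 1].

    Bases are orthonormalized by QR internally. ``angle='largest'`` (default)
    reports the cosine of the largest principal angle — the smallest singular
    value of ``Qa' Qb`` — matching the referenced routine; ``'smallest'``
    reports the cosine of the smallest angle instead.
    """
    Qa = _orthonormalize(basis_a)
    Qb = _orthonormalize(basis_b)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    k = min(Qa.shape[1], Qb.shape[1])
    s = np.clip(s[:k], 0.0, 1.0)
    if angle == "largest":
        return float(s[-1]) if s.size else 0.0
    if angle == "smallest":
        return float(s[0]) if s.size else 0.0
    raise ValueError("angle must be 'largest' or 'smallest'")


def spatial_degeneracy(
    X: np.ndarray,
    Y_a: np.ndarray,
    Y_b: np.ndarray,
    dims: int = 3,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    angle: str = "largest",
) -> float:
    """Similarity of the communication subspaces from one source to two targets.

    Fits rank-``dims`` RRR from ``X`` to each target on the matched source
    samples and compares the ``B_bar`` column spaces (first ``dims``
    predictive dimensions).
    """
    fa = rrr_fit(X, Y_a, m=dims, lambda_grid=lambda_grid, folds=folds)
    fb = rrr_fit(X, Y_b, m=dims, lambda_grid=lambda_grid, folds=folds)
    if fa.B_bar.shape[1] < dims or fb.B_bar.shape[1] < dims:
        raise ValueError(f"fit rank below requested dims={dims}")
    return subspace_similarity(fa.B_bar[:, :dims], fb.B_bar[:, :dims], angle=angle)


def temporal_degeneracy(
    window_pairs,
    dims: int = 3,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    angle: str = "largest",
) -> np.ndarray:
    """Pairwise subspace similarity across per-window RRR fits.

    ``window_pairs`` is an ordered sequence of ``(X_w, Y_w)`` matrices, one
    per time window (e.g. ITI, stimulus, delay 1-4, action). Returns a
    ``w x w`` symmetric matrix with unit diagonal.
    """
    bases = []
    for X_w, Y_w in window_pairs:
        X_w = np.asarray(X_w, dtype=float)
        if X_w.shape[0] <= max(folds, X_w.shape[1]):
            raise ValueError("window has insufficient frames for a per-window fit")
        f = rrr_fit(X_w, Y_w, m=dims, lambda_grid=lambda_grid, folds=folds)
        bases.append(f.B_bar[:, :dims])
    w = len(bases)
    sim = np.eye(w)
    for i in range(w):
        for j in range(i + 1, w):
            sim[i, j] = sim[j, i] = subspace_similarity(
                bases[i], bases[j], angle=angle
            )
    return sim


# ---------------------------------------------------------------------------
# ablation of predictive dimensions
# ---------------------------------------------------------------------------


@dataclass
class AblationProjection:
    M: np.ndarray  # m x p
    Sigma: np.ndarray  # p x p source covariance
    Q: np.ndarray  # p x (p - m), orthonormal, M Q = 0
    X_hat: np.ndarray  # projected source activity


def ablate_predictive_dims(
    X: np.ndarray, fit: RRRFit, m_remove: int
) -> AblationProjection:
    """Project source activity onto the subspace uncorrelated with the first
    ``m_remove`` predictive dimensions.

    ``M = B_bar' Sigma`` with ``Sigma`` the source covariance; ``Q`` holds the
    last ``p - m_remove`` right singular vectors of ``M``, so ``M Q = 0`` and
    ``Q'Q = I``. ``m_remove = 0`` returns the identity basis.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if m_remove < 0 or m_remove >= p:
        raise ValueError(f"m_remove={m_remove} must lie in [0, p={p})")
    if m_remove > fit.B_bar.shape[1]:
        raise ValueError("m_remove exceeds the number of predictive dimensions")
    Sigma = np.cov(X, rowvar=False)
    if m_remove == 0:
        Q = np.eye(p)
        M = np.zeros((0, p))
    else:
        M = fit.B_bar[:, :m_remove].T @ Sigma
        _, _, Vt = np.linalg.svd(M, full_matrices=True)
        Q = Vt[m_remove:].T
    return AblationProjection(M=M, Sigma=Sigma, Q=Q, X_hat=X @ Q)


def cv_ridge_performance(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
) -> tuple[float, float]:
    """Cross-validated ridge prediction performance ``1 - nse`` and its SEM."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    ridge = ridge_fit(X, Y, lambda_grid=lambda_grid, folds=folds)
    perfs = []
    for tr, te in _folds(X.shape[0], folds):
        B = _ridge_solve(X[tr], Y[tr], ridge.lam)
        perfs.append(1.0 - _nse(Y[te], X[te] @ B, Y[tr].mean(axis=0)))
    perfs = np.asarray(perfs)
    return float(perfs.mean()), float(perfs.std(ddof=1) / np.sqrt(perfs.size))


def ablated_performance(
    X: np.ndarray,
    Y: np.ndarray,
    fit: RRRFit,
    m_remove: int,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
) -> dict:
    """Ridge performance predicting ``Y`` after removing predictive dimensions.

    Returns raw ablated and unablated performance plus their ratio
    (``normalized``), the measure reported for ablation experiments.
    """
    proj = ablate_predictive_dims(X, fit, m_remove)
    full, _ = cv_ridge_performance(X, Y, lambda_grid=lambda_grid, folds=folds)
    ablated, _ = cv_ridge_performance(
        proj.X_hat, Y, lambda_grid=lambda_grid, folds=folds
    )
    return {
        "projection": proj,
        "performance": ablated,
        "unablated_performance": full,
        "normalized": ablated / full if full != 0 else float("nan"),
    }
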