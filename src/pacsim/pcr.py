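"""Principal component regression with Procrustes cross-validation.

The response (the hypotensive effect ΔIOP, mm Hg) is regressed on the
leading principal components of the autoscaled predictor matrix; the
latent-space model is then collapsed to raw-unit coefficients
ŷ = b0 + Σ b_i x_i so that predictions need no reference to the latent
basis.  Model quality is summarised by

    RMSE = sqrt( (1/I) Σ (y_i - ŷ_i)^2 )

over the calibration set (RMSEC) and over a pseudo-validation set built
by Procrustes cross-validation (RMSECV).  PCV fits a local model on each
cross-validation split, rotates its loadings onto the global ones by an
orthogonal Procrustes alignment, and re-expresses the held-out rows in
the global basis; applying the single global model to the resulting
matrix then reproduces segment-wise cross-validated prediction errors
without ever storing K separate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddsimca import InsufficientDataError, detect_outliers, fit_simca

_RANK_TOL = 1e-10


@dataclass
class PCRModel:
    """Fitted PCR model in both latent and raw-unit form."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    loadings: np.ndarray  # p x a
    latent_weights: np.ndarray  # a
    b0: float
    b: np.ndarray  # raw-unit slopes, length p
    a: int
    rmsec: float
    n_used: int
    rmsecv: float | None = None
    removed: list[int] = field(default_factory=list)
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.b0 + X @ self.b

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        """Prediction through the score space; must agree with predict()."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        T = ((X - self.x_mean) / self.x_sd) @ self.loadings
        return self.y_mean + T @ self.latent_weights


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def fit_pcr(X: np.ndarray, y: np.ndarray, a: int = 2) -> PCRModel:
    """Fit an a-component PCR model of y on X.

    Predictors are autoscaled, the response is centred but not scaled
    (errors stay in mm Hg).  Raises on a >= rank(X) or n <= a.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on n")
    if n <= a:
        raise InsufficientDataError(f"need n > a, got n={n}, a={a}")

    Z, x_mean, x_sd = _autoscale(X)
    y_mean = float(np.mean(y))
    yc = y - y_mean

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
    if a > rank:
        raise InsufficientDataError(f"a={a} exceeds rank(X)={rank}")
    loadings = Vt[:a].T
    T = Z @ loadings
    q, *_ = np.linalg.lstsq(T, yc, rcond=None)

    b_scaled = loadings @ q
    b = b_scaled / x_sd
    b0 = y_mean - float(x_mean @ b)

    resid = yc - T @ q
    rmsec = float(np.sqrt(np.mean(resid**2)))
    return PCRModel(
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        loadings=loadings,
        latent_weights=q,
        b0=b0,
        b=b,
        a=a,
        rmsec=rmsec,
        n_used=n,
    )


@dataclass
class PseudoValidationSet:
    """PCV output: a matrix shaped like X whose rows, pushed through the
    global calibration model, reproduce cross-validated predictions."""

    X_pv: np.ndarray
    y: np.ndarray
    segments: list[np.ndarray]


def _segments(n: int, K: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, K)]


def pcv_set(
    X: np.ndarray, y: np.ndarray, a: int, K: int, seed: int = 0
) -> PseudoValidationSet:
    """Build a Procrustes pseudo-validation set with K segments.

    Segments are contiguous blocks of a seeded random permutation.  For
    each segment the remaining rows define a local PCA; the orthogonal
    rotation R minimising ||P_local R - P_global||_F (sign-aligned by
    construction) maps local scores of the held-out rows into the global
    basis, and the orthogonal residual is projected outside the global
    score space.  K = n gives leave-one-out behaviour.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if K < 2:
        raise ValueError("K must be >= 2")
    if K < n and n < 2 * K:
        raise InsufficientDataError(f"need n >= 2K (or K = n), got n={n}, K={K}")
    if K > n:
        raise ValueError("K cannot exceed n")

    Z, x_mean, x_sd = _autoscale(X)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    P_g = Vt[:a].T

    X_pv = np.empty_like(Z)
    segs = _segments(n, K, seed)
    for seg in segs:
        keep = np.setdiff1d(np.arange(n), seg)
        Z_loc = Z[keep]
        _, _, Vt_loc = np.linalg.svd(Z_loc, full_matrices=False)
        P_k = Vt_loc[:a].T
        # orthogonal Procrustes alignment of the local basis onto the global
        Uo, _, Vto = np.linalg.svd(P_k.T @ P_g)
        R = Uo @ Vto
        T_k = Z[seg] @ P_k
        body = T_k @ R @ P_g.T
        E_k = Z[seg] - T_k @ P_k.T
        E_pv = E_k - (E_k @ P_g) @ P_g.T
        X_pv[seg] = body + E_pv
    X_pv = X_pv * x_sd + x_mean
    return PseudoValidationSet(X_pv=X_pv, y=y.copy(), segments=segs)


def rmsecv(
    model: PCRModel,
    X: np.ndarray,
    y: np.ndarray,
    K: int | None = None,
    seed: int = 0,
) -> float:
    """RMSE of the calibration model on the PCV pseudo-validation set.

    K defaults to leave-one-out for n <= 60 and to 10 segments above.
    The result is stored on the model (used later as RMSEP for
    prediction intervals).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K is None:
        K = n if n <= 60 else 10
    pv = pcv_set(X, y, model.a, K, seed)
    resid = pv.y - model.predict(pv.X_pv)
    value = float(np.sqrt(np.mean(resid**2)))
    model.rmsecv = value
    return value


def fit_with_outlier_removal(
    X: np.ndarray,
    y: np.ndarray,
    a: int = 2,
    K: int | None = None,
    gamma: float = 0.01,
    max_iter: int = 3,
    seed: int = 0,
) -> PCRModel:
    """Iterated fit: SIMCA-flag outliers, drop them, refit, repeat.

    Stops when no object is flagged or after ``max_iter`` rounds;
    aborts if more than 20% of the rows would be discarded.  Removed
    row indices (into the original X) are recorded on the model, and
    RMSECV is computed on the retained rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    keep = np.arange(n)
    removed: list[int] = []
    for _ in range(max_iter):
        simca = fit_simca(X[keep], a=a, alpha=gamma)
        flags = detect_outliers(simca, X[keep], gamma=gamma)
        if not flags.any():
            break
        removed.extend(keep[flags].tolist())
        if len(removed) > 0.2 * n:
            raise InsufficientDataError(
                f"outlier loop removed {len(removed)}/{n} rows (>20%); "
                "data look degenerate"
            )
        keep = keep[~flags]
    model = fit_pcr(X[keep], y[keep], a=a)
    model.removed = sorted(removed)
    rmsecv(model, X[keep], y[keep], K=K, seed=seed)
    return model


def predict_with_interval(
    model: PCRModel, X_new: np.ndarray
) -> tuple[np.ndarray, float]:
    """Point prediction plus a ±3·RMSEP interval half-width.

    RMSEP is taken to be the model's cross-validated error (RMSECV),
    the only validation error the workflow computes.
    """
    if model.rmsecv is None:
        raise ValueError("model has no RMSECV; run rmsecv() first")
    return model.predict(X_new), 3.0 * model.rmsecv
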