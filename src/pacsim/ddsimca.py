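"""Data-driven SIMCA: a PCA-based one-class classifier.

A target class is modelled by autoscaling the training matrix, fitting a
principal-component decomposition, and summarising each object by two
distances: the score distance h (leverage within the a-dimensional score
space) and the orthogonal distance v (squared residual norm outside it).
Scaled by their training means and method-of-moments degrees of freedom,
the total distance

    c = N_h * h / h0 + N_v * v / v0

is approximately chi-squared with N_h + N_v degrees of freedom, which
yields an acceptance region at significance ``alpha`` and an outlier
threshold corrected for multiple testing.  The same machinery doubles as
a group-similarity test: a second cohort is "similar" when its members
fall inside the first cohort's acceptance region at the expected rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats


class InsufficientDataError(ValueError):
    pass


def _moment_dof(values: np.ndarray) -> tuple[float, float]:
    """Scale factor and degrees of freedom via the method of moments.

    For x ~ (x0/N) * chi2(N): E x = x0 and Var x = 2 x0^2 / N, hence
    N = 2 mean^2 / var.  DoF are kept as positive reals (no rounding);
    they are floored at 1 to keep the chi-squared reference proper.
    """
    mean = float(np.mean(values))
    var = float(np.var(values, ddof=0))
    if var <= 0 or mean <= 0:
        return max(mean, np.finfo(float).tiny), 1.0
    dof = 2.0 * mean * mean / var
    return mean, max(dof, 1.0)


@dataclass
class SIMCAModel:
    """Fitted one-class model (training scaling, loadings and distance law)."""

    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # p x a
    eigenvalues: np.ndarray  # a
    h0: float
    n_h: float
    v0: float
    n_v: float
    alpha: float
    c_crit: float
    n_train: int
    score_only: bool = False  # exact low-rank data: ignore orthogonal part
    kept_columns: np.ndarray | None = None  # indices if constant columns dropped

    @property
    def a(self) -> int:
        return self.loadings.shape[1]

    @property
    def dof(self) -> float:
        return self.n_h + (0.0 if self.score_only else self.n_v)

    def distances(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Score, orthogonal and total distances of new objects."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.kept_columns is not None:
            X = X[:, self.kept_columns]
        Z = (X - self.mean) / self.sd
        T = Z @ self.loadings
        h = np.sum(T * T / self.eigenvalues, axis=1)
        E = Z - T @ self.loadings.T
        v = np.sum(E * E, axis=1)
        c = self.n_h * h / self.h0
        if not self.score_only:
            c = c + self.n_v * v / self.v0
        return h, v, c


@dataclass
class SimilarityResult:
    empirical: float
    theoretical: float
    distances: np.ndarray
    similar: bool
    c_crit: float


def _loo_distances(X: np.ndarray, a: int) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out score and orthogonal distances of the training rows.

    Each object is projected on a model fitted without it, which makes
    the distances behave like those of genuinely new objects.  With few
    objects and many variables the in-sample distances are optimistic
    (the residual space seen by training rows is rank-deficient), so the
    acceptance law would otherwise reject new same-population objects
    far above the nominal rate.
    """
    n, p = X.shape
    h = np.empty(n)
    v = np.empty(n)
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        Xi = X[idx]
        mean = Xi.mean(axis=0)
        sd = Xi.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (Xi - mean) / sd
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        P = Vt[:a].T
        eig = (s[:a] ** 2) / (n - 2)
        z = (X[i] - mean) / sd
        t = z @ P
        h[i] = float(np.sum(t * t / eig))
        r = z - t @ P.T
        v[i] = float(r @ r)
    return h, v


def fit_simca(
    X: np.ndarray,
    a: int = 2,
    alpha: float = 0.01,
    calibration: Literal["auto", "loo", "insample"] = "auto",
) -> SIMCAModel:
    """Fit a DD-SIMCA model to a training matrix.

    Parameters
    ----------
    X : (n, p) array
        Training objects of the target class.
    a : int
        Number of principal components; must satisfy 1 <= a < min(n-1, p).
    alpha : float
        Type-I error of the acceptance region (expected fraction of
        genuine class members rejected).
    calibration : {"auto", "loo", "insample"}
        Which training distances feed the moment estimation of the
        distance law.  "loo" uses leave-one-out distances, unbiased for
        new objects but O(n) SVDs; "insample" uses the plain training
        distances; "auto" (default) picks "loo" for n <= 200, where the
        in-sample optimism matters, and "insample" for larger samples
        where it vanishes.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if a < 1:
        raise ValueError("a must be >= 1")
    if n <= a + 1:
        raise InsufficientDataError(f"need n > a + 1, got n={n}, a={a}")

    sd_all = X.std(axis=0, ddof=1)
    kept = None
    if np.any(sd_all == 0):
        warnings.warn("dropping constant column(s) before autoscaling")
        kept = np.flatnonzero(sd_all > 0)
        X = X[:, kept]
        p = X.shape[1]
    if a >= min(n, p):
        raise InsufficientDataError(f"a={a} too large for {n}x{p} data")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mean) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:a].T
    eig = (s[:a] ** 2) / (n - 1)

    if calibration == "auto":
        calibration = "loo" if n <= 200 else "insample"
    if calibration == "loo":
        h, v = _loo_distances(X, a)
    else:
        T = Z @ loadings
        h = np.sum(T * T / eig, axis=1)
        E = Z - T @ loadings.T
        v = np.sum(E * E, axis=1)

    h0, n_h = _moment_dof(h)
    score_only = False
    if np.all(v < 1e-12 * p):
        warnings.warn(
            "zero orthogonal variance (exact low-rank data); "
            "accepting on score distance only"
        )
        score_only = True
        v0, n_v = 1.0, 1.0
    else:
        v0, n_v = _moment_dof(v)

    dof = n_h + (0.0 if score_only else n_v)
    c_crit = float(stats.chi2.ppf(1.0 - alpha, dof))
    return SIMCAModel(
        mean=mean,
        sd=sd,
        loadings=loadings,
        eigenvalues=eig,
        h0=h0,
        n_h=n_h,
        v0=v0,
        n_v=n_v,
        alpha=alpha,
        c_crit=c_crit,
        n_train=n,
        score_only=score_only,
        kept_columns=kept,
    )


def similarity_test(model: SIMCAModel, X_test: np.ndarray) -> SimilarityResult:
    """Test whether a second group belongs to the modelled class.

    Empirical power is the fraction of test objects inside the
    acceptance region.  Theoretical power is the model-based acceptance
    probability of the test group: its total distances are moment-fitted
    to a scaled chi-squared law and P(C <= c_crit) is evaluated under
    that law.  The similarity decision uses an exact binomial check that
    the rejection count is consistent with the nominal alpha.
    """
    X_test = np.asarray(X_test, dtype=float)
    if X_test.ndim == 1:
        X_test = X_test[None, :]
    m = X_test.shape[0]
    if m == 0:
        raise ValueError("empty test group")
    _, _, c = model.distances(X_test)
    accepted = c <= model.c_crit
    empirical = float(np.mean(accepted))

    c_mean = float(np.mean(c))
    c_var = float(np.var(c, ddof=0))
    if c_var <= 0 or c_mean <= 0:
        theoretical = 1.0 if c_mean <= model.c_crit else 0.0
    else:
        k = 2.0 * c_mean * c_mean / c_var
        scale = c_mean / k
        theoretical = float(stats.chi2.cdf(model.c_crit / scale, k))

    # similar unless the rejection count is binomially incompatible with alpha
    rejected = int(m - accepted.sum())
    p_value = float(stats.binom.sf(rejected - 1, m, model.alpha)) if rejected else 1.0
    similar = p_value >= model.alpha
    return SimilarityResult(empirical, theoretical, c, similar, model.c_crit)


def detect_outliers(
    model: SIMCAModel, X: np.ndarray, gamma: float = 0.01
) -> np.ndarray:
    """Flag outliers at outlier significance ``gamma``.

    The per-object level is corrected for multiplicity: object i is an
    outlier when its total distance exceeds the chi-squared quantile at
    (1 - gamma)^(1/n), so that a clean sample of size n triggers a false
    flag with probability about gamma overall.

    Outlier screening is an in-training-set operation, and a gross
    outlier distorts the very model it is judged by: it drags the
    leading loadings toward itself (hiding in the score space) and
    inflates the moment-estimated scale factors (stretching the
    acceptance region).  Both masking channels are removed by (i)
    computing each object's distances against a model refitted without
    it (leave-one-out) and (ii) judging it against a distance law
    moment-estimated from the remaining objects' distances.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[0]
    if n <= model.a + 2:
        _, _, c = model.distances(X)
        c_out = float(stats.chi2.ppf((1.0 - gamma) ** (1.0 / n), model.dof))
        return c > c_out
    Xk = X if model.kept_columns is None else X[:, model.kept_columns]
    h, v = _loo_distances(Xk, model.a)

    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        h0, n_h = _moment_dof(np.delete(h, i))
        c_i = n_h * h[i] / h0
        dof = n_h
        if not model.score_only:
            v0, n_v = _moment_dof(np.delete(v, i))
            c_i += n_v * v[i] / v0
            dof += n_v
        c_out = float(stats.chi2.ppf((1.0 - gamma) ** (1.0 / n), dof))
        flags[i] = c_i > c_out
    return flags
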