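"""Treatment-selection indicators and the gray-zone rule.

Equating the two arm-specific linear outcome models gives a decision
hyperplane: the full indicator is the coefficient-wise difference of the
LE and LPI models,

    Ind_Full(x) = A0 + Σ_i A_i x_i = ŷ_LE(x) − ŷ_LPI(x),

interpreted as the predicted mm Hg advantage in IOP reduction of lens
extraction over iridotomy for patient x.  Because 37 measurements are
impractical in routine care, a short indicator is distilled from the
full one by backward elimination over ordinary-least-squares
approximations: a variable is dropped only when removing it changes
neither the calibration RMSE nor the cross-validated RMSE significantly
(variance-ratio F test).  The published short form uses gender, IOP,
axial length and anterior chamber depth only.

Decisions: value > g favours LE, value < −g favours LPI, and |value| <= g
falls in a gray zone where neither method has a demonstrated advantage
(default half-width g = 1 mm Hg, the indicator's estimation accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pcr import PCRModel

#: published coefficients of the short indicator (B0, then slopes).
#: Gender is coded 0 = male / 1 = female here; the original coding is
#: not documented and cannot be verified from the publication.
PAPER_SHORT_COEFFICIENTS: dict[str, float] = {
    "intercept": 16.80,
    "gender": -0.28,
    "IOP": 0.24,
    "AL": -0.65,
    "ACD": -2.36,
}


@dataclass
class IndicatorModel:
    """Affine treatment-selection indicator (full or short variant)."""

    variant: Literal["full", "short"]
    intercept: float
    slopes: dict[str, float]
    gray_halfwidth: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.slopes)


@dataclass(frozen=True)
class Recommendation:
    """Indicator value (mm Hg LE-over-LPI advantage) and the decision."""

    value: float
    decision: Literal["LE", "LPI", "GRAY"]


def paper_short(gray_halfwidth: float = 1.0) -> IndicatorModel:
    """The packaged reference short indicator with published coefficients.

    Usable without refitting; indicators refit on synthetic cohorts are
    labelled as such in their provenance and will not match these
    numbers.
    """
    coeffs = dict(PAPER_SHORT_COEFFICIENTS)
    intercept = coeffs.pop("intercept")
    return IndicatorModel(
        variant="short",
        intercept=intercept,
        slopes=coeffs,
        gray_halfwidth=gray_halfwidth,
        provenance={"source": "published coefficients", "gender_coding": "0=male,1=female"},
    )


def derive_full_indicator(
    m_le: PCRModel, m_lpi: PCRModel, gray_halfwidth: float = 1.0
) -> IndicatorModel:
    """Subtract the LPI model from the LE model coefficient-wise."""
    names_le = m_le.feature_names
    names_lpi = m_lpi.feature_names
    if names_le is None or names_lpi is None or names_le != names_lpi:
        raise ValueError("models do not share a feature schema")
    slopes = {
        name: float(m_le.b[i] - m_lpi.b[i]) for i, name in enumerate(names_le)
    }
    return IndicatorModel(
        variant="full",
        intercept=float(m_le.b0 - m_lpi.b0),
        slopes=slopes,
        gray_halfwidth=gray_halfwidth,
        provenance={"source": "difference of fitted arm models"},
    )


def evaluate(ind: IndicatorModel, x: Mapping[str, float] | pd.DataFrame) -> np.ndarray | float:
    """Affine evaluation; raises KeyError naming any absent feature."""
    if isinstance(x, pd.DataFrame):
        missing = [f for f in ind.features if f not in x.columns]
        if missing:
            raise KeyError(f"missing feature(s) {missing}")
        value = np.full(len(x), ind.intercept, dtype=float)
        for name, slope in ind.slopes.items():
            value += slope * x[name].to_numpy(dtype=float)
        return value
    missing = [f for f in ind.features if f not in x]
    if missing:
        raise KeyError(f"missing feature(s) {missing}")
    return float(ind.intercept + sum(s * float(x[n]) for n, s in ind.slopes.items()))


def recommend(value: float, gray_halfwidth: float = 1.0) -> Recommendation:
    """Map an indicator value to LE / LPI / GRAY.

    The boundary |value| = g counts as gray: a method is recommended
    only when its predicted advantage exceeds the indicator's accuracy.
    """
    if gray_halfwidth < 0:
        raise ValueError("gray half-width must be >= 0")
    if value > gray_halfwidth:
        decision = "LE"
    elif value < -gray_halfwidth:
        decision = "LPI"
    else:
        decision = "GRAY"
    return Recommendation(float(value), decision)


# ---------------------------------------------------------------------------
# backward elimination of the full indicator
# ---------------------------------------------------------------------------


def _ols_errors(X: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Calibration RMSE, leave-one-out (PRESS) RMSE and coefficients
    for an OLS fit with intercept."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    # hat diagonal via the thin QR of the design
    Q, _ = np.linalg.qr(A)
    hat = np.sum(Q * Q, axis=1)
    loo = resid / np.clip(1.0 - hat, 1e-12, None)
    rmse_c = float(np.sqrt(np.mean(resid**2)))
    rmse_cv = float(np.sqrt(np.mean(loo**2)))
    return rmse_c, rmse_cv, coef


def backward_select(
    ind_values: np.ndarray,
    X: pd.DataFrame,
    p_level: float = 0.05,
    gray_halfwidth: float = 1.0,
    noise_scale: float = 0.0,
) -> IndicatorModel:
    """Reduce the full indicator to a short one by backward elimination.

    The full indicator's values are approximated by OLS on shrinking
    feature subsets.  At each step every remaining variable is
    tentatively removed and the change is judged by the variance-ratio
    statistic

        F = (RMSE_reduced² + s²) / (RMSE_full² + s²),   s = noise_scale,

    against the F distribution with (n − p_reduced, n − p_full) degrees
    of freedom, separately for the calibration RMSE and the
    leave-one-out RMSE, with the all-variable model as the fixed
    reference.  A variable is removable only when BOTH ratios are
    non-significant at ``p_level``; the one with the smallest
    calibration ratio goes first, and elimination stops when every
    remaining removal would significantly degrade either error.

    ``noise_scale`` is the standard error with which the target itself
    is known.  When the target carries its own noise (as in an ordinary
    regression problem) it can stay 0 and the statistic reduces to the
    plain squared RMSE ratio; when the target is an exactly affine
    function of the candidates (the full indicator evaluated on its own
    features, whose all-variable OLS is exact) the caller must supply
    the indicator's estimation error, so that "changed slightly" means
    "small relative to the accuracy of the indicator itself".
    """
    y = np.asarray(ind_values, dtype=float).ravel()
    n = len(y)
    current = list(X.columns)
    if n <= len(current) + 1:
        raise ValueError("need n > number of candidate features + 1")
    Xv = {c: X[c].to_numpy(dtype=float) for c in current}
    s2 = float(noise_scale) ** 2

    def errors(cols: Sequence[str]) -> tuple[float, float, np.ndarray]:
        M = (
            np.column_stack([Xv[c] for c in cols])
            if cols
            else np.empty((n, 0))
        )
        return _ols_errors(M, y)

    rmse_c0, rmse_cv0, _ = errors(current)
    p_full = len(current) + 1

    def ratio(reduced: float, full: float) -> float:
        denom = full * full + s2
        if denom <= 0:
            return 1.0 if reduced == 0 else np.inf
        return (reduced * reduced + s2) / denom

    while current:
        df_full = max(n - p_full, 1)
        df_red = n - len(current)  # reduced model has one parameter fewer
        f_crit = stats.f.ppf(1.0 - p_level, df_red, df_full)
        best: tuple[float, str] | None = None
        for name in current:
            cols = [c for c in current if c != name]
            r_c, r_cv, _ = errors(cols)
            F_c = ratio(r_c, rmse_c0)
            F_cv = ratio(r_cv, rmse_cv0)
            if F_c < f_crit and F_cv < f_crit:
                if best is None or F_c < best[0]:
                    best = (F_c, name)
        if best is None:
            break
        current.remove(best[1])

    if not current:
        warnings.warn("elimination removed every feature; intercept-only indicator")
    r_c, r_cv, coef = errors(current)
    slopes = {name: float(coef[i + 1]) for i, name in enumerate(current)}
    return IndicatorModel(
        variant="short",
        intercept=float(coef[0]),
        slopes=slopes,
        gray_halfwidth=gray_halfwidth,
        provenance={
            "source": "backward elimination of the full indicator",
            "replacement_rms": r_c,
            "replacement_rms_cv": r_cv,
            "n": n,
        },
    )
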