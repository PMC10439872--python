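"""PCR fitting, Procrustes cross-validation and prediction intervals."""

import numpy as np
import pytest

from pacsim import simulate_outcomes
from pacsim.ddsimca import InsufficientDataError
from pacsim.pcr import (
    fit_pcr,
    fit_with_outlier_removal,
    pcv_set,
    predict_with_interval,
    rmsecv,
)


def _toy_linear(n=12, p=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.uniform(-2, 2, size=p)
    y = 1.5 + X @ beta + noise * rng.standard_normal(n)
    return X, y


def test_single_predictor_exact_fit():
    x = np.arange(1.0, 9.0)[:, None]
    model = fit_pcr(x, 2.0 * x.ravel(), a=1)
    assert model.rmsec == pytest.approx(0.0, abs=1e-10)
    assert model.b[0] == pytest.approx(2.0, abs=1e-10)


def test_full_rank_pcr_equals_ordinary_least_squares():
    """With a = rank(X), PCR predictions match the normal equations."""
    X, y = _toy_linear(noise=0.3)
    model = fit_pcr(X, y, a=5)
    A = np.column_stack([np.ones(len(X)), X])
    beta_ols = np.linalg.solve(A.T @ A, A.T @ y)
    np.testing.assert_allclose(model.predict(X), A @ beta_ols, rtol=1e-8)


def test_latent_and_raw_unit_paths_agree(treated_le):
    treated, _ = treated_le
    model = fit_pcr(treated.X, treated.delta_iop.to_numpy(), a=2)
    np.testing.assert_allclose(
        model.predict(treated.X), model.predict_latent(treated.X), rtol=1e-8
    )


def test_rmsec_nonincreasing_in_component_count():
    X, y = _toy_linear(n=25, p=6, seed=3, noise=0.5)
    errors = [fit_pcr(X, y, a=a).rmsec for a in range(1, 7)]
    assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errors, errors[1:]))


def test_predictions_invariant_under_column_rescaling():
    X, y = _toy_linear(n=30, p=4, seed=4, noise=0.2)
    model = fit_pcr(X, y, a=2)
    X2 = X.copy()
    X2[:, 2] = X2[:, 2] * 250.0 - 7.0
    model2 = fit_pcr(X2, y, a=2)
    np.testing.assert_allclose(model.predict(X), model2.predict(X2), rtol=1e-8)


def test_error_conditions():
    X, y = _toy_linear(n=6, p=5, seed=5)
    with pytest.raises(InsufficientDataError):
        fit_pcr(X, y, a=6)
    with pytest.raises(InsufficientDataError):
        fit_pcr(X[:2], y[:2], a=2)
    with pytest.raises(InsufficientDataError):
        pcv_set(X, y, a=2, K=5)  # n < 2K and K != n


def test_pcv_exact_on_noise_free_low_rank_data():
    """Rank-a predictors with an exactly linear response: the pseudo-
    validation set reproduces the calibration predictions perfectly."""
    rng = np.random.default_rng(6)
    T = rng.standard_normal((40, 2))
    P = rng.standard_normal((6, 2))
    X = T @ P.T
    y = 3.0 + T @ np.array([1.0, -2.0])
    model = fit_pcr(X, y, a=2)
    err = rmsecv(model, X, y, K=8, seed=0)
    assert err < 1e-6


def test_pcv_matches_classical_cross_validation():
    """RMSECV from the pseudo-validation set tracks explicit K-fold CV."""
    rng = np.random.default_rng(7)
    G = rng.standard_normal((10, 10))
    X = rng.standard_normal((60, 10)) @ G
    beta = rng.uniform(-1, 1, 10)
    y = X @ beta + 0.5 * rng.standard_normal(60)

    model = fit_pcr(X, y, a=2)
    pcv_err = rmsecv(model, X, y, K=10, seed=1)

    # independent oracle: explicit 10-fold cross-validation
    folds = np.array_split(np.random.default_rng(1).permutation(60), 10)
    sq = []
    for fold in folds:
        train = np.setdiff1d(np.arange(60), fold)
        local = fit_pcr(X[train], y[train], a=2)
        sq.extend((y[fold] - local.predict(X[fold])) ** 2)
    kfold_err = float(np.sqrt(np.mean(sq)))
    assert abs(pcv_err - kfold_err) / kfold_err < 0.15


def test_pcv_deterministic_given_seed():
    X, y = _toy_linear(n=30, p=6, seed=8, noise=0.4)
    a = pcv_set(X, y, a=2, K=5, seed=3)
    b = pcv_set(X, y, a=2, K=5, seed=3)
    np.testing.assert_array_equal(a.X_pv, b.X_pv)


def test_outlier_loop_noop_on_clean_data(treated_le):
    treated, _ = treated_le
    X, y = treated.X, treated.delta_iop.to_numpy()
    plain = fit_pcr(X, y, a=2)
    looped = fit_with_outlier_removal(X, y, a=2, gamma=0.001)
    if not looped.removed:  # clean draw: identical fit
        np.testing.assert_allclose(looped.b, plain.b, rtol=1e-10)
        assert looped.rmsec == pytest.approx(plain.rmsec)


def test_outlier_loop_removes_planted_gross_outlier(treated_le):
    treated, _ = treated_le
    X = treated.X.copy()
    y = treated.delta_iop.to_numpy().copy()
    X[5] = X[5] + 10.0 * X.std(axis=0)
    y[5] += 25.0
    cleaned = fit_with_outlier_removal(X, y, a=2, gamma=0.01)
    assert 5 in cleaned.removed
    kept = fit_pcr(X, y, a=2)
    assert cleaned.rmsec < kept.rmsec
    # idempotence: re-running on the retained rows removes nothing
    keep = np.setdiff1d(np.arange(len(y)), cleaned.removed)
    again = fit_with_outlier_removal(X[keep], y[keep], a=2, gamma=0.01)
    assert again.removed == []


def test_interval_requires_validation_error(treated_le):
    treated, _ = treated_le
    model = fit_pcr(treated.X, treated.delta_iop.to_numpy(), a=2)
    with pytest.raises(ValueError, match="RMSECV"):
        predict_with_interval(model, treated.X)
    err = rmsecv(model, treated.X, treated.delta_iop.to_numpy())
    _, half = predict_with_interval(model, treated.X)
    assert half == pytest.approx(3.0 * err)


def test_intervals_cover_true_expected_effect(gen_config, treated_le):
    """±3·RMSEP intervals cover the generator's true expected ΔIOP for
    at least 99% of 1000 new patients."""
    from pacsim import generate_cohort

    treated, _ = treated_le
    model = fit_pcr(treated.X, treated.delta_iop.to_numpy(), a=2)
    rmsecv(model, treated.X, treated.delta_iop.to_numpy())
    fresh = generate_cohort(gen_config, 1000, seed=77)
    _, truth = simulate_outcomes(fresh, gen_config, "LE", seed=78)
    pred, half = predict_with_interval(model, fresh.X)
    coverage = np.mean(np.abs(pred - truth.mu_le) <= half)
    assert coverage >= 0.99
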