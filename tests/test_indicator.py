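"""Decision indicators: derivation, selection, evaluation, gray zone."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacsim import (
    default_config,
    fit_pcr,
    generate_cohort,
    simulate_outcomes,
)
from pacsim.indicator import (
    backward_select,
    derive_full_indicator,
    evaluate,
    paper_short,
    recommend,
)
from pacsim.pcr import PCRModel


def _manual_model(b0, slopes, names):
    """Raw-coefficient PCR shell for hand-built examples."""
    p = len(names)
    return PCRModel(
        x_mean=np.zeros(p),
        x_sd=np.ones(p),
        y_mean=b0,
        loadings=np.eye(p),
        latent_weights=np.asarray(slopes, dtype=float),
        b0=b0,
        b=np.asarray(slopes, dtype=float),
        a=p,
        rmsec=0.0,
        n_used=10,
        feature_names=list(names),
    )


def test_published_short_indicator_worked_examples():
    ind = paper_short()
    zeros = {"gender": 0.0, "IOP": 0.0, "AL": 0.0, "ACD": 0.0}
    assert evaluate(ind, zeros) == pytest.approx(16.80)
    typical = {"gender": 0.0, "IOP": 25.5, "AL": 23.5, "ACD": 2.33}
    assert evaluate(ind, typical) == pytest.approx(2.15, abs=0.005)


def test_full_indicator_is_coefficient_subtraction():
    m_le = _manual_model(1.0, [2.0, 0.0], ["x1", "x2"])
    m_lpi = _manual_model(0.5, [0.0, 1.0], ["x1", "x2"])
    full = derive_full_indicator(m_le, m_lpi)
    assert full.intercept == pytest.approx(0.5)
    assert full.slopes["x1"] == pytest.approx(2.0)
    assert full.slopes["x2"] == pytest.approx(-1.0)


def test_identical_models_give_gray_everywhere():
    m = _manual_model(2.0, [1.0, -1.0], ["x1", "x2"])
    full = derive_full_indicator(m, m)
    assert all(v == 0.0 for v in full.slopes.values()) and full.intercept == 0.0
    for x1 in (-3.0, 0.0, 11.0):
        value = evaluate(full, {"x1": x1, "x2": 2 * x1})
        assert recommend(value, 1.0).decision == "GRAY"


def test_schema_mismatch_rejected():
    m1 = _manual_model(0.0, [1.0], ["x1"])
    m2 = _manual_model(0.0, [1.0], ["other"])
    with pytest.raises(ValueError, match="schema"):
        derive_full_indicator(m1, m2)


def test_full_indicator_equals_prediction_difference(treated_le, treated_lpi):
    """evaluate(full, x) = prediction_LE(x) − prediction_LPI(x) exactly."""
    (le, _), (lpi, _) = treated_le, treated_lpi
    names = le.schema.names
    m_le = fit_pcr(le.X, le.delta_iop.to_numpy(), a=2)
    m_le.feature_names = names
    m_lpi = fit_pcr(lpi.X, lpi.delta_iop.to_numpy(), a=2)
    m_lpi.feature_names = names
    full = derive_full_indicator(m_le, m_lpi)
    pooled = pd.concat([le.features, lpi.features], ignore_index=True)
    values = evaluate(full, pooled)
    expected = m_le.predict(pooled.to_numpy()) - m_lpi.predict(pooled.to_numpy())
    np.testing.assert_allclose(values, expected, rtol=1e-8)

    # antisymmetry: swapping the arms negates the indicator and the decision
    swapped = derive_full_indicator(m_lpi, m_le)
    np.testing.assert_allclose(evaluate(swapped, pooled), -values, rtol=1e-8)
    flips = {"LE": "LPI", "LPI": "LE", "GRAY": "GRAY"}
    for v in values[:10]:
        assert recommend(-v).decision == flips[recommend(v).decision]


def test_noiseless_exact_fit_recovers_generator_truth():
    """Full-rank models on noise-free outcomes reproduce the generator's
    true per-patient indicator."""
    base = default_config()
    responses = {
        arm: dataclasses.replace(rs, sigma=1e-9)
        for arm, rs in base.responses.items()
    }
    cfg = dataclasses.replace(base, responses=responses)
    cohort = generate_cohort(cfg, 60, seed=21)
    names = cohort.schema.names
    models = {}
    for arm in ("LE", "LPI"):
        treated, _ = simulate_outcomes(cohort, cfg, arm, seed=22)
        models[arm] = fit_pcr(treated.X, treated.delta_iop.to_numpy(), a=37)
        models[arm].feature_names = names
    full = derive_full_indicator(models["LE"], models["LPI"])
    _, truth = simulate_outcomes(cohort, cfg, "alternate", seed=23)
    np.testing.assert_allclose(
        evaluate(full, cohort.features), truth.indicator, atol=1e-6
    )


def test_backward_selection_recovers_true_support():
    """Ten candidates, four informative: elimination keeps the true four."""
    rng = np.random.default_rng(30)
    n = 200
    X = pd.DataFrame(
        rng.standard_normal((n, 10)), columns=[f"v{i}" for i in range(10)]
    )
    truth = ["v1", "v3", "v6", "v8"]
    y = 2.0 + sum(
        c * X[name].to_numpy() for c, name in zip([3.0, -2.0, 1.5, 2.5], truth)
    )
    y = y + 0.2 * rng.standard_normal(n)
    short = backward_select(y, X, p_level=0.05)
    assert set(truth) <= set(short.features)
    assert short.provenance["replacement_rms"] < 0.5


def test_single_informative_candidate_is_retained():
    rng = np.random.default_rng(31)
    X = pd.DataFrame({"only": rng.standard_normal(100)})
    y = 5.0 * X["only"].to_numpy() + 0.1 * rng.standard_normal(100)
    short = backward_select(y, X)
    assert short.features == ["only"]


def test_uninformative_target_collapses_to_intercept():
    rng = np.random.default_rng(32)
    X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
    y = np.zeros(80)
    with pytest.warns(UserWarning, match="intercept-only"):
        short = backward_select(y, X, noise_scale=1.0)
    assert short.features == []


def test_missing_feature_named_in_error():
    ind = paper_short()
    with pytest.raises(KeyError, match="ACD"):
        evaluate(ind, {"gender": 0.0, "IOP": 25.0, "AL": 23.0})


def test_gray_zone_examples_from_study():
    assert recommend(3.0, 1.0).decision == "LE"
    assert recommend(-3.0, 1.0).decision == "LPI"
    assert recommend(0.5, 1.0).decision == "GRAY"


@settings(derandomize=True, max_examples=200)
@given(
    value=st.floats(-20, 20, allow_nan=False),
    g=st.floats(0, 5, allow_nan=False),
)
def test_recommendation_partition_and_boundary(value, g):
    rec = recommend(value, g)
    if value > g:
        assert rec.decision == "LE"
    elif value < -g:
        assert rec.decision == "LPI"
    else:
        assert rec.decision == "GRAY"
    assert rec.value == value
    # the gray half-width influences the decision, never the value
    assert recommend(value, 2 * g + 1).value == rec.value
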