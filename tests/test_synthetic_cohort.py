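"""Generator marginals, determinism, latent response surfaces and truth."""

import dataclasses

import numpy as np
import pytest

from pacsim import (
    default_config,
    fit_simca,
    generate_cohort,
    similarity_test,
    simulate_outcomes,
)
from pacsim.synthetic_cohort import ResponseSurface


def test_default_config_carries_published_baselines(gen_config):
    assert gen_config.mean("IOP") == 25.5
    assert gen_config.sd("IOP") == 2.3
    assert gen_config.mean("ACD") == 2.33
    assert gen_config.mean("LV") == 0.866
    assert gen_config.mean("AOD500_90") == 0.061
    assert gen_config.mean("TISA500_90") == 0.024


def test_correlation_matrix_is_psd_with_unit_diagonal(gen_config):
    C = gen_config.correlation
    np.testing.assert_allclose(C, C.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
    assert np.linalg.eigvalsh(C).min() >= -1e-10


def test_empty_and_deterministic_generation(gen_config):
    assert generate_cohort(gen_config, 0, seed=1).n == 0
    a = generate_cohort(gen_config, 50, seed=5)
    b = generate_cohort(gen_config, 50, seed=5)
    assert a.data.equals(b.data)
    c = generate_cohort(gen_config, 50, seed=6)
    assert not a.data.equals(c.data)


def test_samples_respect_plausible_ranges(gen_config):
    cohort = generate_cohort(gen_config, 2000, seed=3)
    for spec in gen_config.schema:
        col = cohort.data[spec.name]
        assert col.between(spec.lo, spec.hi).all(), spec.name
        if spec.levels is not None:
            assert col.isin(spec.levels).all(), spec.name


def test_moment_recovery_at_monte_carlo_tolerance(gen_config):
    """Sample means track configured marginals at the 4*SE level (n=3000)."""
    cohort = generate_cohort(gen_config, 3000, seed=1)
    for name in ("IOP", "ACD", "AL", "LV", "age"):
        mean, sd = gen_config.marginals[name]
        tol = 4.0 * sd / np.sqrt(3000)
        assert abs(cohort.data[name].mean() - mean) < tol, name
        assert abs(cohort.data[name].std() - sd) < 5.0 * sd / np.sqrt(3000), name


def test_constant_surface_gives_constant_outcome(gen_config):
    cfg = dataclasses.replace(
        gen_config,
        responses={
            "LE": ResponseSurface(5.0, {}, 1e-12),
            "LPI": ResponseSurface(2.0, {}, 1e-12),
        },
    )
    cohort = generate_cohort(cfg, 10, seed=2)
    treated, truth = simulate_outcomes(cohort, cfg, "LE", seed=3)
    np.testing.assert_allclose(treated.delta_iop, 5.0, atol=1e-9)
    np.testing.assert_allclose(truth.indicator, 3.0, atol=1e-12)


def test_treatment_effect_means_match_study(gen_config):
    cohort = generate_cohort(gen_config, 3000, seed=1)
    le, _ = simulate_outcomes(cohort, gen_config, "LE", seed=2)
    lpi, _ = simulate_outcomes(cohort, gen_config, "LPI", seed=3)
    assert abs(le.delta_iop.mean() - 7.33) < 0.2
    assert abs(lpi.delta_iop.mean() - 4.87) < 0.15
    # dispersion close to the published SDs
    assert abs(le.delta_iop.std() - 3.40) < 0.25
    assert abs(lpi.delta_iop.std() - 2.42) < 0.2


def test_truth_indicator_is_exact_surface_difference(gen_config):
    cohort = generate_cohort(gen_config, 40, seed=9)
    _, truth = simulate_outcomes(cohort, gen_config, "alternate", seed=10)
    le, lpi = gen_config.responses["LE"], gen_config.responses["LPI"]
    manual = (le.intercept - lpi.intercept) * np.ones(cohort.n)
    for name in set(le.slopes) | set(lpi.slopes):
        x = cohort.data[name].to_numpy(dtype=float)
        manual += (le.slopes.get(name, 0.0) - lpi.slopes.get(name, 0.0)) * x
    np.testing.assert_allclose(truth.indicator, manual, rtol=0, atol=1e-10)


def test_unknown_arm_assignment_rejected(gen_config, baseline_cohort):
    with pytest.raises(ValueError, match="arm"):
        simulate_outcomes(baseline_cohort, gen_config, "PI", seed=1)


def test_same_population_arms_are_similar(gen_config):
    """Two n=30 draws from one config pass the one-class similarity check."""
    powers = []
    for seed in range(20):
        a = generate_cohort(gen_config, 30, seed=3000 + seed)
        b = generate_cohort(gen_config, 30, seed=6000 + seed)
        model = fit_simca(a.X, a=2, alpha=0.01)
        powers.append(similarity_test(model, b.X).empirical)
    assert np.median(powers) >= 0.95
    # full acceptance in the majority of runs, as in the original study
    assert np.mean(np.asarray(powers) == 1.0) > 0.5
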