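"""Gillespie direct-method sampling, hitting estimates, Chernoff bounds."""

import math

import numpy as np
import pytest

from fspswitch import (
    Region,
    birth_death_fixture,
    chernoff_epsilon,
    estimate_hitting_probability,
    pure_death_fixture,
    sample_return_times,
    ssa_run,
    two_state_fixture,
)


def test_pure_death_run_has_exactly_n_events():
    fx = pure_death_fixture(mu=1.0)
    tr = ssa_run(fx.network, (5,), 1e6, seed=1)
    assert tr.n_events == 5
    assert tr.states[-1, 0] == 0
    assert np.all(np.diff(tr.times) > 0)


def test_absorbing_origin_yields_constant_trajectory():
    fx = pure_death_fixture(mu=1.0)
    tr = ssa_run(fx.network, (0,), 100.0, seed=2)
    assert tr.n_events == 0
    np.testing.assert_array_equal(tr.states, [[0]])


def test_identical_seed_reproduces_trajectory():
    fx = birth_death_fixture(5.0, 1.0)
    a = ssa_run(fx.network, (2,), 50.0, seed=11)
    b = ssa_run(fx.network, (2,), 50.0, seed=11)
    np.testing.assert_array_equal(a.times, b.times)
    np.testing.assert_array_equal(a.states, b.states)
    c = ssa_run(fx.network, (2,), 50.0, seed=12)
    assert not np.array_equal(a.times, c.times)


def test_every_event_matches_a_fireable_reaction(scaled_entry):
    """Consecutive states differ by exactly one stoichiometry vector whose
    propensity was positive at the pre-state."""
    from fspswitch import propensities

    net = scaled_entry["net"]
    stoichs = net.stoichiometry_matrix
    tr = ssa_run(net, scaled_entry["x0"], 3600.0, seed=9)
    assert tr.n_events > 10
    for i in range(tr.n_events):
        step = tr.states[i + 1] - tr.states[i]
        matches = np.nonzero((stoichs == step).all(axis=1))[0]
        assert len(matches) >= 1
        w = propensities(net, tr.states[i])
        assert any(w[j] > 0 for j in matches)


def test_immigration_death_time_average_near_stationary_mean():
    fx = birth_death_fixture(5.0, 1.0)
    T, n = 400.0, 10
    means = [ssa_run(fx.network, (5,), T, 300 + i).time_average(T) for i in range(n)]
    se = np.std(means, ddof=1) / math.sqrt(n)
    assert abs(np.mean(means) - fx.known["stationary_mean"]) < 3 * se


def test_chernoff_half_width_formula_and_scaling():
    assert chernoff_epsilon(10_000, 0.05) == pytest.approx(
        math.sqrt(math.log(40.0) / 20_000.0), rel=1e-12)
    assert chernoff_epsilon(10_000, 0.05) == pytest.approx(0.01358, abs=2e-5)
    # quadrupling the sample halves the half-width
    assert chernoff_epsilon(40_000, 0.05) == pytest.approx(
        chernoff_epsilon(10_000, 0.05) / 2.0, rel=1e-12)
    for bad in (0.0, 1.0, 2.0, -0.5):
        with pytest.raises(ValueError):
            chernoff_epsilon(100, bad)
    with pytest.raises(ValueError):
        chernoff_epsilon(0, 0.05)


def test_hitting_estimate_trivial_regions():
    fx = birth_death_fixture(5.0, 1.0)
    contains_start = Region.rectangle([(0, None)], name="everything")
    est = estimate_hitting_probability(fx.network, (2,), contains_start,
                                       1.0, n_runs=20, seed=0)
    assert est.p_hat == 1.0
    dead = pure_death_fixture(mu=1.0)
    unreachable = Region.rectangle([(10, None)], name="K >= 10")
    est2 = estimate_hitting_probability(dead.network, (3,), unreachable,
                                        100.0, n_runs=20, seed=0)
    assert est2.p_hat == 0.0


def test_two_state_hitting_estimate_within_chernoff_band():
    fx = two_state_fixture(k=1.0)
    T = math.log(2.0)
    est = estimate_hitting_probability(fx.network, (0,), fx.regions["hit"],
                                       T, n_runs=10_000, delta=0.01, seed=21)
    assert est.epsilon == pytest.approx(0.01628, abs=2e-5)
    assert abs(est.p_hat - 0.5) < est.epsilon


def test_return_time_sampling_matches_harmonic_mean():
    fx = pure_death_fixture(mu=1.0)
    start = Region.rectangle([(3, 3)], name="K = 3")
    target = Region.rectangle([(None, 0)], name="K = 0")
    samples = sample_return_times(fx.network, start, target, t_max=200.0,
                                  n_runs=5_000, seed=4)
    assert samples.censored_fraction == 0.0
    exact = fx.known["mfpt_to_zero"](3)  # 1 + 1/2 + 1/3
    assert abs(samples.mean - exact) < 3 * samples.standard_error


def test_return_sampling_rejects_overlapping_regions():
    fx = pure_death_fixture(mu=1.0)
    start = Region.rectangle([(0, 3)], name="K <= 3")
    target = Region.rectangle([(None, 0)], name="K = 0")
    with pytest.raises(ValueError, match="disjoint"):
        sample_return_times(fx.network, start, target, 10.0, 10, seed=0)


def test_fully_censored_sampling_is_flagged():
    fx = pure_death_fixture(mu=1e-6)  # returns take ~1e6 s
    start = Region.rectangle([(3, 3)])
    target = Region.rectangle([(None, 0)])
    samples = sample_return_times(fx.network, start, target, t_max=1.0,
                                  n_runs=25, seed=6)
    assert samples.censored_fraction == 1.0
    assert math.isnan(samples.mean)
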