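"""Projected generators and the uniformized transient solver."""

import math

import numpy as np
import pytest

from fspswitch import (
    Region,
    birth_death_fixture,
    build_generator,
    dense_expm_reference,
    enumerate_states,
    expand_until_certified,
    fsp_error_bound,
    hitting_probability,
    pure_death_fixture,
    random_generator,
    solve_transient,
    two_state_fixture,
)
from conftest import point_mass


def test_single_state_toy_generator_structure(toy_exponential):
    # one transient state, rate k into the sink, silent overflow column
    k = toy_exponential["k"]
    expected = np.array([[-k, 0, 0], [k, 0, 0], [0, 0, 0]])
    np.testing.assert_allclose(toy_exponential["gen"].matrix.toarray(), expected)


def test_generator_columns_sum_to_zero_and_sign_structure(scaled_entry):
    gen = scaled_entry["gen"]
    gen.validate(tol=1e-12)
    assert np.abs(gen.column_sums()).max() < 1e-12


def test_state_outflow_equals_total_propensity(scaled_entry):
    """Diagonal magnitude equals the summed propensity of the reactions
    that can actually fire (boundary-blocked channels contribute zero)."""
    from fspswitch import propensities

    gen, space, net = scaled_entry["gen"], scaled_entry["space"], scaled_entry["net"]
    diag = gen.matrix.diagonal()
    for idx in [0, 17, space.n_states // 2, space.n_states - 1]:
        w = propensities(net, space.states[idx])
        assert -diag[idx] == pytest.approx(w.sum(), rel=1e-12)


def test_exponential_toy_closed_form(toy_exponential):
    gen, p0 = toy_exponential["gen"], toy_exponential["p0"]
    fx = two_state_fixture(k=1.0)
    space1 = enumerate_states((0,), [fx.regions["hit"]])
    gen1 = build_generator(fx.network, space1, {"hit": fx.regions["hit"]})
    sol = solve_transient(gen1, p0, [math.log(2.0)], tol=1e-12)
    assert hitting_probability(sol, "hit")[-1] == pytest.approx(0.5, abs=1e-12)
    np.testing.assert_allclose(sol.final_prob, [0.5, 0.5, 0.0], atol=1e-12)


def test_time_zero_returns_initial_vector(toy_exponential):
    sol = solve_transient(toy_exponential["gen"], toy_exponential["p0"],
                          [0.0, 1.0], tol=1e-12)
    np.testing.assert_array_equal(sol.prob[0], toy_exponential["p0"])


def test_solver_matches_dense_exponential_birth_death():
    fx = birth_death_fixture(5.0, 1.0)
    space = enumerate_states((199,))
    gen = build_generator(fx.network, space, {})
    p0 = point_mass(space, (0,), gen.n_sinks)
    sol = solve_transient(gen, p0, [0.7, 3.0], tol=1e-12)
    for i, t in enumerate([0.7, 3.0]):
        ref = dense_expm_reference(gen, p0, t)
        assert np.abs(sol.prob[i] - ref).max() <= 1e-8


def test_solver_matches_dense_exponential_random_generator():
    gen = random_generator(150, seed=123, density=0.04)
    p0 = np.zeros(gen.size)
    p0[7] = 1.0
    sol = solve_transient(gen, p0, [0.9], tol=1e-12)
    ref = dense_expm_reference(gen, p0, 0.9)
    assert np.abs(sol.prob[-1] - ref).max() <= 1e-8
    assert abs(sol.totals[-1] - 1.0) <= 1e-9


def test_hitting_probability_complement_identity(scaled_entry):
    sol = scaled_entry["sol"]
    total = sol.transient_mass.copy()
    for name in sol.gen.sink_names:
        total = total + sol.sink_mass(name)
    np.testing.assert_allclose(total, 1.0, atol=1e-9)
    p_hit = hitting_probability(sol, "competence")
    assert np.all(np.diff(p_hit) >= -1e-12)
    assert np.all((p_hit >= 0) & (p_hit <= 1))


def test_unknown_sink_label_raises(scaled_entry):
    with pytest.raises(ValueError, match="unknown sink"):
        hitting_probability(scaled_entry["sol"], "sporulation")


def test_error_bound_zero_without_overflow_flows(toy_exponential):
    sol = solve_transient(toy_exponential["gen"], toy_exponential["p0"],
                          [1.0, 5.0], tol=1e-12)
    np.testing.assert_array_equal(fsp_error_bound(sol), 0.0)


def test_error_bound_nondecreasing_and_box_monotone():
    """FSP guarantees: overflow mass grows in time and shrinks (weakly) as
    the truncation box grows."""
    fx = birth_death_fixture(8.0, 1.0)
    eps_at_T = []
    for bound in (10, 14, 20):
        space = enumerate_states((bound,))
        gen = build_generator(fx.network, space, {})
        p0 = point_mass(space, (0,), gen.n_sinks)
        sol = solve_transient(gen, p0, np.linspace(0.5, 4.0, 8), tol=1e-12)
        eps = fsp_error_bound(sol)
        assert np.all(np.diff(eps) >= -1e-12)
        eps_at_T.append(eps[-1])
    assert eps_at_T[0] > eps_at_T[1] > eps_at_T[2]


def test_certification_immediate_for_contained_toy(toy_exponential):
    fx = toy_exponential["fixture"]
    space, sol = expand_until_certified(
        fx.network, (0,), {"hit": fx.regions["hit"]}, np.array([0]),
        T=2.0, target_eps=1e-6)
    assert space.bounds == (0,)
    assert sol.error_bound[-1] == 0.0


def test_certification_expands_undersized_birth_death_box():
    """A box below the stationary mean + 3 sd must expand at least once and
    end with a certificate below target."""
    fx = birth_death_fixture(30.0, 1.0)
    small = int(30 - 2 * math.sqrt(30.0))
    space, sol = expand_until_certified(
        fx.network, (small,), {}, np.array([0]), T=6.0, target_eps=1e-3)
    assert space.bounds[0] > small
    assert sol.error_bound[-1] <= 1e-3


def test_certification_cap_reports_best_certificate():
    fx = birth_death_fixture(30.0, 1.0)
    with pytest.raises(RuntimeError, match="best certificate"):
        expand_until_certified(fx.network, (3,), {}, np.array([0]),
                               T=6.0, target_eps=1e-12, max_expansions=1)


def test_initial_vector_validation(toy_exponential):
    gen = toy_exponential["gen"]
    with pytest.raises(ValueError, match="sum to 1"):
        solve_transient(gen, [0.5, 0.0, 0.0], [1.0])
    with pytest.raises(ValueError, match="nonnegative"):
        solve_transient(gen, [1.5, -0.5, 0.0], [1.0])
    with pytest.raises(ValueError, match="increasing"):
        solve_transient(gen, [1.0, 0.0, 0.0], [2.0, 1.0])
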