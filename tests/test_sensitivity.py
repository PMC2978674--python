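"""Augmented-system and finite-difference sensitivities."""

import math

import numpy as np
import pytest

from fspswitch import (
    ParameterSet,
    Region,
    build_generator,
    enumerate_states,
    finite_difference_sensitivity,
    generator_derivative,
    sensitivity_table,
    solve_augmented,
    solve_transient,
)
from fspswitch.fixtures import birth_death_fixture, two_state_fixture
from fspswitch.network import MassAction, Reaction, ReactionNetwork, SaturableDegradation


def test_linear_parameter_derivative_is_channel_incidence(scaled):
    """dA/d(ak) is omega times the incidence structure of the ComK
    production channel: production edges carry omega, its diagonal -omega."""
    net, comp = scaled.network, scaled.regions["competence"]
    space = enumerate_states((8, 5), absorbed_regions=[comp])
    dg = generator_derivative(net, space, {"competence": comp}, "ak")
    om = net.params.omega
    d = dg.matrix.toarray()
    nt = space.n_states
    np.testing.assert_allclose(np.diag(d)[:nt], -om)
    np.testing.assert_allclose(np.diag(d)[nt:], 0.0)
    off = d - np.diag(np.diag(d))
    # each column sends exactly omega to the K+1 neighbour (or a sink)
    np.testing.assert_allclose(off.sum(axis=0)[:nt], om)
    np.testing.assert_allclose(off[off != 0], om)


def test_saturable_degradation_derivative_matches_central_difference():
    pr = ParameterSet()
    prop = SaturableDegradation(pr, target=0, rate_name="delta_k")
    states = np.array([[500, 50], [10, 300], [0, 7]])
    for name in ("delta_k", "Gamma_k", "Gamma_s"):
        h = getattr(pr, name) * 1e-6
        hi = SaturableDegradation(pr.replace(**{name: getattr(pr, name) + h}), 0, "delta_k")
        lo = SaturableDegradation(pr.replace(**{name: getattr(pr, name) - h}), 0, "delta_k")
        num = (hi(states) - lo(states)) / (2 * h)
        ana = prop.d_param(states, name)
        np.testing.assert_allclose(ana, num, rtol=1e-6, atol=1e-15)


def test_generator_derivative_rejects_unknown_parameter(toy_exponential):
    fx = toy_exponential["fixture"]
    with pytest.raises(ValueError, match="unknown parameter"):
        generator_derivative(fx.network, toy_exponential["space"],
                             {"hit": fx.regions["hit"]}, "zeta")


def test_augmented_system_closed_form_on_exponential_toy(toy_exponential):
    """Single state -> sink at rate theta: P(T) = 1 - e^{-theta T}, so the
    sensitivity is T e^{-theta T}; checked at theta = 0.1, T = 10."""
    gen, p0 = toy_exponential["gen"], toy_exponential["p0"]
    fx = toy_exponential["fixture"]
    dg = generator_derivative(fx.network, toy_exponential["space"],
                              {"hit": fx.regions["hit"]}, "k")
    sol, s = solve_augmented(gen, dg, p0, 10.0, tol=1e-12)
    raw = float(s[-1, gen.sink_index("hit")])
    assert raw == pytest.approx(10.0 * math.exp(-1.0), abs=1e-10)
    # all three normalizations, from the closed forms
    p = 1.0 - math.exp(-1.0)
    from fspswitch.sensitivity import SensitivityResult

    res = SensitivityResult("k", 0.1, raw, p_hit=p, method="method-1")
    assert res.semi_normalized == pytest.approx(0.1 * raw, rel=1e-12)
    assert res.elasticity == pytest.approx(0.1 * raw / p, rel=1e-12)


def test_zero_derivative_matrix_gives_exactly_zero_sensitivity():
    """A dummy parameter multiplying a zero-stoichiometry channel leaves
    the generator derivative empty and the sensitivity identically zero."""
    params = {"k": 0.5, "dummy": 1.0}

    def build(pr):
        return ReactionNetwork(
            species=("X",),
            reactions=(
                Reaction("exit", (1,), MassAction(pr, (), "k")),
                Reaction("idle", (0,), MassAction(pr, (), "dummy")),
            ),
            params=pr, builder=build)

    net = build(params)
    hit = Region.rectangle([(1, None)], name="X >= 1")
    space = enumerate_states((0,), [hit])
    gen = build_generator(net, space, {"hit": hit})
    dg = generator_derivative(net, space, {"hit": hit}, "dummy")
    assert np.abs(dg.matrix.toarray()).max() == 0.0
    _, s = solve_augmented(gen, dg, np.array([1.0, 0.0, 0.0]), 5.0)
    assert np.all(s == 0.0)


def test_finite_difference_matches_closed_form_with_second_order_convergence(toy_exponential):
    fx = toy_exponential["fixture"]
    space = toy_exponential["space"]
    sinks = {"hit": fx.regions["hit"]}
    exact = 10.0 * math.exp(-1.0)
    errors = {}
    for h in (2e-3, 1e-3, 5e-4):
        res = finite_difference_sensitivity(fx.network, space, sinks, np.array([0]),
                                            10.0, "k", "hit", rel_step=h, tol=1e-13)
        errors[h] = abs(res.raw - exact)
    assert errors[1e-3] / exact <= 1e-4
    # halving the step shrinks the central-difference error ~4x
    assert errors[1e-3] / errors[5e-4] == pytest.approx(4.0, rel=0.2)
    assert errors[2e-3] / errors[1e-3] == pytest.approx(4.0, rel=0.2)


def test_finite_difference_rejects_bad_step(toy_exponential):
    fx = toy_exponential["fixture"]
    with pytest.raises(ValueError, match="rel_step"):
        finite_difference_sensitivity(fx.network, toy_exponential["space"],
                                      {"hit": fx.regions["hit"]}, np.array([0]),
                                      10.0, "k", "hit", rel_step=0.5)


def test_augmented_p_block_equals_plain_transient_solve():
    fx = birth_death_fixture(4.0, 1.0)
    region = Region.rectangle([(12, None)], name="K >= 12")
    space = enumerate_states((11,), [region])
    gen = build_generator(fx.network, space, {"hit": region})
    p0 = np.zeros(gen.size)
    p0[0] = 1.0
    dg = generator_derivative(fx.network, space, {"hit": region}, "mu")
    sol_aug, _ = solve_augmented(gen, dg, p0, 3.0, tol=1e-12, times=[1.0, 3.0])
    sol = solve_transient(gen, p0, [1.0, 3.0], tol=1e-12)
    assert np.abs(sol_aug.prob - sol.prob).max() <= 1e-10


def test_methods_agree_on_scaled_circuit(scaled, scaled_entry):
    """Method 1 (augmented system) and method 2 (1% central difference)
    agree within 5% for every kinetic rate of the scaled circuit."""
    net = scaled.network
    space, region = scaled_entry["space"], scaled_entry["region"]
    params = ["ak", "bk", "bs", "delta_k", "delta_s"]
    table = sensitivity_table(net, space, {"competence": region},
                              scaled_entry["x0"], 7200.0, params, "competence",
                              method="both", rel_step=0.01, tol=1e-11)
    m1 = {r.parameter: r.raw for r in table if r.method == "method-1"}
    m2 = {r.parameter: r.raw for r in table if r.method == "method-2"}
    for p in params:
        assert abs(m1[p] - m2[p]) <= 0.05 * max(abs(m1[p]), abs(m2[p]))


def test_parameter_order_permutes_results_identically(toy_exponential, scaled, scaled_entry):
    net = scaled.network
    space, region = scaled_entry["space"], scaled_entry["region"]
    a = sensitivity_table(net, space, {"competence": region}, scaled_entry["x0"],
                          1800.0, ["ak", "bs"], "competence", method="method-1")
    b = sensitivity_table(net, space, {"competence": region}, scaled_entry["x0"],
                          1800.0, ["bs", "ak"], "competence", method="method-1")
    assert [r.parameter for r in a] == ["ak", "bs"]
    assert [r.parameter for r in b] == ["bs", "ak"]
    assert a[0].raw == b[1].raw and a[1].raw == b[0].raw


def test_table_reports_consistent_normalizations(scaled, scaled_entry):
    net = scaled.network
    space, region = scaled_entry["space"], scaled_entry["region"]
    (res,) = sensitivity_table(net, space, {"competence": region},
                               scaled_entry["x0"], 1800.0, ["bk"], "competence",
                               method="method-1")
    assert res.semi_normalized == pytest.approx(res.theta0 * res.raw, rel=1e-12)
    assert res.elasticity == pytest.approx(res.semi_normalized / res.p_hit, rel=1e-12)
    assert res.metadata["sink"] == "competence"
    assert res.metadata["horizon_s"] == 1800.0
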