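"""Deterministic structure of the competence circuit and the full model."""

import numpy as np
import pytest
from scipy.optimize import brentq

from fspswitch import (
    ParameterSet,
    deterministic_rhs,
    full_competence_network,
    reduced_competence_network,
    ssa_run,
    vegetative_fixed_point,
)
from fspswitch.competence import (
    fast_subsystem_roots,
    fixed_point_concentrations,
)

BINDING = {"kb_k": 2e-3, "kb_s": 2e-3, "mecA_total": 500.0}


def test_rhs_at_origin_is_pure_production(reduced_net):
    np.testing.assert_allclose(deterministic_rhs(reduced_net, [0.0, 0.0]),
                               [0.0028, 0.057], rtol=1e-12)


def test_vegetative_fixed_point_value_and_residual(reduced_net):
    K, S = fixed_point_concentrations(reduced_net)
    # low-K root: ComK on the order of tens, ComS on the order of hundreds
    assert 10 < K < 30 and 150 < S < 350
    assert np.linalg.norm(deterministic_rhs(reduced_net, [K, S])) < 1e-10
    counts = vegetative_fixed_point(reduced_net)
    np.testing.assert_array_equal(counts, [round(K), round(S)])


def test_fixed_point_matches_independent_bisection_with_feedback_off():
    """With both regulated production terms off, the root has a closed form
    found here by an independent 1-D bisection."""
    params = ParameterSet(bk=1e-30, bs=1e-30)
    net = reduced_competence_network(params)
    K, S = fixed_point_concentrations(net)
    assert S == pytest.approx(0.0, abs=1e-6)

    def f(k):  # ak = delta_k * k / (1 + k/Gamma_k) at S = 0
        return params.ak - params.delta_k * k / (1.0 + k / params.Gamma_k)

    K_ref = brentq(f, 0.1, 50.0, xtol=1e-13)
    assert K == pytest.approx(K_ref, rel=1e-9)


def test_fixed_point_scan_failure_reports_box():
    # overwhelming basal production pushes the root far beyond the scan box
    net = reduced_competence_network(ParameterSet(ak=10.0))
    with pytest.raises(RuntimeError, match=r"\[0, 200"):
        fixed_point_concentrations(net)


def test_fast_comk_subsystem_is_bistable_at_vegetative_coms(reduced_net):
    roots = fast_subsystem_roots(reduced_net)
    assert len(roots) == 3
    low, threshold, high = roots
    assert 10 < low < 20 and 35 < threshold < 55 and 140 < high < 180


def test_fast_subsystem_monostable_without_feedback():
    net = reduced_competence_network(ParameterSet(bk=1e-30))
    assert len(fast_subsystem_roots(net)) == 1


def test_full_model_requires_binding_config():
    with pytest.raises(ValueError, match="full model requires config rates"):
        full_competence_network(ParameterSet())
    with pytest.raises(ValueError, match="kb_s"):
        full_competence_network(ParameterSet(), {"kb_k": 1e-3, "mecA_total": 100.0})


def test_full_model_conserves_total_meca():
    net = full_competence_network(ParameterSet(), BINDING)
    a_tot = int(BINDING["mecA_total"])
    x0 = (16, 226, a_tot, 0, 0)
    tr = ssa_run(net, x0, 600.0, seed=5)
    totals = tr.states[:, 2] + tr.states[:, 3] + tr.states[:, 4]
    assert np.all(totals == a_tot)
    assert tr.n_events > 10  # binding/unbinding actually fired


def test_full_model_rhs_matches_reduced_at_quasi_steady_state(reduced_net):
    """Projecting the full rate equations onto (ComK, ComS) with complexes
    at their quasi-steady state reproduces the reduced rate equations."""
    pr = ParameterSet()
    full = full_competence_network(pr, BINDING)
    a_tot = BINDING["mecA_total"]
    for K, S in [(5.0, 50.0), (16.0, 226.0), (80.0, 150.0), (150.0, 20.0)]:
        D = 1.0 + K / pr.Gamma_k + S / pr.Gamma_s
        A = a_tot / D
        Ck = a_tot * (K / pr.Gamma_k) / D
        Cs = a_tot * (S / pr.Gamma_s) / D
        rhs_full = deterministic_rhs(full, [K, S, A, Ck, Cs])
        rhs_red = deterministic_rhs(reduced_net, [K, S])
        np.testing.assert_allclose(rhs_full[:2], rhs_red, rtol=1e-2, atol=1e-9)


def test_full_and_reduced_ssa_means_agree():
    """Time-averaged ComK of the full model (fast binding, Michaelis ratios
    matched) approaches the reduced model within Monte-Carlo error."""
    pr = ParameterSet(omega=0.2)
    reduced = reduced_competence_network(pr)
    full = full_competence_network(pr, {"kb_k": 2e-2, "kb_s": 2e-2, "mecA_total": 100.0})
    a_tot = int(round(100.0 * pr.omega))
    x0r = vegetative_fixed_point(reduced)
    x0f = (int(x0r[0]), int(x0r[1]), a_tot, 0, 0)
    T, n = 3600.0, 30
    means_r = [ssa_run(reduced, x0r, T, 100 + i).time_average(T) for i in range(n)]
    means_f = [ssa_run(full, x0f, T, 200 + i).time_average(T) for i in range(n)]
    se = np.hypot(np.std(means_r, ddof=1), np.std(means_f, ddof=1)) / np.sqrt(n)
    assert abs(np.mean(means_r) - np.mean(means_f)) < 3 * se


def test_pure_decay_trajectories_are_monotone():
    """With production rates numerically zero every species is nonincreasing
    along any SSA path."""
    net = reduced_competence_network(ParameterSet(ak=1e-300, bk=1e-300, bs=1e-300))
    tr = ssa_run(net, (30, 40), 1e6, seed=3)
    assert np.all(np.diff(tr.states[:, 0]) <= 0)
    assert np.all(np.diff(tr.states[:, 1]) <= 0)
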