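"""Return-time distribution and its three expectation estimators."""

import math

import numpy as np
import pytest

from fspswitch import (
    ProjectedGenerator,
    Region,
    build_generator,
    build_return_system,
    enumerate_states,
    expected_return_time_integral,
    expected_return_time_riemann,
    mfpt_linear_solve,
    return_probability,
    sample_return_times,
    uniform_region_distribution,
)
from fspswitch.fixtures import pure_death_fixture, two_state_fixture


@pytest.fixture(scope="module")
def pure_death_system():
    fx = pure_death_fixture(mu=1.0)
    zero = Region.rectangle([(None, 0)], name="K = 0")
    space = enumerate_states((5,), [zero])
    gen = build_return_system(fx.network, space, zero)
    return fx, space, gen, zero


def test_uniform_distribution_over_region():
    space = enumerate_states((3, 0))
    region = Region.rectangle([(0, 3), (None, None)], name="all four")
    p0 = uniform_region_distribution(space, region, n_sinks=2)
    np.testing.assert_allclose(p0[:4], 0.25)
    assert p0.sum() == pytest.approx(1.0)
    point = Region.rectangle([(2, 2), (None, None)])
    p1 = uniform_region_distribution(space, point, n_sinks=0)
    assert p1[2] == 1.0 and p1.sum() == 1.0


def test_uniform_distribution_empty_region_errors():
    absorbed = Region.rectangle([(2, None), (None, None)], name="absorbed")
    space = enumerate_states((3, 0), [absorbed])
    with pytest.raises(ValueError, match="no retained state"):
        uniform_region_distribution(space, absorbed, n_sinks=2)


def test_pure_death_return_generator_structure(pure_death_system):
    _, space, gen, _ = pure_death_system
    A = gen.matrix.toarray()
    # lower-bidiagonal: rate mu*K from K to K-1, K=1 feeding the sink
    for K in range(2, 6):
        src = space.position_of(np.array([[K]]))[0]
        dst = space.position_of(np.array([[K - 1]]))[0]
        assert A[dst, src] == pytest.approx(K)
    assert A[gen.sink_index("return"), space.position_of(np.array([[1]]))[0]] == 1.0
    assert np.abs(A.sum(axis=0)).max() < 1e-12


def test_return_probability_exponential_closed_form():
    fx = two_state_fixture(k=0.5)
    space = enumerate_states((0,), [fx.regions["hit"]])
    gen = build_generator(fx.network, space, {"return": fx.regions["hit"]})
    grid = np.array([0.0, 1.0, 2.0, 4.0])
    g1, g2 = return_probability(gen, np.array([1.0, 0.0, 0.0]), grid, tol=1e-12)
    assert g1[0] == 0.0
    np.testing.assert_allclose(g1, 1.0 - np.exp(-0.5 * grid), atol=1e-10)
    np.testing.assert_array_equal(g2, 0.0)


def test_return_probability_pure_death_matches_ssa(pure_death_system):
    """g1(t) from the dual-sink solve agrees with the empirical CDF of
    seeded SSA first-passage samples within the Chernoff band."""
    from fspswitch import chernoff_epsilon

    fx, space, gen, zero = pure_death_system
    p0 = np.zeros(gen.size)
    p0[space.position_of(np.array([[3]]))[0]] = 1.0
    grid = np.array([0.0, 1.0, 2.0, 4.0])
    g1, _ = return_probability(gen, p0, grid, tol=1e-12)
    start = Region.rectangle([(3, 3)], name="K = 3")
    n = 5000
    samples = sample_return_times(fx.network, start, zero, t_max=50.0,
                                  n_runs=n, seed=17)
    eps = chernoff_epsilon(n, 0.01)
    for t, g in zip(grid[1:], g1[1:]):
        empirical = np.mean(samples.samples <= t)
        assert abs(empirical - g) < eps


def test_riemann_estimator_exponential_and_step():
    grid = np.arange(0.0, 20.0 + 1e-9, 0.01)
    g1 = 1.0 - np.exp(-grid)
    est = expected_return_time_riemann(g1, grid)
    assert est == pytest.approx(1.0, rel=0.01)
    # step CDF 0 -> 1 at tau: estimator recovers tau up to grid quantization
    tau = 7.4321
    step = (grid >= tau).astype(float)
    assert abs(expected_return_time_riemann(step, grid) - tau) <= 0.01


def test_riemann_gap_shrinks_with_grid_refinement():
    gaps = {}
    for dt in (0.2, 0.1):
        grid = np.arange(0.0, 25.0 + 1e-9, dt)
        g1 = 1.0 - np.exp(-grid)
        gaps[dt] = abs(expected_return_time_riemann(g1, grid, variant="right")
                       - expected_return_time_integral(g1, grid))
    assert gaps[0.1] <= 0.55 * gaps[0.2]


def test_integral_estimator_exponential_and_degenerate():
    grid = np.arange(0.0, 20.0 + 1e-9, 0.01)
    g1 = 1.0 - np.exp(-grid)
    assert expected_return_time_integral(g1, grid) == pytest.approx(1.0, rel=0.005)
    instant = np.ones_like(grid)
    instant[0] = 0.0
    assert expected_return_time_integral(instant, grid) <= 0.01


def test_estimators_agree_on_pure_death(pure_death_system):
    _, space, gen, _ = pure_death_system
    p0 = np.zeros(gen.size)
    p0[space.position_of(np.array([[3]]))[0]] = 1.0
    grid = np.arange(0.0, 30.0 + 1e-9, 0.02)
    g1, g2 = return_probability(gen, p0, grid, tol=1e-12)
    exact = mfpt_linear_solve(gen, p0)
    assert exact == pytest.approx(1.0 + 0.5 + 1.0 / 3.0, abs=1e-12)
    riemann = expected_return_time_riemann(g1, grid)
    integral = expected_return_time_integral(g1, grid)
    assert abs(riemann - exact) <= 0.02 * exact
    assert abs(integral - exact) <= 0.02 * exact


def test_mfpt_errors_on_unreachable_sink():
    # second transient state is isolated: no path to the sink
    A = np.array([[-1.0, 0.0, 0.0],
                  [0.0, 0.0, 0.0],
                  [1.0, 0.0, 0.0]])
    gen = ProjectedGenerator.from_matrix(A, sink_names=("return",))
    with pytest.raises(ValueError, match="cannot reach any absorbing sink"):
        mfpt_linear_solve(gen, np.array([0.5, 0.5, 0.0]))


def test_decreasing_series_is_rejected():
    grid = np.array([0.0, 1.0, 2.0])
    bad = np.array([0.0, 0.5, 0.4])
    with pytest.raises(ValueError, match="not a valid CDF"):
        expected_return_time_riemann(bad, grid)
    with pytest.raises(ValueError, match="not a valid CDF"):
        expected_return_time_integral(bad, grid)
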