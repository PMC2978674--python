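import math

import numpy as np
import pytest

from fspswitch import (
    Region,
    build_generator,
    enumerate_states,
    reduced_competence_network,
    scaled_competence_fixture,
    solve_transient,
    two_state_fixture,
    vegetative_fixed_point,
)


@pytest.fixture(scope="session")
def reduced_net():
    return reduced_competence_network()


@pytest.fixture(scope="session")
def scaled():
    """Competence circuit at omega = 0.1 with its regions and boxes."""
    return scaled_competence_fixture(0.1)


@pytest.fixture(scope="session")
def scaled_entry(scaled):
    """Certified 2-hour entry solve on the scaled circuit."""
    net = scaled.network
    comp = scaled.regions["competence"]
    space = enumerate_states(scaled.recommended_box, absorbed_regions=[comp])
    gen = build_generator(net, space, {"competence": comp})
    x0 = scaled.known["vegetative_state"]
    p0 = np.zeros(gen.size)
    p0[int(space.position_of(x0[None, :])[0])] = 1.0
    grid = np.linspace(720.0, 7200.0, 10)
    sol = solve_transient(gen, p0, grid, tol=1e-12)
    return {"net": net, "space": space, "gen": gen, "p0": p0, "sol": sol,
            "region": comp, "x0": x0, "T": 7200.0}


@pytest.fixture(scope="session")
def toy_exponential():
    """Two-state fixture with k = 0.1: generator, p0, closed forms."""
    fx = two_state_fixture(k=0.1)
    space = enumerate_states((0,), absorbed_regions=[fx.regions["hit"]])
    gen = build_generator(fx.network, space, {"hit": fx.regions["hit"]})
    return {"fixture": fx, "space": space, "gen": gen,
            "p0": np.array([1.0, 0.0, 0.0]), "k": 0.1}


def point_mass(space, counts, n_sinks):
    p0 = np.zeros(space.n_states + n_sinks)
    pos = int(space.position_of(np.asarray(counts)[None, :])[0])
    assert pos >= 0
    p0[pos] = 1.0
    return p0
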