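"""Gillespie stochastic simulation (direct method) with hitting detection.

Exact sample paths of the jump process defined by a reaction network: at
each event an exponential waiting time with rate equal to the total
propensity is drawn, then a channel is chosen with probability
proportional to its propensity (two uniform draws per event).

Randomness is pinned to numpy's PCG64 generator.  Ensemble estimates
derive one child seed per run from the master seed through
``SeedSequence(master_seed).spawn(n_runs)`` (a counter-based split), so
run ``i`` is reproducible in isolation.

Monte-Carlo hitting estimates carry a distribution-free two-sided
Chernoff–Hoeffding half-width ``epsilon = sqrt(ln(2/delta) / (2 n))``:
``P(|p_hat - p| >= epsilon) <= delta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork, validate_state
from .statespace import Region

__all__ = [
    "Trajectory",
    "HittingEstimate",
    "ReturnTimeSamples",
    "ssa_run",
    "estimate_hitting_probability",
    "chernoff_epsilon",
    "sample_return_times",
]


@dataclass
class Trajectory:
    """One sample path: state after each event, including the initial state
    at time 0."""

    times: np.ndarray
    states: np.ndarray  # (n_events + 1, n_species)
    seed: object

    @property
    def n_events(self) -> int:
        return len(self.times) - 1

    def time_average(self, t_final: float, species: int = 0,
                     t_start: float = 0.0) -> float:
        """Holding-time-weighted average of one species over [t_start, t_final]."""
        edges = np.clip(np.append(self.times, t_final), t_start, t_final)
        hold = np.diff(edges)
        return float(np.sum(hold * self.states[:, species]) / (t_final - t_start))


def _propensity_closure(net: ReactionNetwork):
    if net.fast_propensities is not None:
        return net.fast_propensities

    def generic(*x):
        xa = np.asarray(x, dtype=np.int64)
        return tuple(float(r.rates(xa[None, :])[0]) for r in net.reactions)

    return generic


def ssa_run(net: ReactionNetwork, x0, t_final: float, seed) -> Trajectory:
    """One exact direct-method sample path on [0, t_final].

    The path terminates at the first event time beyond ``t_final`` or when
    all propensities vanish (an absorbing state yields a constant
    trajectory, not an error).  Reproducible for a fixed seed.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    x = tuple(int(v) for v in validate_state(x0, net.n_species))
    props = _propensity_closure(net)
    stoich = [tuple(int(s) for s in r.stoichiometry) for r in net.reactions]
    rng = np.random.default_rng(seed)
    times = [0.0]
    path = [x]
    t = 0.0
    while True:
        w = props(*x)
        a0 = math.fsum(w)
        if a0 <= 0.0:
            break
        t += rng.exponential() / a0
        if t > t_final:
            break
        u = rng.random() * a0
        acc = 0.0
        for j, wj in enumerate(w):
            acc += wj
            if u < acc:
                break
        x = tuple(xi + si for xi, si in zip(x, stoich[j]))
        times.append(t)
        path.append(x)
    return Trajectory(times=np.array(times), states=np.array(path, dtype=np.int64), seed=seed)


def chernoff_epsilon(n_runs: int, delta: float) -> float:
    """Two-sided Hoeffding/Chernoff half-width ``sqrt(ln(2/delta)/(2 n))``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not (0.0 < delta < 1.0):
        raise ValueError(f"confidence parameter delta must lie in (0, 1), got {delta}")
    return math.sqrt(math.log(2.0 / delta) / (2.0 * n_runs))


@dataclass
class HittingEstimate:
    """Monte-Carlo hitting-probability estimate with Chernoff certificate."""

    n_runs: int
    n_hits: int
    p_hat: float
    epsilon: float
    delta: float
    seed: object

    def as_dict(self) -> dict:
        return {
            "n_runs": self.n_runs, "n_hits": self.n_hits, "p_hat": self.p_hat,
            "epsilon": self.epsilon, "delta": self.delta, "seed": self.seed,
        }


def _run_hits(net: ReactionNetwork, x0: tuple, region: Region, T: float, rng) -> bool:
    """Lean direct-method loop that stops at the first region entry."""
    props = _propensity_closure(net)
    stoich = [tuple(int(s) for s in r.stoichiometry) for r in net.reactions]
    x = x0
    if region.contains_point(x):
        return True
    t = 0.0
    while True:
        w = props(*x)
        a0 = math.fsum(w)
        if a0 <= 0.0:
            return False
        t += rng.exponential() / a0
        if t > T:
            return False
        u = rng.random() * a0
        acc = 0.0
        for j, wj in enumerate(w):
            acc += wj
            if u < acc:
                break
        x = tuple(xi + si for xi, si in zip(x, stoich[j]))
        if region.contains_point(x):
            return True


def estimate_hitting_probability(net: ReactionNetwork, x0, region: Region,
                                 T: float, n_runs: int, delta: float = 0.01,
                                 seed: int = 0) -> HittingEstimate:
    """Fraction of runs whose path enters ``region`` by time ``T``.

    The estimate carries the Chernoff half-width at confidence ``delta``.
    Per-run seeds are spawned deterministically from ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    eps = chernoff_epsilon(n_runs, delta)
    x0 = tuple(int(v) for v in validate_state(x0, net.n_species))
    children = np.random.SeedSequence(seed).spawn(n_runs)
    hits = 0
    for child in children:
        rng = np.random.default_rng(child)
        if _run_hits(net, x0, region, T, rng):
            hits += 1
    return HittingEstimate(n_runs=n_runs, n_hits=hits, p_hat=hits / n_runs,
                           epsilon=eps, delta=delta, seed=seed)


@dataclass
class ReturnTimeSamples:
    """First-entry times into a target region from a uniformly drawn start.

    Runs that have not entered by ``t_max`` are censored and excluded from
    the mean; the censored fraction is reported alongside.
    """

    samples: np.ndarray
    n_censored: int
    t_max: float
    seed: object

    @property
    def n_runs(self) -> int:
        return len(self.samples) + self.n_censored

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n_runs

    @property
    def mean(self) -> float:
        if len(self.samples) == 0:
            return math.nan
        return float(np.mean(self.samples))

    @property
    def standard_error(self) -> float:
        if len(self.samples) < 2:
            return math.nan
        return float(np.std(self.samples, ddof=1) / math.sqrt(len(self.samples)))


def sample_return_times(net: ReactionNetwork, start_region: Region,
                        return_region: Region, t_max: float, n_runs: int,
                        seed: int = 0) -> ReturnTimeSamples:
    """SSA sampling of the first-entry time into ``return_region``.

    Each run starts at a state drawn uniformly from the (finite,
    rectangular) ``start_region``, which must be disjoint from
    ``return_region``; the first entry time into the return region is
    recorded, runs not returning by ``t_max`` are censored.
    """
    starts = start_region.lattice_points()
    if starts.shape[0] == 0:
        raise ValueError("start_region contains no lattice state")
    if starts.shape[1] != net.n_species:
        raise ValueError("start_region dimension does not match the network")
    overlap = return_region.contains(starts)
    if np.any(overlap):
        bad = tuple(int(v) for v in starts[np.argmax(overlap)])
        raise ValueError(
            f"start and return regions must be disjoint; both contain {bad}"
        )
    props = _propensity_closure(net)
    stoich = [tuple(int(s) for s in r.stoichiometry) for r in net.reactions]
    children = np.random.SeedSequence(seed).spawn(n_runs)
    samples: list[float] = []
    n_censored = 0
    for child in children:
        rng = np.random.default_rng(child)
        x = tuple(int(v) for v in starts[rng.integers(starts.shape[0])])
        t = 0.0
        returned = False
        while True:
            w = props(*x)
            a0 = math.fsum(w)
            if a0 <= 0.0:
                break
            t += rng.exponential() / a0
            if t > t_max:
                break
            u = rng.random() * a0
            acc = 0.0
            for j, wj in enumerate(w):
                acc += wj
                if u < acc:
                    break
            x = tuple(xi + si for xi, si in zip(x, stoich[j]))
            if return_region.contains_point(x):
                samples.append(t)
                returned = True
                break
        if not returned:
            n_censored += 1
    return ReturnTimeSamples(samples=np.array(samples), n_censored=n_censored,
                             t_max=t_max, seed=seed)
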