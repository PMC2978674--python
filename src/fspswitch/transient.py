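"""Transient solution of projected master equations by uniformization.

The solver evaluates ``p(t) = e^{A t} p(0)`` through the uniformized chain
``B = I + A / lam`` with ``lam`` the largest total exit rate:

    e^{A t} p = sum_k  Poisson(lam*t; k) * B^k p .

Because every column of ``A`` sums to zero, ``B`` is a stochastic matrix;
all terms are nonnegative, so the computation is free of cancellation,
conserves probability up to the truncated Poisson tail, and is
deterministic for fixed inputs.  The series is truncated where the Poisson
tail falls below the requested tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln
from scipy.stats import poisson

from .generator import OVERFLOW, ProjectedGenerator, build_generator
from .network import ReactionNetwork
from .statespace import Region, StateSpace, enumerate_states

__all__ = [
    "TransientSolution",
    "solve_transient",
    "hitting_probability",
    "fsp_error_bound",
    "expand_until_certified",
    "resolve_initial_distribution",
    "uniform_region_distribution",
]

_MAX_MATVECS = 50_000_000  # hard cap on series terms per solve

#: probabilities in [-CLAMP, 0) are reported as 0; raw values are kept
_CLAMP = 1e-12


def _poisson_weights(mu: float, tol: float) -> np.ndarray:
    """Poisson(mu) pmf for k = 0..kmax with tail mass below ``tol``."""
    if mu <= 0:
        return np.array([1.0])
    kmax = int(poisson.isf(min(tol, 0.1), mu))
    kmax = max(kmax + 10, 10)
    k = np.arange(kmax + 1)
    logw = k * np.log(mu) - mu - gammaln(k + 1)
    return np.exp(logw)


def _propagate(matvec: Callable[[np.ndarray], np.ndarray], p: np.ndarray,
               mu: float, tol: float) -> np.ndarray:
    """One uniformization step: ``sum_k Pois(mu; k) * B^k p``."""
    w = _poisson_weights(mu, tol)
    if len(w) > _MAX_MATVECS:
        raise RuntimeError(
            f"uniformization would need {len(w)} terms (lam*dt = {mu:.3g}); "
            "split the time grid or reduce the horizon"
        )
    y = w[0] * p
    v = p
    for k in range(1, len(w)):
        v = matvec(v)
        y = y + w[k] * v
    return y


@dataclass
class TransientSolution:
    """Probability mass over a time grid for a projected generator.

    ``sink_mass[name]`` is the absorbed probability per grid time (each
    series nondecreasing); ``error_bound`` is the overflow-sink series, the
    FSP truncation-error certificate for any reported hitting probability.
    Full probability vectors are stored when requested (``prob``), the
    final vector always (``final_prob``); totals track conservation.
    """

    times: np.ndarray
    gen: ProjectedGenerator
    sink_mass_raw: dict[str, np.ndarray]
    totals: np.ndarray
    transient_mass: np.ndarray
    final_prob: np.ndarray
    prob: np.ndarray | None = None
    tol: float = 1e-10

    def sink_mass(self, name: str) -> np.ndarray:
        if name not in self.sink_mass_raw:
            raise ValueError(
                f"unknown sink {name!r}; available sinks: {list(self.sink_mass_raw)}"
            )
        return np.clip(self.sink_mass_raw[name], 0.0, None)

    @property
    def error_bound(self) -> np.ndarray:
        """FSP certificate: probability mass lost to the overflow sink."""
        return self.sink_mass(OVERFLOW)

    def validate(self, mass_tol: float = 1e-9) -> None:
        if np.any(np.abs(self.totals - 1.0) > mass_tol):
            worst = float(np.abs(self.totals - 1.0).max())
            raise AssertionError(f"probability not conserved (max |1-total| = {worst:g})")
        for name, series in self.sink_mass_raw.items():
            if np.any(np.diff(series) < -mass_tol):
                raise AssertionError(f"sink mass {name!r} is not nondecreasing")


def solve_transient(gen: ProjectedGenerator, p0: Sequence[float] | np.ndarray,
                    times: Sequence[float] | np.ndarray, tol: float = 1e-10,
                    store: str = "auto") -> TransientSolution:
    """Integrate ``dp/dt = A p`` from ``p(0) = p0`` over an increasing grid.

    ``store`` controls whether full probability vectors are kept per grid
    time ("full"), only sink masses and the final vector ("sinks"), or
    chosen by problem size ("auto": full below 20,000 states).
    """
    A = gen.matrix
    m = A.shape[0]
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (m,):
        raise ValueError(f"p0 must have shape ({m},), got {p0.shape}")
    if np.any(p0 < 0):
        raise ValueError("p0 must be nonnegative")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"p0 must sum to 1 (got {p0.sum():.12g})")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-D grid")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and nonnegative")

    if store == "auto":
        store = "full" if m <= 20_000 else "sinks"
    if store not in ("full", "sinks"):
        raise ValueError("store must be 'full', 'sinks' or 'auto'")

    lam = max(float(-A.diagonal().min(initial=0.0)), 1e-300)
    B = (A * (1.0 / lam)).tolil()
    B.setdiag(B.diagonal() + 1.0)
    B = B.tocsr()
    matvec = B.__matmul__

    # leading segment from t = 0 to times[0], then the grid intervals
    segments = np.diff(np.concatenate([[0.0], times]))
    seg_tol = tol / max(len(segments), 1)

    nt = gen.transient_count
    sink_series = {name: np.empty(len(times)) for name in gen.sink_names}
    totals = np.empty(len(times))
    transient_mass = np.empty(len(times))
    probs = np.empty((len(times), m)) if store == "full" else None

    p = p0.copy()
    for i, dt in enumerate(segments):
        if dt > 0:
            p = _propagate(matvec, p, lam * dt, seg_tol)
        for k, name in enumerate(gen.sink_names):
            sink_series[name][i] = p[nt + k]
        totals[i] = p.sum()
        transient_mass[i] = p[:nt].sum()
        if probs is not None:
            probs[i] = p

    sol = TransientSolution(
        times=times, gen=gen, sink_mass_raw=sink_series, totals=totals,
        transient_mass=transient_mass, final_prob=p, prob=probs, tol=tol,
    )
    sol.validate(mass_tol=max(1e-9, 10 * tol))
    return sol


def hitting_probability(sol: TransientSolution, sink: str) -> np.ndarray:
    """P(process has entered ``sink``'s region at least once by t).

    Equals the absorbed mass of that sink: one minus the mass retained in
    transient states minus the mass of the other sinks.
    """
    return sol.sink_mass(sink)


def fsp_error_bound(sol: TransientSolution) -> np.ndarray:
    """Truncation-error certificate: the overflow-sink mass per grid time.

    Any reported region-hitting probability carries this series as a
    one-sided accuracy bound.
    """
    return sol.error_bound


def uniform_region_distribution(space: StateSpace, region: Region,
                                n_sinks: int = 0) -> np.ndarray:
    """Uniform initial distribution over the retained states of ``region``.

    Gives equal probability 1/N to each of the N retained states in the
    region and zero elsewhere (including the ``n_sinks`` trailing sink
    entries).
    """
    mask = space.mask_in(region)
    count = int(mask.sum())
    if count == 0:
        raise ValueError(
            f"region {region.name or region!r} contains no retained state of the space"
        )
    p0 = np.zeros(space.n_states + n_sinks)
    p0[:space.n_states][mask] = 1.0 / count
    return p0


def resolve_initial_distribution(p0_spec, space: StateSpace, n_sinks: int) -> np.ndarray:
    """Build an initial probability vector from a point state, a Region
    (uniform), an explicit vector, or a callable of the space."""
    if isinstance(p0_spec, Region):
        return uniform_region_distribution(space, p0_spec, n_sinks)
    if callable(p0_spec):
        return np.asarray(p0_spec(space), dtype=float)
    arr = np.asarray(p0_spec)
    if arr.ndim == 1 and arr.shape[0] == space.n_states + n_sinks and arr.dtype.kind == "f":
        return arr.astype(float)
    counts = np.asarray(p0_spec, dtype=np.int64)
    if counts.shape != (space.n_species,):
        raise ValueError(
            "p0 specification must be a count vector, a Region, a probability "
            f"vector of length {space.n_states + n_sinks}, or a callable"
        )
    pos = int(space.position_of(counts[None, :])[0])
    if pos < 0:
        raise ValueError(f"initial state {tuple(counts)} is not retained in the space")
    p0 = np.zeros(space.n_states + n_sinks)
    p0[pos] = 1.0
    return p0


def expand_until_certified(net: ReactionNetwork,
                           initial_bounds: Sequence[int],
                           sink_regions: dict[str, Region],
                           p0_spec,
                           T: float,
                           target_eps: float,
                           times: Sequence[float] | None = None,
                           growth: float = 1.5,
                           max_expansions: int = 12,
                           tol: float = 1e-10,
                           store: str = "auto",
                           ) -> tuple[StateSpace, TransientSolution]:
    """Grow the truncation box until the FSP certificate meets ``target_eps``.

    The box is expanded by a fixed multiplicative step per species until
    the overflow mass at the horizon satisfies ``eps(T) <= target_eps`` or
    ``max_expansions`` is exhausted (then an error reports the best
    certificate achieved).  The growth sequence is deterministic.
    """
    if not (0.0 < target_eps < 1.0):
        raise ValueError("target_eps must lie in (0, 1)")
    bounds = [int(b) for b in initial_bounds]
    grid = np.asarray(times, dtype=float) if times is not None else np.array([T], dtype=float)
    if abs(grid[-1] - T) > 1e-12 * max(T, 1.0):
        raise ValueError("the last grid time must equal the horizon T")
    best_eps = np.inf
    for _ in range(max_expansions + 1):
        space = enumerate_states(bounds, absorbed_regions=list(sink_regions.values()))
        gen = build_generator(net, space, sink_regions)
        p0 = resolve_initial_distribution(p0_spec, space, gen.n_sinks)
        sol = solve_transient(gen, p0, grid, tol=tol, store=store)
        eps = float(sol.error_bound[-1])
        best_eps = min(best_eps, eps)
        if eps <= target_eps:
            return space, sol
        bounds = [int(np.ceil((b + 1) * growth)) - 1 for b in bounds]
    raise RuntimeError(
        f"FSP box expansion cap reached ({max_expansions} expansions); best "
        f"certificate eps(T) = {best_eps:.3g} > target {target_eps:.3g}"
    )
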