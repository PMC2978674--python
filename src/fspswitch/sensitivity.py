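"""Sensitivity of region-hitting probabilities to kinetic parameters.

Two routes are implemented and cross-validated, mirroring the two-method
comparison used for the competence circuit:

* **Method 1 (augmented system):** the hitting probability solves
  ``dp/dt = A p``; differentiating in a parameter theta gives the block
  system

      d/dt [p; s] = [[A, 0], [dA/dtheta, A]] [p; s],    s(0) = 0,

  whose sink component of ``s(T)`` is the exact derivative of the absorbed
  mass.  The derivative matrix ``dA/dtheta`` is assembled analytically
  from the propensity templates (and verified against numerical
  differentiation at build time).

* **Method 2 (finite differences):** a central difference of the FSP
  hitting probability at a relative step ``h``, both perturbed solves on
  the identical state space and time grid.

Results are reported in three scalings side by side: raw ``dP/dtheta``,
semi-normalized ``theta0 * dP/dtheta`` (comparable across parameters), and
elasticity ``(theta0 / P) * dP/dtheta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .generator import ProjectedGenerator, _assemble, build_generator
from .network import ReactionNetwork, get_param
from .statespace import Region, StateSpace
from .transient import TransientSolution, resolve_initial_distribution, solve_transient

__all__ = [
    "GeneratorDerivative",
    "SensitivityResult",
    "generator_derivative",
    "solve_augmented",
    "finite_difference_sensitivity",
    "sensitivity_table",
]


@dataclass
class GeneratorDerivative:
    """Entrywise partial derivative of a projected generator in one parameter."""

    matrix: object  # sparse CSR, same shape/ordering as the generator
    parameter: str
    theta0: float


def generator_derivative(net: ReactionNetwork, space: StateSpace,
                         sink_regions: Mapping[str, Region], parameter: str,
                         verify: bool = True) -> GeneratorDerivative:
    """Assemble ``dA/dtheta`` analytically on the given space.

    Every edge of the generator carries the analytic partial derivative of
    its propensity; the diagonal closes the columns to zero, so the
    sparsity pattern is contained in the generator's pattern plus the
    diagonal.  With ``verify=True`` the analytic propensity derivatives are
    checked against a central difference (relative step 1e-6) on a sampled
    set of states.
    """
    for r in net.reactions:
        if not hasattr(r.propensity, "d_param"):
            raise ValueError(
                f"reaction {r.name!r} propensity supports no parameter derivatives"
            )
    try:
        get_param(net.params, parameter)
    except (AttributeError, KeyError, TypeError):
        raise ValueError(f"unknown parameter {parameter!r} for this network") from None
    theta0 = get_param(net.params, parameter)

    deriv = _assemble(
        net, space, sink_regions,
        lambda reaction, states: reaction.propensity.d_param(states, parameter),
    )
    if verify:
        _verify_derivatives(net, space, parameter, theta0)
    return GeneratorDerivative(matrix=deriv.matrix, parameter=parameter, theta0=theta0)


def _verify_derivatives(net: ReactionNetwork, space: StateSpace, parameter: str,
                        theta0: float, n_sample: int = 32, rel_step: float = 1e-6,
                        rel_tol: float = 1e-6) -> None:
    """Spot-check analytic propensity derivatives with central differences."""
    from .network import set_param

    n = space.n_states
    idx = np.unique(np.linspace(0, n - 1, min(n_sample, n)).astype(int))
    states = space.states[idx]
    h = theta0 * rel_step
    hi = set_param(net.params, parameter, theta0 + h)
    lo = set_param(net.params, parameter, theta0 - h)
    for r in net.reactions:
        ana = np.asarray(r.propensity.d_param(states, parameter), dtype=float)
        w_hi = np.asarray(r.propensity.with_params(hi)(states), dtype=float)
        w_lo = np.asarray(r.propensity.with_params(lo)(states), dtype=float)
        num = (w_hi - w_lo) / (2.0 * h)
        scale = np.maximum(np.maximum(np.abs(ana), np.abs(num)),
                           1e-9 * max(1.0, float(np.abs(num).max(initial=0.0))))
        bad = np.abs(ana - num) > rel_tol * scale
        if np.any(bad):
            raise AssertionError(
                f"analytic derivative of {r.name!r} w.r.t. {parameter!r} disagrees "
                f"with central difference at state {tuple(int(v) for v in states[np.argmax(bad)])}"
            )


def _solve_augmented_multi(gen: ProjectedGenerator,
                           dmats: Sequence,
                           p0: np.ndarray,
                           times: np.ndarray,
                           tol: float) -> tuple[TransientSolution, list[np.ndarray]]:
    """Uniformized integration of the block system for several parameters
    at once, sharing the forward propagation of ``p``.

    Returns the plain transient solution and, per parameter, the
    sensitivity vector ``s(t)`` on the grid (list of ``(T, m)`` arrays).
    """
    from .transient import _poisson_weights

    A = gen.matrix
    m = A.shape[0]
    times = np.asarray(times, dtype=float)
    lam = max(float(-A.diagonal().min(initial=0.0)), 1e-300)
    B = (A * (1.0 / lam)).tolil()
    B.setdiag(B.diagonal() + 1.0)
    B = B.tocsr()
    D = [dm * (1.0 / lam) for dm in dmats]

    segments = np.diff(np.concatenate([[0.0], times]))
    seg_tol = tol / max(len(segments), 1)

    p = np.asarray(p0, dtype=float).copy()
    s = [np.zeros(m) for _ in dmats]
    p_out = np.empty((len(times), m))
    s_out = [np.empty((len(times), m)) for _ in dmats]

    for i, dt in enumerate(segments):
        if dt > 0:
            w = _poisson_weights(lam * dt, seg_tol)
            yp = w[0] * p
            ys = [w[0] * sj for sj in s]
            for k in range(1, len(w)):
                s = [B @ sj + Dj @ p for sj, Dj in zip(s, D)]
                p = B @ p
                yp += w[k] * p
                for ysj, sj in zip(ys, s):
                    ysj += w[k] * sj
            p, s = yp, ys
        p_out[i] = p
        for out, sj in zip(s_out, s):
            out[i] = sj

    nt = gen.transient_count
    sink_series = {name: p_out[:, nt + k] for k, name in enumerate(gen.sink_names)}
    sol = TransientSolution(
        times=times, gen=gen, sink_mass_raw=sink_series, totals=p_out.sum(axis=1),
        transient_mass=p_out[:, :nt].sum(axis=1), final_prob=p_out[-1],
        prob=p_out if m <= 20_000 else None, tol=tol,
    )
    sol.validate(mass_tol=max(1e-9, 10 * tol))
    return sol, s_out


def solve_augmented(gen: ProjectedGenerator, dgen: GeneratorDerivative,
                    p0: Sequence[float] | np.ndarray, T: float,
                    tol: float = 1e-10,
                    times: Sequence[float] | np.ndarray | None = None,
                    ) -> tuple[TransientSolution, np.ndarray]:
    """Integrate the augmented system for one parameter.

    Returns the transient solution (its p-block) and the sensitivity
    vectors ``s(t)`` on the grid; ``s[-1, gen.sink_index(name)]`` is the
    raw derivative of that sink's hitting probability at the horizon.
    """
    grid = np.asarray(times, dtype=float) if times is not None else np.array([T])
    if abs(grid[-1] - T) > 1e-12 * max(T, 1.0):
        raise ValueError("the last grid time must equal the horizon T")
    p0 = np.asarray(p0, dtype=float)
    sol, s_list = _solve_augmented_multi(gen, [dgen.matrix], p0, grid, tol)
    return sol, s_list[0]


@dataclass
class SensitivityResult:
    """Sensitivity of a hitting probability to one kinetic parameter.

    ``raw`` is ``dP/dtheta``; ``semi_normalized`` is ``theta0 * raw``;
    ``elasticity`` is ``theta0/P * raw``.  ``method`` records which route
    produced it ("method-1" augmented system, "method-2" central
    difference with relative ``step``).
    """

    parameter: str
    theta0: float
    raw: float
    p_hit: float
    method: str
    step: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def semi_normalized(self) -> float:
        return self.theta0 * self.raw

    @property
    def elasticity(self) -> float:
        if self.p_hit == 0.0:
            return float("nan")
        return self.theta0 * self.raw / self.p_hit

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter, "theta0": self.theta0, "raw": self.raw,
            "semi_normalized": self.semi_normalized, "elasticity": self.elasticity,
            "p_hit": self.p_hit, "method": self.method, "step": self.step,
            **({"metadata": self.metadata} if self.metadata else {}),
        }


def finite_difference_sensitivity(net: ReactionNetwork, space: StateSpace,
                                  sink_regions: Mapping[str, Region], p0_spec,
                                  T: float, parameter: str, sink: str,
                                  rel_step: float = 0.01, tol: float = 1e-10,
                                  p_hit: float | None = None) -> SensitivityResult:
    """Method 2: central difference of the FSP hitting probability.

    ``[P(theta0(1+h)) - P(theta0(1-h))] / (2 theta0 h)``, both perturbed
    solves on the identical state space, initial vector and time grid.
    ``p_hit`` (the unperturbed probability, used only for the elasticity
    scaling) is computed with one extra solve when not supplied.
    """
    if not (0.0 < rel_step < 0.2):
        raise ValueError("rel_step must lie in (0, 0.2)")
    theta0 = get_param(net.params, parameter)
    grid = np.array([T])
    values = []
    nets = {}
    for sign in (+1.0, -1.0):
        nets[sign] = net.replace_param(parameter, theta0 * (1.0 + sign * rel_step))
    for sign in (+1.0, -1.0):
        gen = build_generator(nets[sign], space, sink_regions)
        p0 = resolve_initial_distribution(p0_spec, space, gen.n_sinks)
        sol = solve_transient(gen, p0, grid, tol=tol, store="sinks")
        values.append(float(sol.sink_mass(sink)[-1]))
    for v in values:
        if not np.isfinite(v):
            raise FloatingPointError(
                f"hitting probability not finite at perturbed {parameter!r}"
            )
    raw = (values[0] - values[1]) / (2.0 * theta0 * rel_step)
    if p_hit is None:
        gen0 = build_generator(net, space, sink_regions)
        p0 = resolve_initial_distribution(p0_spec, space, gen0.n_sinks)
        p_hit = float(solve_transient(gen0, p0, grid, tol=tol,
                                      store="sinks").sink_mass(sink)[-1])
    return SensitivityResult(parameter=parameter, theta0=theta0, raw=raw,
                             p_hit=p_hit, method="method-2", step=rel_step)


def sensitivity_table(net: ReactionNetwork, space: StateSpace,
                      sink_regions: Mapping[str, Region], p0_spec, T: float,
                      parameters: Sequence[str], sink: str,
                      method: str = "method-1", rel_step: float = 0.01,
                      tol: float = 1e-10,
                      metadata: dict | None = None) -> list[SensitivityResult]:
    """One :class:`SensitivityResult` per parameter, all scalings populated.

    Method 1 shares a single forward propagation across all parameters;
    method "both" concatenates the two tables (method-1 first).  The
    competence region, horizon and initial condition in use are echoed in
    each result's metadata.
    """
    if method not in ("method-1", "method-2", "both"):
        raise ValueError("method must be 'method-1', 'method-2' or 'both'")
    meta = dict(metadata or {})
    meta.setdefault("horizon_s", T)
    meta.setdefault("sink", sink)
    meta.setdefault("regions", {name: (r.name or "predicate")
                                for name, r in sink_regions.items()})
    meta.setdefault("normalization",
                    "raw dP/dtheta; semi_normalized theta0*dP/dtheta; "
                    "elasticity theta0/P*dP/dtheta")
    results: list[SensitivityResult] = []

    if method in ("method-1", "both"):
        gen = build_generator(net, space, sink_regions)
        p0 = resolve_initial_distribution(p0_spec, space, gen.n_sinks)
        dgens = [generator_derivative(net, space, sink_regions, name)
                 for name in parameters]
        sol, s_list = _solve_augmented_multi(
            gen, [dg.matrix for dg in dgens], p0, np.array([T]), tol)
        p_hit = float(sol.sink_mass(sink)[-1])
        j = gen.sink_index(sink)
        for dg, s in zip(dgens, s_list):
            results.append(SensitivityResult(
                parameter=dg.parameter, theta0=dg.theta0, raw=float(s[-1, j]),
                p_hit=p_hit, method="method-1", metadata=dict(meta)))

    if method in ("method-2", "both"):
        gen0 = build_generator(net, space, sink_regions)
        p0 = resolve_initial_distribution(p0_spec, space, gen0.n_sinks)
        p_hit = float(solve_transient(gen0, p0, np.array([T]), tol=tol,
                                      store="sinks").sink_mass(sink)[-1])
        for name in parameters:
            res = finite_difference_sensitivity(
                net, space, sink_regions, p0_spec, T, name, sink,
                rel_step=rel_step, tol=tol, p_hit=p_hit)
            res.metadata = dict(meta)
            results.append(res)
    return results
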