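"""Reaction networks with Hill-type propensities on a molecule-count lattice.

A network is a list of reaction channels, each carrying an integer
stoichiometry vector ``nu`` and a propensity function ``w(x)`` giving the
firing rate at molecule-count state ``x``.  States are plain numpy integer
vectors, one entry per species.  Propensities are represented by small
template objects (Hill activation, Hill repression, saturable degradation,
mass action, free-form expression) so that analytic parameter derivatives
are available for sensitivity analysis and so that a network can be rebuilt
with perturbed parameters.

Concentration/molecule conversion uses a single system-size factor
``omega`` (molecules per nM).  Propensity templates are written so that the
macroscopic rate ``w(omega * c) / omega`` is independent of ``omega`` at
fixed concentration ``c``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "KINETIC_PARAMETERS",
    "Reaction",
    "ReactionNetwork",
    "HillActivation",
    "HillRepression",
    "SaturableDegradation",
    "LinearDilution",
    "MassAction",
    "ExpressionPropensity",
    "propensities",
    "validate_state",
    "get_param",
    "set_param",
]

#: kinetic parameters that sensitivity analysis may differentiate against
KINETIC_PARAMETERS = (
    "ak", "bk", "bs", "k0", "k1", "delta_k", "delta_s", "Gamma_k", "Gamma_s",
)


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameters of the competence circuit (nominal literature values).

    Rates are per second, concentrations in nM.  ``omega`` converts
    concentrations to molecule counts (molecules per nM); with the default
    ``omega = 1`` counts are numerically equal to nM.

    Attributes
    ----------
    ak : basal ComK expression rate (nM/s).
    bk : saturating expression rate of the ComK positive feedback (nM/s).
    bs : unrepressed ComS expression rate (nM/s).
    k0 : ComK concentration for half-maximal ComK auto-activation (nM).
    k1 : ComK concentration for half-maximal ComS repression (nM).
    delta_k : unrepressed ComK degradation rate (1/s).
    delta_s : unrepressed ComS degradation rate (1/s).
    Gamma_k : ComK concentration for half-maximal degradation (nM).
    Gamma_s : ComS concentration for half-maximal degradation (nM).
    n : Hill coefficient of the ComK positive feedback.
    p : Hill coefficient of ComS repression by ComK.
    omega : system size (molecules per nM).
    dilution_k, dilution_s : optional first-order dilution rates (1/s),
        zero by default.
    """

    ak: float = 0.0028
    bk: float = 0.049
    bs: float = 0.057
    k0: float = 100.0
    k1: float = 110.0
    delta_k: float = 0.0014
    delta_s: float = 0.0014
    Gamma_k: float = 500.0
    Gamma_s: float = 50.0
    n: int = 2
    p: int = 5
    omega: float = 1.0
    dilution_k: float = 0.0
    dilution_s: float = 0.0

    def __post_init__(self) -> None:
        for name in KINETIC_PARAMETERS + ("omega",):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        if self.n < 1 or self.p < 1:
            raise ValueError("Hill coefficients n and p must be >= 1")
        if self.dilution_k < 0 or self.dilution_s < 0:
            raise ValueError("dilution rates must be nonnegative")

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def get_param(params: Any, name: str) -> float:
    """Look up a named parameter on a :class:`ParameterSet` or a mapping."""
    if isinstance(params, Mapping):
        return float(params[name])
    return float(getattr(params, name))


def set_param(params: Any, name: str, value: float) -> Any:
    """Return a copy of ``params`` with one named parameter replaced."""
    if isinstance(params, Mapping):
        if name not in params:
            raise KeyError(f"unknown parameter {name!r}")
        out = dict(params)
        out[name] = value
        return out
    return params.replace(**{name: value})


def _col(states: np.ndarray, index: int) -> np.ndarray:
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[None, :]
    return states[:, index]


class Propensity:
    """Base class for propensity templates.

    Subclasses implement ``value(states)`` on an ``(N, d)`` array of counts
    and ``d_param(states, name)`` for the analytic partial derivative with
    respect to a named kinetic parameter (zero array if independent).
    """

    params: Any

    def __call__(self, states: np.ndarray) -> np.ndarray:
        return self.value(np.atleast_2d(np.asarray(states, dtype=float)))

    def value(self, states: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        raise NotImplementedError(
            f"{type(self).__name__} does not provide analytic parameter derivatives"
        )

    def with_params(self, params: Any) -> "Propensity":
        return dataclasses.replace(self, params=params)


@dataclass(frozen=True)
class HillActivation(Propensity):
    """Production with basal rate plus positively auto-regulated Hill term.

    ``w = omega*ak + omega*bk * x^n / ((omega*k0)^n + x^n)`` where ``x`` is
    the count of the activating species.
    """

    params: ParameterSet
    activator: int = 0

    def value(self, states: np.ndarray) -> np.ndarray:
        pr = self.params
        K = _col(states, self.activator)
        Kn = K ** pr.n
        k0n = (pr.omega * pr.k0) ** pr.n
        return pr.omega * pr.ak + pr.omega * pr.bk * Kn / (k0n + Kn)

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        pr = self.params
        K = _col(states, self.activator)
        Kn = K ** pr.n
        k0n = (pr.omega * pr.k0) ** pr.n
        if name == "ak":
            return np.full_like(K, pr.omega)
        if name == "bk":
            return pr.omega * Kn / (k0n + Kn)
        if name == "k0":
            # d/dk0 of omega*bk*Kn/(k0n + Kn); dk0n/dk0 = n*k0n/k0
            return -pr.omega * pr.bk * Kn * pr.n * k0n / pr.k0 / (k0n + Kn) ** 2
        return np.zeros_like(K)


@dataclass(frozen=True)
class HillRepression(Propensity):
    """Production repressed by a Hill function of another species.

    ``w = omega*bs / (1 + (x/(omega*k1))^p)`` with ``x`` the repressor count.
    """

    params: ParameterSet
    repressor: int = 0

    def value(self, states: np.ndarray) -> np.ndarray:
        pr = self.params
        K = _col(states, self.repressor)
        r = (K / (pr.omega * pr.k1)) ** pr.p
        return pr.omega * pr.bs / (1.0 + r)

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        pr = self.params
        K = _col(states, self.repressor)
        r = (K / (pr.omega * pr.k1)) ** pr.p
        if name == "bs":
            return pr.omega / (1.0 + r)
        if name == "k1":
            return pr.omega * pr.bs * pr.p * r / (pr.k1 * (1.0 + r) ** 2)
        return np.zeros_like(K)


@dataclass(frozen=True)
class SaturableDegradation(Propensity):
    """Michaelis–Menten-like degradation shared between two competing species.

    ``w = delta * x_target / (1 + K/(omega*Gamma_k) + S/(omega*Gamma_s))``.
    The shared denominator models competition of ComK and ComS for the MecA
    protease complex.  ``rate_name`` selects ``delta_k`` or ``delta_s``.
    """

    params: ParameterSet
    target: int
    rate_name: str
    comk: int = 0
    coms: int = 1

    def _denominator(self, states: np.ndarray) -> np.ndarray:
        pr = self.params
        K = _col(states, self.comk)
        S = _col(states, self.coms)
        return 1.0 + K / (pr.omega * pr.Gamma_k) + S / (pr.omega * pr.Gamma_s)

    def value(self, states: np.ndarray) -> np.ndarray:
        delta = get_param(self.params, self.rate_name)
        return delta * _col(states, self.target) / self._denominator(states)

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        pr = self.params
        X = _col(states, self.target)
        D = self._denominator(states)
        delta = get_param(pr, self.rate_name)
        if name == self.rate_name:
            return X / D
        if name == "Gamma_k":
            K = _col(states, self.comk)
            return delta * X * K / (pr.omega * pr.Gamma_k**2) / D**2
        if name == "Gamma_s":
            S = _col(states, self.coms)
            return delta * X * S / (pr.omega * pr.Gamma_s**2) / D**2
        return np.zeros_like(X)


@dataclass(frozen=True)
class LinearDilution(Propensity):
    """First-order dilution ``w = rate * x_target``."""

    params: Any
    target: int
    rate_name: str

    def value(self, states: np.ndarray) -> np.ndarray:
        return get_param(self.params, self.rate_name) * _col(states, self.target)

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        X = _col(states, self.target)
        if name == self.rate_name:
            return X.copy()
        return np.zeros_like(X)


@dataclass(frozen=True)
class MassAction(Propensity):
    """Mass-action kinetics ``w = c / omega^(m-1) * prod_i x_i`` over reactant indices.

    ``c`` is the macroscopic rate constant (per second, per nM for each
    reactant beyond the first); an empty reactant list gives a zeroth-order
    (constant) channel with rate ``c * omega``.  ``param_name`` exposes the
    constant to sensitivity analysis under that name.
    """

    params: Any
    reactants: tuple[int, ...]
    param_name: str
    omega: float = 1.0

    def _scale(self) -> float:
        m = len(self.reactants)
        return self.omega ** (1 - m)

    def value(self, states: np.ndarray) -> np.ndarray:
        c = get_param(self.params, self.param_name)
        states = np.atleast_2d(np.asarray(states, dtype=float))
        w = np.full(states.shape[0], c * self._scale())
        for idx in self.reactants:
            w = w * states[:, idx]
        return w

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if name != self.param_name:
            return np.zeros(states.shape[0])
        w = np.full(states.shape[0], self._scale())
        for idx in self.reactants:
            w = w * states[:, idx]
        return w


@dataclass(frozen=True)
class ExpressionPropensity:
    """Free-form propensity evaluated from a numpy expression string.

    Species names are available as variables (arrays of counts), parameters
    by name, and a restricted numpy namespace (``exp``, ``log``, ``sqrt``,
    ``minimum``, ``maximum``, ``where``).  No analytic derivative is
    provided; sensitivity analysis rejects such channels.
    """

    expression: str
    species: tuple[str, ...]
    params: Any

    _NAMESPACE = {
        "exp": np.exp, "log": np.log, "sqrt": np.sqrt,
        "minimum": np.minimum, "maximum": np.maximum, "where": np.where,
    }

    def __call__(self, states: np.ndarray) -> np.ndarray:
        return self.value(np.atleast_2d(np.asarray(states, dtype=float)))

    def value(self, states: np.ndarray) -> np.ndarray:
        env = dict(self._NAMESPACE)
        for i, name in enumerate(self.species):
            env[name] = states[:, i]
        if isinstance(self.params, Mapping):
            env.update({k: float(v) for k, v in self.params.items()})
        elif self.params is not None:
            env.update({k: v for k, v in self.params.as_dict().items()
                        if isinstance(v, (int, float))})
        out = eval(self.expression, {"__builtins__": {}}, env)  # noqa: S307
        return np.broadcast_to(np.asarray(out, dtype=float), (states.shape[0],)).copy()

    def d_param(self, states: np.ndarray, name: str) -> np.ndarray:
        raise NotImplementedError(
            "expression propensities have no analytic parameter derivative"
        )

    def with_params(self, params: Any) -> "ExpressionPropensity":
        return dataclasses.replace(self, params=params)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: stoichiometric change vector plus propensity."""

    name: str
    stoichiometry: tuple[int, ...]
    propensity: Any  # Propensity template or callable states -> rates

    def rates(self, states: np.ndarray) -> np.ndarray:
        w = self.propensity(states)
        return np.asarray(w, dtype=float)


@dataclass
class ReactionNetwork:
    """An ordered collection of species and reaction channels.

    ``params`` may be a :class:`ParameterSet` or a plain dict for custom
    models.  ``builder``, when set by a factory, rebuilds the network from a
    replaced parameter object (used by finite-difference sensitivity).
    ``fast_propensities`` is an optional scalar-arithmetic closure
    ``(x_1, ..., x_d) -> tuple of rates`` used by the SSA inner loop.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    params: Any = None
    builder: Callable[[Any], "ReactionNetwork"] | None = None
    fast_propensities: Callable[..., tuple] | None = None

    def __post_init__(self) -> None:
        if len(self.reactions) < 1:
            raise ValueError("a reaction network needs at least one reaction channel")
        d = len(self.species)
        for r in self.reactions:
            if len(r.stoichiometry) != d:
                raise ValueError(
                    f"reaction {r.name!r}: stoichiometry length {len(r.stoichiometry)} "
                    f"!= number of species {d}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer array of shape (n_reactions, n_species)."""
        return np.array([r.stoichiometry for r in self.reactions], dtype=np.int64)

    def with_params(self, params: Any) -> "ReactionNetwork":
        if self.builder is None:
            raise ValueError(
                "this network has no builder; rebuild it manually with new parameters"
            )
        return self.builder(params)

    def replace_param(self, name: str, value: float) -> "ReactionNetwork":
        return self.with_params(set_param(self.params, name, value))


def validate_state(counts: Sequence[int] | np.ndarray, n_species: int) -> np.ndarray:
    """Check a molecule-count state: right length, nonnegative integers."""
    x = np.asarray(counts)
    if x.shape != (n_species,):
        raise ValueError(f"state must have shape ({n_species},), got {x.shape}")
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError("molecule counts must be integers")
        x = np.round(x).astype(np.int64)
    if np.any(x < 0):
        raise ValueError(f"molecule counts must be nonnegative, got {x}")
    return x.astype(np.int64)


def propensities(net: ReactionNetwork, x: Sequence[int] | np.ndarray) -> np.ndarray:
    """Evaluate all reaction propensities at a single state.

    Returns a length-M vector, elementwise nonnegative and finite.
    """
    xv = validate_state(x, net.n_species)
    w = np.array([float(r.rates(xv[None, :])[0]) for r in net.reactions])
    if not np.all(np.isfinite(w)):
        raise FloatingPointError(f"non-finite propensity at state {xv}: {w}")
    if np.any(w < 0):
        raise ValueError(f"negative propensity at state {xv}: {w}")
    return w
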