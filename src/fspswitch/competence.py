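"""The ComK/ComS competence circuit of *Bacillus subtilis*.

The excitable MeKS module: ComK activates its own transcription through a
Hill-type positive feedback, represses ComS transcription, and both
proteins are degraded by the shared MecA--ClpP--ClpC protease, for which
they compete.  Two model variants are provided:

* the reduced two-species model (ComK, ComS) with four reaction channels,
  obtained from the full circuit by quasi-steady-state elimination of the
  MecA complexes -- this is the workhorse model, fully parameterised by
  nominal literature values;
* the full five-species model (ComK, ComS, MecA, MecA:ComK, MecA:ComS)
  with explicit mass-action binding/unbinding, whose binding constants are
  not fixed by the literature and must be supplied via configuration
  (experimental).

Reduced-model channels, in molecule units with system size ``Omega``:

    production of ComK   w1 = Omega*ak + Omega*bk*K^n / ((Omega*k0)^n + K^n)
    degradation of ComK  w2 = delta_k*K / (1 + K/(Omega*Gk) + S/(Omega*Gs))
    production of ComS   w3 = Omega*bs / (1 + (K/(Omega*k1))^p)
    degradation of ComS  w4 = delta_s*S / (1 + K/(Omega*Gk) + S/(Omega*Gs))

The deterministic rate equations are the macroscopic limit
``dc/dt = sum_r nu_r w_r(Omega*c) / Omega``; they are independent of
``Omega``.  The vegetative state is the low-ComK stable root of those
equations; with nominal parameters it sits near (K, S) = (16, 226) nM and
is the unique fixed point of the full system.  Excitability is of the
fast--slow kind: at frozen (vegetative) ComS the fast ComK subsystem is
bistable, with an unstable threshold near 45 nM and an upper branch near
160 nM, so fluctuations that push ComK past the separatrix trigger a long
excursion to suprabasal ComK -- a competence episode -- before ComS
repression restores the vegetative state.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
from scipy.optimize import brentq

from .network import (
    HillActivation,
    HillRepression,
    LinearDilution,
    MassAction,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SaturableDegradation,
)

__all__ = [
    "reduced_competence_network",
    "full_competence_network",
    "deterministic_rhs",
    "vegetative_fixed_point",
    "fixed_point_concentrations",
    "find_deterministic_roots",
    "DEFAULT_COMPETENCE_THRESHOLD_NM",
    "DEFAULT_RETURN_THRESHOLD_NM",
    "DEFAULT_HORIZON_S",
    "fast_subsystem_roots",
    "competence_threshold_molecules",
    "return_threshold_molecules",
]

#: ComK concentration (nM) above which the cell is scored as competent.
#: Chosen above the excitation threshold of the fast ComK subsystem at
#: vegetative ComS (~45 nM) with a safety margin, and roughly four times
#: the vegetative ComK level, so that crossings mark committed excitable
#: excursions rather than ordinary fluctuations.  All outputs echo the
#: region actually used.
DEFAULT_COMPETENCE_THRESHOLD_NM = 65.0

#: ComK concentration (nM) below which the cell is scored as returned to
#: the vegetative state (the vegetative fixed point sits near 16 nM).
DEFAULT_RETURN_THRESHOLD_NM = 25.0

#: the study horizon: 40 hours of molecular reactions, in seconds
DEFAULT_HORIZON_S = 144_000.0


def competence_threshold_molecules(params: ParameterSet,
                                   threshold_nm: float = DEFAULT_COMPETENCE_THRESHOLD_NM) -> int:
    """Competence threshold in molecules for a given system size."""
    return max(1, int(round(threshold_nm * params.omega)))


def return_threshold_molecules(params: ParameterSet,
                               threshold_nm: float = DEFAULT_RETURN_THRESHOLD_NM) -> int:
    """Vegetative-return threshold in molecules for a given system size."""
    return max(1, int(round(threshold_nm * params.omega)))


def _reduced_fast_closure(pr: ParameterSet):
    ak, bk, bs = pr.ak, pr.bk, pr.bs
    dk, ds = pr.delta_k, pr.delta_s
    n, p, om = pr.n, pr.p, pr.omega
    k0n = (om * pr.k0) ** n
    k1m = om * pr.k1
    gk = om * pr.Gamma_k
    gs = om * pr.Gamma_s
    lk, ls = pr.dilution_k, pr.dilution_s
    if lk > 0 or ls > 0:
        def props(K: float, S: float) -> tuple:
            Kn = K ** n
            D = 1.0 + K / gk + S / gs
            return (om * ak + om * bk * Kn / (k0n + Kn), dk * K / D,
                    om * bs / (1.0 + (K / k1m) ** p), ds * S / D,
                    lk * K, ls * S)
    else:
        def props(K: float, S: float) -> tuple:
            Kn = K ** n
            D = 1.0 + K / gk + S / gs
            return (om * ak + om * bk * Kn / (k0n + Kn), dk * K / D,
                    om * bs / (1.0 + (K / k1m) ** p), ds * S / D)
    return props


def reduced_competence_network(params: ParameterSet | None = None) -> ReactionNetwork:
    """The two-species, four-channel reduced competence model.

    Species order is ``("ComK", "ComS")``.  Optional first-order dilution
    channels are appended when ``params.dilution_k/s`` are nonzero.
    """
    pr = params if params is not None else ParameterSet()
    if not isinstance(pr, ParameterSet):
        raise TypeError("reduced_competence_network expects a ParameterSet")
    reactions = [
        Reaction("ComK production", (1, 0), HillActivation(pr, activator=0)),
        Reaction("ComK degradation", (-1, 0),
                 SaturableDegradation(pr, target=0, rate_name="delta_k")),
        Reaction("ComS production", (0, 1), HillRepression(pr, repressor=0)),
        Reaction("ComS degradation", (0, -1),
                 SaturableDegradation(pr, target=1, rate_name="delta_s")),
    ]
    if pr.dilution_k > 0:
        reactions.append(Reaction("ComK dilution", (-1, 0),
                                  LinearDilution(pr, target=0, rate_name="dilution_k")))
    if pr.dilution_s > 0:
        reactions.append(Reaction("ComS dilution", (0, -1),
                                  LinearDilution(pr, target=1, rate_name="dilution_s")))
    return ReactionNetwork(
        species=("ComK", "ComS"),
        reactions=tuple(reactions),
        params=pr,
        builder=reduced_competence_network,
        fast_propensities=_reduced_fast_closure(pr),
    )


_FULL_REQUIRED = ("kb_k", "kb_s", "mecA_total")


def full_competence_network(params: ParameterSet | None = None,
                            binding_params: dict | None = None) -> ReactionNetwork:
    """The five-species competence model with explicit MecA complexes.

    Experimental: the binding/unbinding rate constants are not fixed by the
    literature and must be supplied in ``binding_params``:

    * ``kb_k``, ``kb_s`` -- association rates of MecA with ComK / ComS
      (1/(nM s));
    * ``mecA_total`` -- total MecA concentration (nM, conserved);
    * optionally ``kcat_k``, ``kcat_s`` (complex-mediated degradation, 1/s)
      and ``ku_k``, ``ku_s`` (dissociation, 1/s).

    Unsupplied catalytic and dissociation rates are derived from the
    consistency rule that quasi-steady-state elimination of the complexes
    must reproduce the reduced model: the Michaelis constants
    ``(ku + kcat)/kb`` must equal ``Gamma_k`` / ``Gamma_s`` and the
    saturated turnover must satisfy ``kcat * mecA_total / Gamma = delta``.
    Species order is ``("ComK", "ComS", "MecA", "MecA_ComK", "MecA_ComS")``;
    total MecA (free plus both complexes) is conserved by every channel.
    """
    pr = params if params is not None else ParameterSet()
    if binding_params is None or any(k not in binding_params for k in _FULL_REQUIRED):
        missing = [] if binding_params is None else [
            k for k in _FULL_REQUIRED if k not in binding_params]
        raise ValueError(
            "full model requires config rates: supply binding_params with keys "
            f"{_FULL_REQUIRED} (missing: {missing or 'all'})"
        )
    bp = dict(binding_params)
    a_tot = float(bp["mecA_total"])
    if a_tot <= 0:
        raise ValueError("mecA_total must be strictly positive")
    for sp, gamma, delta in (("k", pr.Gamma_k, pr.delta_k), ("s", pr.Gamma_s, pr.delta_s)):
        kb = float(bp[f"kb_{sp}"])
        if kb <= 0:
            raise ValueError(f"kb_{sp} must be strictly positive")
        kcat = float(bp.get(f"kcat_{sp}", delta * gamma / a_tot))
        ku = float(bp.get(f"ku_{sp}", kb * gamma - kcat))
        if ku <= 0:
            raise ValueError(
                f"derived ku_{sp} = kb_{sp}*Gamma - kcat_{sp} = {ku:.3g} <= 0; "
                "increase kb or supply ku explicitly"
            )
        bp[f"kcat_{sp}"], bp[f"ku_{sp}"] = kcat, ku
    rates = {
        "kb_k": float(bp["kb_k"]), "ku_k": bp["ku_k"], "kcat_k": bp["kcat_k"],
        "kb_s": float(bp["kb_s"]), "ku_s": bp["ku_s"], "kcat_s": bp["kcat_s"],
        "mecA_total": a_tot,
    }
    om = pr.omega
    species = ("ComK", "ComS", "MecA", "MecA_ComK", "MecA_ComS")
    reactions = (
        Reaction("ComK production", (1, 0, 0, 0, 0), HillActivation(pr, activator=0)),
        Reaction("ComS production", (0, 1, 0, 0, 0), HillRepression(pr, repressor=0)),
        Reaction("MecA:ComK binding", (-1, 0, -1, 1, 0),
                 MassAction(rates, reactants=(0, 2), param_name="kb_k", omega=om)),
        Reaction("MecA:ComK unbinding", (1, 0, 1, -1, 0),
                 MassAction(rates, reactants=(3,), param_name="ku_k", omega=om)),
        Reaction("MecA-mediated ComK degradation", (0, 0, 1, -1, 0),
                 MassAction(rates, reactants=(3,), param_name="kcat_k", omega=om)),
        Reaction("MecA:ComS binding", (0, -1, -1, 0, 1),
                 MassAction(rates, reactants=(1, 2), param_name="kb_s", omega=om)),
        Reaction("MecA:ComS unbinding", (0, 1, 1, 0, -1),
                 MassAction(rates, reactants=(4,), param_name="ku_s", omega=om)),
        Reaction("MecA-mediated ComS degradation", (0, 0, 1, 0, -1),
                 MassAction(rates, reactants=(4,), param_name="kcat_s", omega=om)),
    )

    def builder(new_params: Any) -> ReactionNetwork:
        if isinstance(new_params, ParameterSet):
            return full_competence_network(new_params, dict(binding_params))
        raise TypeError("full model builder expects a ParameterSet")

    ak, bk, bs = pr.ak, pr.bk, pr.bs
    n, p = pr.n, pr.p
    k0n = (om * pr.k0) ** n
    k1m = om * pr.k1
    kbk, kuk, cak = rates["kb_k"] / om, rates["ku_k"], rates["kcat_k"]
    kbs_, kus, cas = rates["kb_s"] / om, rates["ku_s"], rates["kcat_s"]

    def fast(K: float, S: float, A: float, Ck: float, Cs: float) -> tuple:
        Kn = K ** n
        return (om * ak + om * bk * Kn / (k0n + Kn),
                om * bs / (1.0 + (K / k1m) ** p),
                kbk * K * A, kuk * Ck, cak * Ck,
                kbs_ * S * A, kus * Cs, cas * Cs)

    net = ReactionNetwork(species=species, reactions=reactions, params=pr,
                          builder=builder, fast_propensities=fast)
    net.binding_params = rates  # resolved constants, echoed in outputs
    return net


def deterministic_rhs(net: ReactionNetwork, conc: Sequence[float] | np.ndarray) -> np.ndarray:
    """Macroscopic rate equations ``sum_r nu_r w_r(Omega*c) / Omega``.

    ``conc`` is a real concentration vector (nM); the result is in nM/s and
    independent of ``Omega``.
    """
    c = np.asarray(conc, dtype=float)
    if c.shape != (net.n_species,):
        raise ValueError(f"concentration vector must have shape ({net.n_species},)")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    omega = net.params.omega if isinstance(net.params, ParameterSet) else 1.0
    x = (omega * c)[None, :]
    rhs = np.zeros(net.n_species)
    for r in net.reactions:
        rhs += np.asarray(r.stoichiometry, dtype=float) * float(r.rates(x)[0]) / omega
    return rhs


def _s_nullcline(net: ReactionNetwork, K: float, s_max: float = 1e7) -> float:
    """Solve rhs_S(K, S) = 0 for S >= 0 at fixed K (unique: rhs_S is
    strictly decreasing in S)."""

    def f(S: float) -> float:
        return deterministic_rhs(net, np.array([K, S]))[1]

    if f(0.0) <= 0.0:
        return 0.0
    hi = 64.0
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > s_max:
            raise RuntimeError(f"no ComS nullcline crossing below S = {s_max}")
    return brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-15)


def find_deterministic_roots(net: ReactionNetwork, k_max: float = 200.0,
                             k_step: float = 1.0) -> list[tuple[float, float]]:
    """All fixed points of the reduced rhs with K in [0, k_max].

    Deterministic sign-change scan of g(K) = rhs_K(K, S*(K)) on a uniform
    K grid, followed by bracketed root refinement; S*(K) is the unique ComS
    nullcline.  Excitable parameterisations yield three roots (stable node,
    saddle, unstable focus).
    """
    if net.n_species != 2:
        raise ValueError("fixed-point scan requires a two-species (reduced) network")

    def g(K: float) -> float:
        return deterministic_rhs(net, np.array([K, _s_nullcline(net, K)]))[0]

    grid = np.arange(0.0, k_max + k_step / 2, k_step)
    vals = np.array([g(K) for K in grid])
    roots: list[tuple[float, float]] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append((grid[i], _s_nullcline(net, grid[i])))
        elif vals[i] * vals[i + 1] < 0:
            K_root = brentq(g, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-15)
            roots.append((K_root, _s_nullcline(net, K_root)))
    return roots


def fast_subsystem_roots(net: ReactionNetwork, s_freeze: float | None = None,
                         k_max: float = 400.0, k_step: float = 1.0) -> list[float]:
    """Fixed points of the fast ComK subsystem at frozen ComS (in nM).

    The circuit is excitable in the fast--slow sense when this subsystem is
    bistable at the vegetative ComS level: a low stable root, an unstable
    excitation threshold, and an upper stable branch.  ``s_freeze``
    defaults to the vegetative ComS concentration.
    """
    if net.n_species != 2:
        raise ValueError("fast-subsystem scan requires a two-species network")
    if s_freeze is None:
        s_freeze = fixed_point_concentrations(net)[1]

    def g(K: float) -> float:
        return deterministic_rhs(net, np.array([K, s_freeze]))[0]

    grid = np.arange(0.0, k_max + k_step / 2, k_step)
    vals = np.array([g(K) for K in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-15))
    return roots


def fixed_point_concentrations(net: ReactionNetwork, k_max: float = 200.0) -> tuple[float, float]:
    """The low-ComK (vegetative) root of the rate equations, in nM."""
    roots = find_deterministic_roots(net, k_max=k_max)
    if not roots:
        raise RuntimeError(
            f"no sign change of the ComK nullcline found for K in [0, {k_max}] "
            f"(S solved from its own nullcline); widen the scan box"
        )
    K, S = roots[0]
    residual = deterministic_rhs(net, np.array([K, S]))
    if np.linalg.norm(residual) >= 1e-10:
        raise RuntimeError(f"fixed-point residual too large: {residual}")
    return K, S


def vegetative_fixed_point(net: ReactionNetwork, k_max: float = 200.0) -> np.ndarray:
    """Vegetative state as integer molecule counts (low-ComK stable root).

    The root is located in concentration units and converted with the
    network's ``omega``; the unrounded root satisfies ``|rhs| < 1e-10``.
    """
    K, S = fixed_point_concentrations(net, k_max=k_max)
    omega = net.params.omega
    return np.array([int(round(K * omega)), int(round(S * omega))], dtype=np.int64)
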