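"""Projected CME generators with absorbing sinks.

The infinite master equation ``dp/dt = A p`` is projected onto a finite
state space: transitions among retained states are kept; transitions into
a named absorbing region (e.g. the competence region) flow into that
region's sink state; transitions leaving the box that belong to no named
region flow into the ``overflow`` sink, whose accumulated mass is the FSP
truncation-error certificate.  Sinks receive and never emit.  The diagonal
is set to minus the column's off-diagonal sum, so every column of the
operator sums to zero by construction (and is asserted to).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .network import ReactionNetwork
from .statespace import Region, StateSpace

__all__ = ["ProjectedGenerator", "build_generator", "OVERFLOW"]

OVERFLOW = "overflow"


@dataclass
class ProjectedGenerator:
    """Finite transition-rate operator with absorbing sink states.

    ``matrix`` is sparse CSR of shape ``(n_t + n_s, n_t + n_s)`` in column
    convention (``matrix[i, j]`` is the rate from state ``j`` to state
    ``i``); the first ``n_t`` indices are the transient states in the
    enumeration order of ``space``, followed by the sinks in ``sink_names``
    order.
    """

    matrix: sp.csr_matrix
    space: StateSpace | None
    sink_names: tuple[str, ...]

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sinks(self) -> int:
        return len(self.sink_names)

    @property
    def transient_count(self) -> int:
        return self.size - self.n_sinks

    def sink_index(self, name: str) -> int:
        if name not in self.sink_names:
            raise ValueError(
                f"unknown sink {name!r}; available sinks: {list(self.sink_names)}"
            )
        return self.transient_count + self.sink_names.index(name)

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def validate(self, tol: float = 1e-12) -> None:
        """Assert generator invariants: zero column sums, sign structure,
        silent sinks."""
        m = self.matrix
        scale = max(1.0, float(np.abs(m.diagonal()).max(initial=0.0)))
        worst = float(np.abs(self.column_sums()).max(initial=0.0))
        if worst > tol * scale:
            raise AssertionError(f"generator columns do not sum to zero (max |sum| = {worst:g})")
        diag = m.diagonal()
        if np.any(diag > 0):
            raise AssertionError("generator has positive diagonal entries")
        coo = m.tocoo()
        off = coo.row != coo.col
        if np.any(coo.data[off] < 0):
            raise AssertionError("generator has negative off-diagonal entries")
        nt = self.transient_count
        if np.any(coo.col[off] >= nt):
            raise AssertionError("absorbing sink states must not emit transitions")

    @staticmethod
    def from_matrix(matrix, sink_names: tuple[str, ...] = (),
                    space: StateSpace | None = None) -> "ProjectedGenerator":
        """Wrap an explicit rate matrix (dense or sparse, column convention)."""
        m = sp.csr_matrix(matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("generator matrix must be square")
        return ProjectedGenerator(matrix=m, space=space, sink_names=tuple(sink_names))


def build_generator(net: ReactionNetwork, space: StateSpace,
                    sink_regions: Mapping[str, Region]) -> ProjectedGenerator:
    """Assemble the projected generator for ``net`` on ``space``.

    ``sink_regions`` maps sink labels to the absorbed regions used when the
    space was enumerated; an ``overflow`` sink for states outside the box
    (and in no named region) is always appended.  Destination lookup order:
    named sink regions first (they may extend beyond the box), then
    retained in-box states, then overflow.
    """
    return _assemble(net, space, sink_regions,
                     lambda reaction, states: reaction.rates(states))


def _assemble(net: ReactionNetwork, space: StateSpace,
              sink_regions: Mapping[str, Region], value_fn) -> ProjectedGenerator:
    """Shared assembly for the generator and its parameter derivatives.

    ``value_fn(reaction, states)`` supplies the per-state edge weights;
    routing (which destination each edge feeds) is always determined by the
    *propensities*' support, i.e. weights may be negative for derivative
    matrices but edges only exist where the propensity itself can fire.
    """
    if net.n_species != space.n_species:
        raise ValueError(
            f"network has {net.n_species} species but space has {space.n_species}"
        )
    if OVERFLOW in sink_regions:
        raise ValueError(f"sink name {OVERFLOW!r} is reserved for the truncation sink")
    sink_names = tuple(sink_regions) + (OVERFLOW,)
    regions = [sink_regions[name] for name in sink_regions]

    for name, region in zip(sink_regions, regions):
        if np.any(space.mask_in(region)):
            raise ValueError(
                f"sink region {name!r} overlaps retained states; enumerate the "
                "state space with this region absorbed"
            )

    n = space.n_states
    nt_plus = n + len(sink_names)
    states = space.states
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    outflow = np.zeros(n)

    for reaction in net.reactions:
        w_route = np.asarray(reaction.rates(states), dtype=float)  # routing support
        vals_r = np.asarray(value_fn(reaction, states), dtype=float)
        active = w_route > 0
        if not np.any(active):
            continue
        src = np.nonzero(active)[0]
        dest = states[src] + np.asarray(reaction.stoichiometry, dtype=np.int64)
        if np.any(dest < 0):
            bad = src[np.any(dest < 0, axis=1)][0]
            raise ValueError(
                f"reaction {reaction.name!r} fires with positive propensity at "
                f"state {tuple(int(v) for v in states[bad])} but would drive a count negative"
            )
        target = np.full(src.shape[0], n + len(sink_names) - 1, dtype=np.int64)  # overflow
        unrouted = np.ones(src.shape[0], dtype=bool)
        for k, region in enumerate(regions):
            member = region.contains(dest) & unrouted
            target[member] = n + k
            unrouted &= ~member
        if np.any(unrouted):
            pos = space.position_of(dest[unrouted])
            idx = np.nonzero(unrouted)[0]
            inside = pos >= 0
            target[idx[inside]] = pos[inside]
            # remaining stay at overflow
        rows.append(target)
        cols.append(src)
        vals.append(vals_r[src])
        np.add.at(outflow, src, vals_r[src])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(-outflow)

    matrix = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nt_plus, nt_plus),
    ).tocsr()
    gen = ProjectedGenerator(matrix=matrix, space=space, sink_names=sink_names)
    scale = max(1.0, float(np.abs(matrix.diagonal()).max(initial=0.0)))
    worst = float(np.abs(gen.column_sums()).max(initial=0.0))
    if worst > 1e-12 * scale:
        raise AssertionError(f"assembled generator columns sum to {worst:g}, expected 0")
    return gen
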