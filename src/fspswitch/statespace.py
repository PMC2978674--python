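"""Finite lattice state spaces and regions of the molecule-count lattice.

A :class:`Region` is a pure predicate over count vectors (with an optional
rectangle shorthand); a :class:`StateSpace` is the deterministic
enumeration of a box of lattice states minus any absorbed regions.  The
enumeration order is lexicographic with the *first species fastest* and is
fixed, so state indexing is bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Region", "StateSpace", "enumerate_states"]


@dataclass(frozen=True)
class Rect:
    lo: tuple[int, ...]
    hi: tuple[int | None, ...]  # None = unbounded above


@dataclass(frozen=True)
class Region:
    """A subset of the nonnegative lattice, by rectangle or predicate.

    The predicate must be pure and total on the lattice; it receives an
    ``(N, d)`` integer array and returns a boolean array of length N.
    """

    predicate: Callable[[np.ndarray], np.ndarray] | None = None
    rect: Rect | None = None
    name: str = ""

    @staticmethod
    def rectangle(bounds: Sequence[tuple[int | None, int | None]], name: str = "") -> "Region":
        """Axis-aligned box; each entry is ``(lo, hi)``, ``None`` meaning
        0 below / unbounded above."""
        lo = tuple(0 if b[0] is None else int(b[0]) for b in bounds)
        hi = tuple(None if b[1] is None else int(b[1]) for b in bounds)
        return Region(rect=Rect(lo=lo, hi=hi), name=name)

    @staticmethod
    def where(fn: Callable[[np.ndarray], np.ndarray], name: str = "") -> "Region":
        return Region(predicate=fn, name=name)

    @staticmethod
    def from_expression(expr: str, species: Sequence[str], name: str = "") -> "Region":
        """Predicate from a boolean numpy expression over species names,
        e.g. ``"ComK >= 100"``."""
        species = tuple(species)

        def fn(states: np.ndarray) -> np.ndarray:
            env = {"__builtins__": {}}
            local = {nm: states[:, i] for i, nm in enumerate(species)}
            out = eval(expr, env, local)  # noqa: S307
            return np.broadcast_to(np.asarray(out, dtype=bool), (states.shape[0],)).copy()

        return Region(predicate=fn, name=name or expr)

    def __post_init__(self) -> None:
        if (self.predicate is None) == (self.rect is None):
            raise ValueError("a Region needs exactly one of predicate or rect")

    def contains(self, states: np.ndarray) -> np.ndarray:
        """Vectorized membership on an (N, d) array of counts."""
        states = np.atleast_2d(np.asarray(states))
        if self.rect is not None:
            mask = np.ones(states.shape[0], dtype=bool)
            for i, (lo, hi) in enumerate(zip(self.rect.lo, self.rect.hi)):
                mask &= states[:, i] >= lo
                if hi is not None:
                    mask &= states[:, i] <= hi
            return mask
        return np.asarray(self.predicate(states), dtype=bool)

    def contains_point(self, counts: Sequence[int]) -> bool:
        if self.rect is not None:
            for x, lo, hi in zip(counts, self.rect.lo, self.rect.hi):
                if x < lo or (hi is not None and x > hi):
                    return False
            return True
        return bool(self.contains(np.asarray(counts)[None, :])[0])

    def lattice_points(self) -> np.ndarray:
        """Enumerate the (finite) rectangle's lattice points; errors for
        predicate regions or unbounded rectangles."""
        if self.rect is None:
            raise ValueError("lattice_points requires a rectangle region")
        if any(h is None for h in self.rect.hi):
            raise ValueError(f"rectangle region {self.name!r} is unbounded")
        ranges = [np.arange(lo, hi + 1) for lo, hi in zip(self.rect.lo, self.rect.hi)]
        grids = np.meshgrid(*ranges, indexing="ij")
        return np.stack([g.ravel(order="F") for g in grids], axis=1).astype(np.int64)


@dataclass
class StateSpace:
    """Deterministic enumeration of retained lattice states in a box.

    ``bounds`` are per-species inclusive maxima; ``states`` is the ordered
    ``(N, d)`` array of retained states (first species fastest); positions
    of arbitrary in-box states are recovered via :meth:`position_of`.
    """

    bounds: tuple[int, ...]
    states: np.ndarray
    _positions: np.ndarray = field(repr=False)  # full-box flat index -> position or -1

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_species(self) -> int:
        return len(self.bounds)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(b + 1 for b in self.bounds)

    def in_box(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states))
        mask = np.all(states >= 0, axis=1)
        for i, b in enumerate(self.bounds):
            mask &= states[:, i] <= b
        return mask

    def position_of(self, states: np.ndarray) -> np.ndarray:
        """Positions of count vectors in the enumeration; -1 for states
        outside the box or not retained."""
        states = np.atleast_2d(np.asarray(states))
        pos = np.full(states.shape[0], -1, dtype=np.int64)
        ok = self.in_box(states)
        if np.any(ok):
            flat = np.ravel_multi_index(
                tuple(states[ok].T), self.dims, order="F"
            )
            pos[ok] = self._positions[flat]
        return pos

    def mask_in(self, region) -> np.ndarray:
        """Boolean mask of retained states lying in ``region``."""
        return region.contains(self.states)


def enumerate_states(bounds: Sequence[int],
                     absorbed_regions: Iterable = ()) -> StateSpace:
    """Enumerate the lattice box ``0 <= x_i <= bounds[i]`` minus absorbed regions.

    Absorbed regions must be pairwise disjoint on the box (validated by a
    scan); overlap raises an error naming the first overlapping state.
    Order is lexicographic with the first species varying fastest.
    """
    bounds = tuple(int(b) for b in bounds)
    if any(b < 0 for b in bounds):
        raise ValueError(f"bounds must be nonnegative, got {bounds}")
    ranges = [np.arange(b + 1) for b in bounds]
    grids = np.meshgrid(*ranges, indexing="ij")
    all_states = np.stack([g.ravel(order="F") for g in grids], axis=1).astype(np.int64)

    regions = list(absorbed_regions)
    masks = [r.contains(all_states) for r in regions]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            overlap = masks[i] & masks[j]
            if np.any(overlap):
                first = tuple(int(v) for v in all_states[np.argmax(overlap)])
                ni = regions[i].name or f"region {i}"
                nj = regions[j].name or f"region {j}"
                raise ValueError(
                    f"absorbed regions {ni!r} and {nj!r} overlap at state {first}"
                )
    absorbed = np.zeros(all_states.shape[0], dtype=bool)
    for m in masks:
        absorbed |= m

    retained = all_states[~absorbed]
    positions = np.full(all_states.shape[0], -1, dtype=np.int64)
    positions[~absorbed] = np.arange(retained.shape[0])
    return StateSpace(bounds=bounds, states=retained, _positions=positions)
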