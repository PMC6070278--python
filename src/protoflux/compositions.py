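"""Integer compositions of a protocell and the lattice they live on.

A composition records how many sequences of each type a protocell
carries.  Types are ordered: the ``g`` functional catalyst types first
(in network order), the defective type ``omega`` always last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

OMEGA = "omega"

#: hard default on exact-solver state-space size; larger problems should
#: use the agent-based solver.
DEFAULT_STATE_CAP = 100_000


class StateSpaceError(ValueError):
    """Raised when the composition lattice exceeds the configured cap."""


@dataclass(frozen=True)
class Composition:
    """Counts of each sequence type inside one protocell.

    Parameters
    ----------
    counts
        Integer counts, one per type (functional types then ``omega``).
    types
        Type identifiers matching ``counts``; last entry must be
        ``"omega"``.
    """

    counts: tuple[int, ...]
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.types):
            raise ValueError("counts and types must have equal length")
        if self.types[-1] != OMEGA:
            raise ValueError("last type must be 'omega'")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_dict(cls, counts: dict[str, int], types: tuple[str, ...]) -> "Composition":
        return cls(tuple(int(counts.get(t, 0)) for t in types), tuple(types))

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def functional(self) -> tuple[int, ...]:
        return self.counts[:-1]

    @property
    def omega(self) -> int:
        return self.counts[-1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.types, self.counts))


def _enumerate(total: int, k: int) -> np.ndarray:
    """All length-``k`` nonnegative integer tuples summing to ``total``,
    in lexicographically decreasing order of the tuple (deterministic)."""
    if k == 1:
        return np.array([[total]], dtype=np.int64)
    rows = []
    for first in range(total, -1, -1):
        tail = _enumerate(total - first, k - 1)
        block = np.empty((tail.shape[0], k), dtype=np.int64)
        block[:, 0] = first
        block[:, 1:] = tail
        rows.append(block)
    return np.concatenate(rows, axis=0)


@dataclass
class CompositionLattice:
    """Ordered enumeration of every composition with a given total.

    ``size == C(total + g, g)`` where ``g + 1`` is the number of types.
    Indexing is bijective and deterministic.
    """

    total: int
    types: tuple[str, ...]
    counts: np.ndarray = field(repr=False)
    _index: dict[tuple[int, ...], int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {tuple(row): i for i, row in enumerate(self.counts.tolist())}

    @property
    def size(self) -> int:
        return self.counts.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.types)

    def index_of(self, counts) -> int:
        if isinstance(counts, Composition):
            counts = counts.counts
        return self._index[tuple(int(c) for c in counts)]

    def composition(self, index: int) -> Composition:
        return Composition(tuple(self.counts[index].tolist()), self.types)

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        for i in range(self.size):
            yield self.composition(i)


def enumerate_compositions(
    total: int,
    g: int,
    types: tuple[str, ...] | None = None,
    state_cap: int = DEFAULT_STATE_CAP,
) -> CompositionLattice:
    """Enumerate all compositions of ``total`` sequences over ``g``
    functional types plus ``omega``.

    Raises
    ------
    StateSpaceError
        If ``C(total + g, g)`` exceeds ``state_cap``; use the
        agent-based solver for such problems.
    """
    if total < 0 or g < 1:
        raise ValueError("total must be >= 0 and g >= 1")
    size = comb(total + g, g)
    if size > state_cap:
        raise StateSpaceError(
            f"composition lattice has {size} states (> cap {state_cap}); "
            "use the agent-based solver for large ploidy / many types"
        )
    if types is None:
        types = tuple(f"t{i}" for i in range(g)) + (OMEGA,)
    if len(types) != g + 1 or types[-1] != OMEGA:
        raise ValueError("types must list g functional ids followed by 'omega'")
    counts = _enumerate(total, g + 1)
    return CompositionLattice(total=total, types=tuple(types), counts=counts)
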