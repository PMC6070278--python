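"""The protocell life-cycle: development then assortment.

Development replicates the vesicle contents by ``2N`` independent
samplings with replacement from the initial composition ``j``; each
draw yields functional type ``i`` with probability ``q * j_i / N`` and
the defective type ``omega`` with the remaining probability
``1 - q + q * j_omega / N`` (mutation is an irreversible sink).  The
doubled contents then assort uniformly at random into two daughters of
``N`` sequences each (multivariate hypergeometric split).

The marginal law of a single daughter is again a multinomial over ``N``
draws with the same per-draw probabilities — the Wright-Fisher
factorization — although the two daughters are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import multivariate_hypergeom

from protoflux.compositions import Composition, CompositionLattice, enumerate_compositions

__all__ = [
    "LifecycleParams",
    "draw_probabilities",
    "development_distribution",
    "assortment_distribution",
    "lifecycle_offspring_marginal",
    "sample_lifecycle",
    "multinomial_logpmf",
]


@dataclass(frozen=True)
class LifecycleParams:
    """Ploidy ``N``, replication accuracy ``q`` and number of
    functional types ``g``."""

    N: int
    q: float
    g: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.g < 1:
            raise ValueError("g must be >= 1")

    @classmethod
    def from_mutation_rate(cls, N: int, mu: float, L: int, g: int) -> "LifecycleParams":
        """Accuracy from per-base error ``mu`` and length ``L``:
        ``q = (1 - mu) ** L``."""
        return cls(N=N, q=(1.0 - mu) ** L, g=g)

    @property
    def n_types(self) -> int:
        return self.g + 1


def _as_counts(j, n_types: int) -> np.ndarray:
    if isinstance(j, Composition):
        arr = j.as_array()
    else:
        arr = np.asarray(j, dtype=np.int64)
    if arr.shape[-1] != n_types:
        raise ValueError(f"composition has {arr.shape[-1]} types, expected {n_types}")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return arr


def draw_probabilities(j, params: LifecycleParams) -> np.ndarray:
    """Per-draw sampling probabilities during development.

    Supports a batch of compositions (last axis = types); the omega
    probability is computed as the exact complement of the functional
    ones to keep rows summing to one.
    """
    counts = _as_counts(j, params.n_types)
    if np.any(counts.sum(axis=-1) != params.N):
        raise ValueError(f"composition must sum to N={params.N}")
    p = params.q * counts / params.N
    p[..., -1] = 1.0 - p[..., :-1].sum(axis=-1)
    return np.clip(p, 0.0, 1.0)


_LOG_ZERO = -1e9  # exp() underflows to exactly 0.0; keeps 0 * log(0) = 0


def multinomial_logpmf(counts: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    """Vectorized multinomial log-pmf.

    ``counts`` has shape (..., k) summing to ``n``; ``p`` shape (k,).
    """
    counts = np.asarray(counts)
    logp = np.where(p > 0.0, np.log(np.where(p > 0.0, p, 1.0)), _LOG_ZERO)
    coef = gammaln(n + 1) - gammaln(counts + 1).sum(axis=-1)
    return coef + counts @ logp


def development_distribution(
    j, params: LifecycleParams
) -> tuple[CompositionLattice, np.ndarray]:
    """Exact distribution of the doubled contents ``k`` (total ``2N``)
    after development from ``j``: multinomial over ``2N`` draws."""
    counts = _as_counts(j, params.n_types)
    p = draw_probabilities(counts, params)
    lattice = enumerate_compositions(2 * params.N, params.g)
    probs = np.exp(multinomial_logpmf(lattice.counts, 2 * params.N, p))
    return lattice, probs


def assortment_distribution(k) -> tuple[CompositionLattice, np.ndarray]:
    """Exact distribution of one daughter ``m`` when ``k`` (total
    ``2N``) splits uniformly: multivariate hypergeometric; the other
    daughter is ``k - m``.  Symmetric under swapping daughters."""
    k = np.asarray(k, dtype=np.int64) if not isinstance(k, Composition) else k.as_array()
    total = int(k.sum())
    if total % 2 != 0:
        raise ValueError(f"doubled contents must have even total, got {total}")
    N = total // 2
    g = k.shape[0] - 1
    lattice = enumerate_compositions(N, g)
    feasible = np.all(lattice.counts <= k, axis=1)
    probs = np.zeros(lattice.size)
    probs[feasible] = multivariate_hypergeom.pmf(lattice.counts[feasible], m=k, n=N)
    return lattice, probs


def lifecycle_offspring_marginal(
    j, params: LifecycleParams
) -> tuple[CompositionLattice, np.ndarray]:
    """Marginal law of one daughter after development + assortment:
    multinomial over ``N`` draws with the development per-draw
    probabilities (equals the exact marginalization of the composed
    process)."""
    counts = _as_counts(j, params.n_types)
    p = draw_probabilities(counts, params)
    lattice = enumerate_compositions(params.N, params.g)
    probs = np.exp(multinomial_logpmf(lattice.counts, params.N, p))
    return lattice, probs


def sample_lifecycle(
    j, params: LifecycleParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one full life-cycle: develop to ``2N`` then split.

    Returns both daughters (they are dependent given ``j``: their
    counts sum to the development outcome componentwise).
    """
    counts = _as_counts(j, params.n_types)
    p = draw_probabilities(counts, params)
    k = rng.multinomial(2 * params.N, p)
    m1 = rng.multivariate_hypergeometric(k, params.N)
    return m1, k - m1
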