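"""Infinite-population stationary distribution via the life-cycle kernel.

The kernel ``K(m|j) = W(m) * P_WF(m|j)`` combines the Wright-Fisher
daughter marginal with fitness weighting (survival probability
proportional to the critical-metabolite flux of the daughter).  The
stationary population frequencies ``F`` and mean fitness ``Wbar`` solve
the eigen-equation ``K F = Wbar F`` and are found by Perron-Frobenius
(power) iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from protoflux.compositions import CompositionLattice, enumerate_compositions
from protoflux.lifecycle import LifecycleParams, draw_probabilities, multinomial_logpmf
from protoflux.metabolism.flux import FluxFunction

__all__ = [
    "LifecycleKernel",
    "PopulationDistribution",
    "build_kernel",
    "wright_fisher_matrix",
    "stationary_distribution",
    "ConvergenceError",
    "DegenerateKernelError",
]

_LOG_ZERO = -1e9


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class DegenerateKernelError(ValueError):
    """The kernel admits no meaningful stationary state (e.g. all-zero
    fitness)."""


@dataclass
class LifecycleKernel:
    """Dense life-cycle transition kernel on a composition lattice.

    ``matrix[m, j]`` is the rate at which parents of composition ``j``
    contribute surviving daughters of composition ``m``; it is NOT
    column-stochastic because it carries the fitness weight ``W(m)``.
    """

    lattice: CompositionLattice
    matrix: np.ndarray
    fitness: np.ndarray
    params: LifecycleParams


@dataclass
class PopulationDistribution:
    """Stationary frequencies over the composition lattice.

    ``frequencies`` describe protocells at the start of their
    life-cycle (i.e. post-selection survivors).  ``mean_fitness`` is
    the leading eigenvalue: the mean flux of the pre-selection daughter
    pool ``P @ F``, which is *not* the same as the expectation of the
    flux under ``frequencies`` (the latter is the fitness-weighted
    pool mean).
    """

    lattice: CompositionLattice
    frequencies: np.ndarray
    mean_fitness: float
    n_iterations: int = 0
    residual: float = 0.0


def wright_fisher_matrix(params: LifecycleParams, lattice: CompositionLattice) -> np.ndarray:
    """Column-stochastic daughter-marginal matrix ``P[m, j]``:
    probability that a parent of composition ``j`` yields a daughter of
    composition ``m`` (multinomial over ``N`` draws)."""
    from scipy.special import gammaln

    counts = lattice.counts
    p = draw_probabilities(counts, params)  # (S, g+1), row per parent j
    logp = np.where(p > 0.0, np.log(np.where(p > 0.0, p, 1.0)), _LOG_ZERO)
    coef = gammaln(params.N + 1) - gammaln(counts + 1).sum(axis=1)  # (S,) per m
    # log P[m, j] = coef[m] + sum_i m_i log p_j,i
    return np.exp(coef[:, None] + counts.astype(float) @ logp.T)


def build_kernel(
    flux,
    params: LifecycleParams,
    lattice: CompositionLattice | None = None,
    state_cap: int = 100_000,
) -> LifecycleKernel:
    """Assemble ``K(m|j) = W(m) * Multinomial_N(m; p(j))``.

    ``flux`` is a :class:`FluxFunction` (or any callable mapping a
    counts matrix with omega column to a fitness vector).
    """
    if lattice is None:
        types = (
            flux.network.composition_types
            if isinstance(flux, FluxFunction)
            else None
        )
        lattice = enumerate_compositions(params.N, params.g, types=types, state_cap=state_cap)
    counts = lattice.counts  # (S, g+1)
    if isinstance(flux, FluxFunction):
        fitness = flux.on_counts(counts)
    else:
        fitness = np.asarray(flux(counts), dtype=float)
    if np.any(fitness < 0):
        raise ValueError("fitness must be nonnegative")

    matrix = fitness[:, None] * wright_fisher_matrix(params, lattice)
    return LifecycleKernel(lattice=lattice, matrix=matrix, fitness=fitness, params=params)


def stationary_distribution(
    kernel: LifecycleKernel,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    start: np.ndarray | None = None,
) -> PopulationDistribution:
    """Power iteration with L1 normalization.

    Converged when ``||K F - Wbar F||_1 <= tol * Wbar`` (relative
    residual; the kernel scale is the mean fitness itself).
    """
    K = kernel.matrix
    if not np.any(kernel.fitness > 0):
        raise DegenerateKernelError("all compositions have zero fitness")
    S = K.shape[0]
    F = np.full(S, 1.0 / S) if start is None else np.asarray(start, dtype=float) / np.sum(start)
    residual = np.inf
    for it in range(1, max_iter + 1):
        KF = K @ F
        wbar = KF.sum()
        if wbar <= 0:
            raise DegenerateKernelError("population flowed entirely into zero-fitness states")
        F_new = KF / wbar
        residual = np.abs(KF - wbar * F).sum() / wbar
        F = F_new
        if residual <= tol:
            return PopulationDistribution(
                lattice=kernel.lattice,
                frequencies=F,
                mean_fitness=float(wbar),
                n_iterations=it,
                residual=float(residual),
            )
    raise ConvergenceError(
        f"power iteration did not reach tol={tol} in {max_iter} iterations "
        f"(residual {residual:.3e})",
        residual=float(residual),
    )
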