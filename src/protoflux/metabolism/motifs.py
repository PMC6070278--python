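"""Steady-state flux through single reaction motifs.

Each motif relates the incoming substrate flux(es) to the reaction
velocity at the metabolite steady state.  In the vanishing-leak limit
(``delta -> 0``) the velocity is piecewise linear, ``min`` of the
incoming fluxes and the limiting velocity ``kcat * [E]``; at finite
leak it is the admissible root of a quadratic (unimolecular) or cubic
(bimolecular) whose implied substrate concentrations are nonnegative.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mm_velocity",
    "unimolecular_motif_flux",
    "unimolecular_motif_flux_finite_delta",
    "bimolecular_motif_flux",
    "bimolecular_motif_flux_finite_delta",
]


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")


def mm_velocity(enzyme_conc: float, substrate_conc: float, kcat: float, Km: float) -> float:
    """Michaelis-Menten velocity ``kcat [E] [S] / (Km + [S])``."""
    _check_nonneg(enzyme_conc=enzyme_conc, substrate_conc=substrate_conc, kcat=kcat)
    if Km <= 0:
        raise ValueError(f"Km must be > 0, got {Km}")
    return kcat * enzyme_conc * substrate_conc / (Km + substrate_conc)


def unimolecular_motif_flux(j_in: float, enzyme_count: float, kcat: float):
    """Piecewise-linear (zero-leak) unimolecular velocity ``min(j, kcat E)``."""
    if np.any(np.asarray(j_in) < 0) or np.any(np.asarray(enzyme_count) < 0):
        raise ValueError("fluxes and counts must be nonnegative")
    return np.minimum(j_in, kcat * np.asarray(enzyme_count, dtype=float))


def unimolecular_motif_flux_finite_delta(
    j_in: float, enzyme_count: float, kcat: float, Km: float, delta: float
) -> float:
    """Velocity at finite leak: root of
    ``(v - j)(v - kcat E) + delta Km v = 0``
    with nonnegative implied concentration ``[S] = (j - v)/delta``.

    The admissible root is the smaller one; it is strictly below
    ``min(j, kcat E)`` for ``delta > 0`` and continuous with the
    piecewise limit as ``delta -> 0``.
    """
    _check_nonneg(j_in=j_in, enzyme_count=enzyme_count, kcat=kcat)
    if delta <= 0:
        raise ValueError("delta must be > 0 (use unimolecular_motif_flux for delta=0)")
    vmax = kcat * enzyme_count
    b = j_in + vmax + delta * Km
    disc = b * b - 4.0 * j_in * vmax
    # disc = (j - vmax + dKm)^2 + 4 dKm vmax >= 0 always
    root = 2.0 * j_in * vmax / (b + np.sqrt(disc))  # stable form of the '-' root
    return float(root)


def bimolecular_motif_flux(j1: float, j2: float, enzyme_count: float, kcat: float):
    """Piecewise-linear bimolecular velocity ``min(j1, j2, kcat E)``."""
    if np.any(np.asarray(j1) < 0) or np.any(np.asarray(j2) < 0):
        raise ValueError("fluxes must be nonnegative")
    if np.any(np.asarray(enzyme_count) < 0):
        raise ValueError("counts must be nonnegative")
    return np.minimum(np.minimum(j1, j2), kcat * np.asarray(enzyme_count, dtype=float))


def bimolecular_motif_flux_finite_delta(
    j1: float,
    j2: float,
    enzyme_count: float,
    kcat: float,
    Km: float,
    a1: float,
    a2: float,
    delta: float,
) -> float:
    """Velocity at finite leak: admissible root of the cubic

    ``(v-j1)(v-j2)(v-kcat E) - (a1 v + a2 v - a1 j1 - a2 j2) v delta
    + Km v delta^2 = 0``

    selected so that both implied concentrations ``(j1-v)/delta`` and
    ``(j2-v)/delta`` are nonnegative; among admissible roots the
    smallest is taken (continuity with the ``delta -> 0`` limit).
    """
    _check_nonneg(j1=j1, j2=j2, enzyme_count=enzyme_count, kcat=kcat)
    if delta <= 0:
        raise ValueError("delta must be > 0 (use bimolecular_motif_flux for delta=0)")
    if j1 == 0.0 or j2 == 0.0 or enzyme_count == 0.0:
        return 0.0
    vmax = kcat * enzyme_count
    # expand (v-j1)(v-j2)(v-vmax) - delta*v*((a1+a2) v - a1 j1 - a2 j2) + Km delta^2 v
    c3 = 1.0
    c2 = -(j1 + j2 + vmax) - delta * (a1 + a2)
    c1 = j1 * j2 + j1 * vmax + j2 * vmax + delta * (a1 * j1 + a2 * j2) + Km * delta * delta
    c0 = -j1 * j2 * vmax
    roots = np.roots([c3, c2, c1, c0])
    jmin = min(j1, j2)
    tol = 1e-9 * max(1.0, jmin, vmax)
    admissible = sorted(
        r.real
        for r in roots
        if abs(r.imag) <= tol and -tol <= r.real <= jmin + tol
    )
    if not admissible:  # cannot occur for valid inputs
        raise RuntimeError(
            f"no admissible root for bimolecular motif (j1={j1}, j2={j2}, "
            f"E={enzyme_count}, kcat={kcat}, delta={delta}); roots={roots}"
        )
    return float(min(max(admissible[0], 0.0), jmin))
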