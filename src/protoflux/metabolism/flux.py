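"""Steady-state critical-metabolite flux of a whole network.

Because the networks are irreversible, feed-forward and non-competing,
the network flux is obtained by composing motif solutions in
topological order: the incoming flux of a recycler is the waste
stoichiometry of its upstream catalyst times the upstream velocity.

``compose_network_flux`` is the piecewise-linear (zero-leak) fitness
used by the evolutionary model; the finite-leak algebraic composition
and the brute-force ODE integration serve as numeric oracles.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp

from protoflux.compositions import Composition
from protoflux.metabolism.motifs import (
    bimolecular_motif_flux_finite_delta,
    unimolecular_motif_flux_finite_delta,
)
from protoflux.metabolism.network import (
    ENVIRONMENTAL_INPUT,
    INTERMEDIATE,
    CatalystSpec,
    NetworkSpec,
)

__all__ = [
    "compose_network_flux",
    "compose_network_flux_finite_delta",
    "ode_steady_state_flux",
    "FluxFunction",
]


def _counts_array(network: NetworkSpec, composition) -> np.ndarray:
    """Coerce a composition into a float array over the network's
    catalysts (batch dimension allowed; a trailing omega count is
    accepted and ignored)."""
    n_cat = network.n_catalysts
    if isinstance(composition, Composition):
        arr = np.asarray(composition.functional, dtype=float)
    elif isinstance(composition, dict):
        arr = np.array([float(composition.get(cid, 0)) for cid in network.catalyst_ids])
    else:
        arr = np.asarray(composition, dtype=float)
        if arr.shape[-1] == n_cat + 1:  # includes omega
            arr = arr[..., :n_cat]
    if arr.shape[-1] != n_cat:
        raise ValueError(
            f"composition has {arr.shape[-1]} catalyst counts, network expects {n_cat}"
        )
    if np.any(arr < 0):
        raise ValueError("catalyst counts must be nonnegative")
    return arr


def _incoming(network: NetworkSpec, cat: CatalystSpec, velocities: dict) -> list:
    """Incoming flux for each substrate (np.inf for environmental inputs)."""
    js = []
    for mid in cat.substrates:
        kind = network.metabolite(mid).kind
        if kind == ENVIRONMENTAL_INPUT:
            js.append(np.inf)
        else:
            producer = network.producer_of(mid)
            js.append(producer.products[mid] * velocities[producer.id])
    return js


def compose_network_flux(network: NetworkSpec, composition) -> float | np.ndarray:
    """Critical-metabolite output flux in the piecewise-linear limit.

    Saturated keystones run at ``kcat * count``; recyclers at the
    ``min`` of their incoming waste flux(es) and ``kcat * count``.
    Accepts a single composition or a batch (last axis = catalysts).
    """
    counts = _counts_array(network, composition)
    scalar = counts.ndim == 1
    velocities: dict[str, np.ndarray] = {}
    phi = np.zeros(counts.shape[:-1], dtype=float)
    order = {cid: i for i, cid in enumerate(network.catalyst_ids)}
    for cat in network.topological_order():
        n = counts[..., order[cat.id]]
        v = cat.kcat * n
        if not cat.saturated:
            for j in _incoming(network, cat, velocities):
                v = np.minimum(v, j)
        velocities[cat.id] = v
        cm = cat.products.get(network.critical_metabolite, 0.0)
        if cm:
            phi = phi + cm * v
    return float(phi) if scalar else phi


def compose_network_flux_finite_delta(
    network: NetworkSpec, composition, delta: float
) -> float:
    """Algebraic finite-leak network flux, composing the quadratic /
    cubic motif roots in topological order.

    Exact for non-competing feed-forward networks: each intermediate's
    steady-state balance is precisely its consumer's motif equation
    with incoming flux ``c_W * v_upstream``.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    counts = _counts_array(network, composition)
    if counts.ndim != 1:
        raise ValueError("finite-delta composition is scalar only")
    velocities: dict[str, float] = {}
    phi = 0.0
    order = {cid: i for i, cid in enumerate(network.catalyst_ids)}
    for cat in network.topological_order():
        n = float(counts[order[cat.id]])
        if cat.saturated:
            v = cat.kcat * n
        else:
            js = _incoming(network, cat, velocities)
            if any(np.isinf(j) for j in js):
                raise ValueError(
                    f"catalyst {cat.id}: unsaturated environmental consumption "
                    "has no finite-leak solution"
                )
            if cat.bimolecular:
                v = bimolecular_motif_flux_finite_delta(
                    js[0], js[1], n, cat.kcat, cat.Km, cat.a1, cat.a2, delta
                )
            else:
                v = unimolecular_motif_flux_finite_delta(js[0], n, cat.kcat, cat.Km, delta)
        velocities[cat.id] = v
        cm = cat.products.get(network.critical_metabolite, 0.0)
        phi += cm * v
    return float(phi)


# ---------------------------------------------------------------------------
# ODE oracle


def _velocity_at(network: NetworkSpec, cat: CatalystSpec, n: float, conc: dict) -> float:
    if cat.saturated:
        return cat.kcat * n
    subs = [conc[mid] for mid in cat.substrates]
    if cat.bimolecular:
        s1, s2 = subs
        return cat.kcat * n * s1 * s2 / (cat.Km + cat.a1 * s1 + cat.a2 * s2 + s1 * s2)
    (s,) = subs
    return cat.kcat * n * s / (cat.Km + s)


def network_rhs(
    network: NetworkSpec, counts: np.ndarray, delta: float | None = None
) -> tuple[list[str], callable, callable]:
    """Build the intermediate-concentration ODE right-hand side.

    Returns ``(intermediate_ids, rhs(t, y), phi(y))`` where ``phi``
    evaluates the instantaneous critical-output production rate.
    """
    inter_ids = [m.id for m in network.metabolites if m.kind == INTERMEDIATE]
    deltas = {
        m.id: (delta if delta is not None else m.permeability)
        for m in network.metabolites
        if m.kind == INTERMEDIATE
    }
    order = {cid: i for i, cid in enumerate(network.catalyst_ids)}
    n_by_cat = {cat.id: float(counts[order[cat.id]]) for cat in network.catalysts}

    def velocities(y: np.ndarray) -> dict[str, float]:
        conc = dict(zip(inter_ids, np.maximum(y, 0.0)))
        return {
            cat.id: _velocity_at(network, cat, n_by_cat[cat.id], conc)
            for cat in network.catalysts
        }

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v = velocities(y)
        dy = np.empty_like(y)
        for i, mid in enumerate(inter_ids):
            prod = 0.0
            producer = network.producer_of(mid)
            if producer is not None:
                prod = producer.products[mid] * v[producer.id]
            cons = sum(v[c.id] for c in network.catalysts if mid in c.substrates)
            dy[i] = prod - deltas[mid] * max(y[i], 0.0) - cons
        return dy

    def phi(y: np.ndarray) -> float:
        v = velocities(y)
        crit = network.critical_metabolite
        return sum(cat.products.get(crit, 0.0) * v[cat.id] for cat in network.catalysts)

    return inter_ids, rhs, phi


def ode_steady_state_flux(
    network: NetworkSpec,
    composition,
    delta: float,
    rtol: float = 1e-10,
    max_time: float = 1e8,
) -> float:
    """Integrate the intermediate mass-action/Michaelis-Menten ODEs to
    stationarity and return the critical-output production rate.

    Catalyst concentrations are identified with counts.  Agrees with
    :func:`compose_network_flux` to ``O(delta)`` away from the
    piecewise-linear kinks.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    counts = _counts_array(network, composition)
    inter_ids, rhs, phi = network_rhs(network, counts, delta)
    if not inter_ids:
        return float(phi(np.zeros(0)))
    y = np.zeros(len(inter_ids))
    t_char = 1.0 / delta  # leak sets the slowest relaxation scale
    t_end = t_char
    prev = None
    while t_end <= max_time:
        sol = solve_ivp(rhs, (0.0, t_end), y, method="BDF", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        y_new = sol.y[:, -1]
        if prev is not None:
            scale = np.maximum(np.abs(y_new), 1e-30)
            if np.max(np.abs(y_new - prev) / scale) < rtol:
                return float(phi(y_new))
        prev = y_new
        y = y_new
        t_end *= 4.0
    raise RuntimeError(
        f"ODE steady state not reached within t={max_time} "
        f"(last concentrations {dict(zip(inter_ids, y))})"
    )


# ---------------------------------------------------------------------------


class FluxFunction:
    """Map compositions to critical-metabolite flux (protocell fitness).

    Parameters
    ----------
    network
        The reaction network.
    mode
        ``"piecewise_delta0"`` (default, the zero-leak fitness) or
        ``"finite_delta_ode"`` (numeric oracle; requires ``delta``).
    delta
        Membrane permeability for the finite-leak mode.
    """

    MODES = ("piecewise_delta0", "finite_delta_ode")

    def __init__(self, network: NetworkSpec, mode: str = "piecewise_delta0", delta: float | None = None):
        if mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        if mode == "finite_delta_ode" and (delta is None or delta <= 0):
            raise ValueError("finite_delta_ode mode requires delta > 0")
        self.network = network
        self.mode = mode
        self.delta = delta

    def __call__(self, composition) -> float | np.ndarray:
        if self.mode == "piecewise_delta0":
            return compose_network_flux(self.network, composition)
        counts = _counts_array(self.network, composition)
        if counts.ndim == 1:
            return ode_steady_state_flux(self.network, counts, self.delta)
        return np.array([ode_steady_state_flux(self.network, c, self.delta) for c in counts])

    def on_counts(self, counts_matrix: np.ndarray) -> np.ndarray:
        """Vectorized piecewise evaluation over rows of a counts matrix
        (omega column, if present, is ignored)."""
        if self.mode != "piecewise_delta0":
            raise ValueError("batch evaluation is only supported in piecewise mode")
        return np.atleast_1d(compose_network_flux(self.network, counts_matrix))

    def __repr__(self) -> str:  # pragma: no cover
        return f"FluxFunction({self.network.name!r}, mode={self.mode!r})"
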