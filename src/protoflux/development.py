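"""Within-protocell development ODEs (validation oracle only).

Sequences replicate at rate ``r * [M]`` while the metabolic network
runs; this module verifies the two analytic facts that justify the
evolutionary model's time-scale separation: the type-ratio ``x`` is a
constant of motion, and after the metabolite transient the total
sequence concentration grows exponentially at the scaled flux
``phi = Phi / total``.  The evolutionary model itself never calls this
module — development there is replaced by the 2N-sampling scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from protoflux.metabolism.flux import _counts_array, network_rhs
from protoflux.metabolism.network import INTERMEDIATE, NetworkSpec

__all__ = ["DevelopmentTrajectory", "simulate_development"]


@dataclass
class DevelopmentTrajectory:
    """Time series of sequence and metabolite concentrations."""

    times: np.ndarray
    sequences: np.ndarray  # (T, n_catalysts)
    intermediates: np.ndarray  # (T, n_intermediates)
    metabolite: np.ndarray  # (T,) critical metabolite concentration
    fractions: np.ndarray  # (T, n_catalysts) x_i = seq_i / total
    phi: np.ndarray  # (T,) instantaneous Phi / total
    intermediate_ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "M": self.metabolite, "phi": self.phi}
        for i in range(self.sequences.shape[1]):
            cols[f"seq{i}"] = self.sequences[:, i]
            cols[f"x{i}"] = self.fractions[:, i]
        for i, mid in enumerate(self.intermediate_ids):
            cols[str(mid)] = self.intermediates[:, i]
        return pd.DataFrame(cols)

    def growth_rate(self, tail: float = 0.25) -> float:
        """Asymptotic ``d log(total)/dt`` from a linear fit over the
        last ``tail`` fraction of the trajectory."""
        total = self.sequences.sum(axis=1)
        n = len(self.times)
        sl = slice(max(int((1 - tail) * n), 1), n)
        return float(np.polyfit(self.times[sl], np.log(total[sl]), 1)[0])


def simulate_development(
    network: NetworkSpec,
    initial_sequences,
    r: float,
    t_end: float,
    delta: float = 1e-2,
    initial_metabolite: float = 0.0,
    rtol: float = 1e-9,
    n_points: int = 400,
) -> DevelopmentTrajectory:
    """Integrate the coupled metabolism + replication system.

    State: catalyst concentrations (replicating at rate ``r*[M]``), the
    intermediate concentrations, and the critical metabolite ``[M]``
    (produced at the network rate, depleted at ``r*[M]*total``).
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    seq0 = _counts_array(network, initial_sequences).astype(float)
    n_cat = network.n_catalysts
    inter_ids = [m.id for m in network.metabolites if m.kind == INTERMEDIATE]
    n_int = len(inter_ids)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        seqs = y[:n_cat]
        inters = y[n_cat : n_cat + n_int]
        M = y[-1]
        _, met_rhs, phi_fn = network_rhs(network, seqs, delta)
        dseq = r * M * seqs
        dint = met_rhs(t, inters)
        dM = phi_fn(inters) - r * M * seqs.sum()
        return np.concatenate([dseq, dint, [dM]])

    y0 = np.concatenate([seq0, np.zeros(n_int), [initial_metabolite]])
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"development integration failed: {sol.message}")

    seqs = sol.y[:n_cat].T
    inters = sol.y[n_cat : n_cat + n_int].T
    M = sol.y[-1]
    totals = seqs.sum(axis=1)
    fractions = seqs / totals[:, None]
    phi = np.empty(len(sol.t))
    for i in range(len(sol.t)):
        _, _, phi_fn = network_rhs(network, seqs[i], delta)
        phi[i] = phi_fn(inters[i]) / totals[i]
    return DevelopmentTrajectory(
        times=sol.t,
        sequences=seqs,
        intermediates=inters,
        metabolite=M,
        fractions=fractions,
        phi=phi,
        intermediate_ids=inter_ids,
    )
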