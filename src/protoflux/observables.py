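"""Population summary statistics and parameter scans.

All observables accept either an exact :class:`PopulationDistribution`
or a finite agent population given as an integer counts matrix of
shape ``(P, g+1)`` (omega last).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from protoflux.lifecycle import LifecycleParams
from protoflux.metabolism.fixtures import get_fixture
from protoflux.metabolism.flux import FluxFunction
from protoflux.metabolism.network import NetworkSpec
from protoflux.population.abm import ABMResult, run_agent_based
from protoflux.population.kernel import PopulationDistribution, build_kernel, stationary_distribution

__all__ = [
    "coexistence_fraction",
    "mean_flux",
    "defective_frequency",
    "ternary_projection",
    "plot_ternary",
    "scan",
    "distribution_frame",
]


def _counts_and_weights(dist) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dist, PopulationDistribution):
        return dist.lattice.counts, dist.frequencies
    if isinstance(dist, ABMResult):
        dist = dist.final_population
    counts = np.asarray(dist, dtype=np.int64)
    if counts.ndim != 2:
        raise TypeError("expected a PopulationDistribution or a (P, g+1) counts matrix")
    return counts, np.full(counts.shape[0], 1.0 / counts.shape[0])


def coexistence_fraction(dist, g: int | None = None, min_copies: int = 1) -> float:
    """Fraction of the population carrying at least ``min_copies`` of
    every functional type (omega irrelevant)."""
    counts, weights = _counts_and_weights(dist)
    if g is None:
        g = counts.shape[1] - 1
    ok = np.all(counts[:, :g] >= min_copies, axis=1)
    return float(weights[ok].sum())


def mean_flux(dist, flux: FluxFunction) -> float:
    """Expectation of the flux under the distribution; for the exact
    solver this equals the leading eigenvalue (mean fitness)."""
    counts, weights = _counts_and_weights(dist)
    values = flux.on_counts(counts) if isinstance(flux, FluxFunction) else np.asarray(flux(counts))
    return float(np.dot(weights, values))


def defective_frequency(dist) -> float:
    """Expected omega fraction ``E[m_omega] / N``."""
    counts, weights = _counts_and_weights(dist)
    totals = counts.sum(axis=1)
    return float(np.dot(weights, counts[:, -1] / totals))


def ternary_projection(dist, axes: Sequence[int] = (0, 1, 2)) -> pd.DataFrame:
    """Project a distribution onto three type-axes for simplex plots.

    Each composition yields the frequencies of the three selected types
    renormalized among themselves, with the distribution mass as
    weight.  Compositions with all three selected counts zero get
    ``defined=False`` and NaN coordinates (excluded from plots); the
    plotted mass deficit equals their total weight.
    """
    if len(axes) != 3:
        raise ValueError("exactly three axes required")
    counts, weights = _counts_and_weights(dist)
    sel = counts[:, list(axes)].astype(float)
    totals = sel.sum(axis=1)
    defined = totals > 0
    coords = np.full_like(sel, np.nan)
    coords[defined] = sel[defined] / totals[defined, None]
    return pd.DataFrame(
        {
            "f1": coords[:, 0],
            "f2": coords[:, 1],
            "f3": coords[:, 2],
            "weight": weights,
            "defined": defined,
        }
    )


def plot_ternary(df: pd.DataFrame, path: str | Path, title: str | None = None) -> None:
    """Render a ternary projection table (columns f1, f2, f3, weight,
    defined) as a simplex scatter plot (SVG/PNG by file extension).

    Requires matplotlib; undefined-coordinate rows are excluded.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[df["defined"]]
    # barycentric -> cartesian: x = f2 + f3/2, y = f3 * sqrt(3)/2
    x = sub["f2"] + 0.5 * sub["f3"]
    y = sub["f3"] * np.sqrt(3) / 2
    fig, ax = plt.subplots(figsize=(5, 4.6))
    ax.plot([0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0], color="0.3", lw=1)
    sc = ax.scatter(x, y, c=sub["weight"], s=12, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="frequency")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def distribution_frame(dist: PopulationDistribution, flux: FluxFunction | None = None) -> pd.DataFrame:
    """Tidy table of a stationary distribution (one row per composition)."""
    lattice = dist.lattice
    data = {"index": np.arange(lattice.size)}
    for t, name in enumerate(lattice.types):
        data[str(name)] = lattice.counts[:, t]
    data["frequency"] = dist.frequencies
    if flux is not None:
        data["flux"] = flux.on_counts(lattice.counts)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# scans


def _cache_key(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:24]


def scan(
    network: str | NetworkSpec,
    N_values: Iterable[int],
    q_values: Iterable[float] = (1.0,),
    solver: str = "exact",
    pop_size: int = 1000,
    generations: int = 5000,
    replicates: int = 1,
    seed: int = 0,
    min_copies: int = 1,
    window: float = 0.1,
    state_cap: int = 100_000,
    tol: float = 1e-10,
    cache_dir: str | Path | None = None,
    fixture_kwargs: dict | None = None,
    selection: str = "without_replacement",
) -> pd.DataFrame:
    """Scan observables over a grid of ploidy and replication accuracy.

    One row per grid point (per replicate for the agent-based solver);
    deterministic iteration order, per-point seeds derived from the
    master ``seed`` via ``SeedSequence`` spawning.  Per-point failures
    are recorded (``status`` column) and the scan continues.
    """
    if solver not in ("exact", "abm", "both"):
        raise ValueError("solver must be 'exact', 'abm' or 'both'")
    if isinstance(network, str):
        net = get_fixture(network, **(fixture_kwargs or {}))
    else:
        net = network
    flux = FluxFunction(net)
    g = net.n_catalysts
    solvers = ["exact", "abm"] if solver == "both" else [solver]
    cache_path = Path(cache_dir) if cache_dir is not None else None
    if cache_path is not None:
        cache_path.mkdir(parents=True, exist_ok=True)

    rows = []
    point_index = 0
    for N in N_values:
        for q in q_values:
            params = LifecycleParams(N=int(N), q=float(q), g=g)
            for sv in solvers:
                n_reps = replicates if sv == "abm" else 1
                for rep in range(n_reps):
                    point_index += 1
                    rep_seed = np.random.SeedSequence(
                        entropy=seed, spawn_key=(point_index,)
                    )
                    key_payload = {
                        "network": net.name,
                        "fixture_kwargs": fixture_kwargs or {},
                        "N": int(N),
                        "q": float(q),
                        "solver": sv,
                        "replicate": rep,
                        "seed": seed,
                        "pop_size": pop_size if sv == "abm" else None,
                        "generations": generations if sv == "abm" else None,
                        "min_copies": min_copies,
                        "selection": selection if sv == "abm" else None,
                    }
                    row = {
                        "network": net.name,
                        "solver": sv,
                        "N": int(N),
                        "q": float(q),
                        "replicate": rep,
                        "status": "ok",
                        "coexistence_fraction": np.nan,
                        "mean_flux": np.nan,
                        "defective_frequency": np.nan,
                    }
                    if cache_path is not None:
                        f = cache_path / f"{_cache_key(key_payload)}.json"
                        if f.exists():
                            rows.append(json.loads(f.read_text()))
                            continue
                    try:
                        if sv == "exact":
                            kernel = build_kernel(flux, params, state_cap=state_cap)
                            dist = stationary_distribution(kernel, tol=tol)
                            row["coexistence_fraction"] = coexistence_fraction(
                                dist, g=g, min_copies=min_copies
                            )
                            row["mean_flux"] = mean_flux(dist, flux)
                            row["defective_frequency"] = defective_frequency(dist)
                        else:
                            result = run_agent_based(
                                flux,
                                params,
                                pop_size=pop_size,
                                generations=generations,
                                rng=np.random.default_rng(rep_seed),
                                selection=selection,
                            )
                            obs = result.stationary_observables(window=window)
                            row.update(obs)
                            row["status"] = result.status
                    except Exception as exc:  # record and continue
                        row["status"] = f"error: {exc}"
                    if cache_path is not None and not row["status"].startswith("error"):
                        (cache_path / f"{_cache_key(key_payload)}.json").write_text(
                            json.dumps(row)
                        )
                    rows.append(row)
    return pd.DataFrame(rows)
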