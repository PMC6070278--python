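# protoflux

Evolutionary dynamics of metabolic protocells: vesicles encapsulating `N`
catalytic sequences whose fitness is the steady-state output flux of a small
irreversible Michaelis–Menten reaction network, evolving under a
Wright–Fisher life-cycle with replication errors (an irreversible defective
type `omega`) and random assortment of the doubled contents at fission.

## What is implemented

- **metabolism** — reaction-network specification and validation
  (feed-forward, non-competing, saturated keystone catalysts), the
  piecewise-linear zero-leak flux `Φ` used as fitness (`min`-composition of
  motif velocities in topological order), the finite-leak quadratic/cubic
  motif roots, and a brute-force ODE steady-state oracle. Seven built-in
  fixtures: `keystone_recycler` (+ `_near`/`_far` boundary variants),
  `serial3`, `parallel3`, `bimolecular3`, `serial4`, `parallel4`,
  `bimolecular4`; networks are also readable/writable as YAML/JSON.
- **lifecycle** — exact development (multinomial over `2N` samplings with
  replacement, mutation to `omega`), assortment (multivariate hypergeometric
  split), the Wright–Fisher daughter marginal, and seeded samplers.
- **population** — the exact infinite-population solver (life-cycle kernel
  `K(m|j) = Φ(m)·P(m|j)` + Perron–Frobenius power iteration) and a fully
  vectorized agent-based simulator (`P` protocells double, then half survive
  with probability proportional to flux). Two selection schemes are provided:
  the described successive draws without replacement (default) and
  multinomial with-replacement selection; only the latter converges exactly
  to the eigen-solver limit (the without-replacement scheme has saturating
  inclusion probabilities and keeps a small systematic offset — see
  `tests/test_acceptance.py`).
- **development** — validation-only ODE model of within-protocell growth
  (type-ratio conservation, exponential growth at the scaled flux).
- **observables** — coexistence fraction, mean flux, defective-type
  frequency, ternary simplex projections, and resumable parameter scans.
- **cli** — `protoflux fixtures` and `protoflux run` (TSV observables,
  stationary-distribution dumps, JSON log/config provenance).

## Usage

```sh
# list built-in networks with their default parameters
protoflux fixtures
protoflux fixtures --json

# exact-solver coexistence scan over ploidy (Fig-1C-style table)
protoflux run --fixture keystone_recycler_far --N 10:100:10 --q 1.0 \
    --solver exact --out out_far

# paired exact/agent-based run with a parameter override
protoflux run --fixture parallel4 --set cm_theta=10 --N 100 \
    --solver both -P 1000 -G 5000 --seed 1 --out out_p4
```

Python API sketch:

```python
from protoflux import (LifecycleParams, FluxFunction, get_fixture,
                       build_kernel, stationary_distribution,
                       run_agent_based, coexistence_fraction)

flux = FluxFunction(get_fixture("keystone_recycler_far"))
params = LifecycleParams(N=30, q=0.99, g=2)
dist = stationary_distribution(build_kernel(flux, params))
print(dist.mean_fitness, coexistence_fraction(dist))

res = run_agent_based(flux, params, pop_size=1000, generations=5000, rng=1)
print(res.stationary_observables())
```

## Conventions

- Catalyst concentration = copy number (no volume/dilution factor).
- Environmental inputs are plentiful and constant; keystones run at their
  limiting velocity `kcat·[E]`.
- `Km`, `a1`, `a2` matter only at finite membrane permeability `delta`
  (defaults 1.0); they drop out of the piecewise-linear fitness.
- Compositions are integer vectors ordered as network catalysts followed by
  `omega`; exact solvers enumerate the full lattice (capped at 1e5 states —
  beyond that, use the agent-based solver).
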