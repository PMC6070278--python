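"""Observables over exact distributions and agent populations."""

import numpy as np
import pytest
import scipy.linalg

from protoflux.compositions import enumerate_compositions
from protoflux.lifecycle import LifecycleParams
from protoflux.metabolism import FluxFunction, get_fixture
from protoflux.observables import (
    coexistence_fraction,
    defective_frequency,
    distribution_frame,
    mean_flux,
    scan,
    ternary_projection,
)
from protoflux.population import build_kernel, stationary_distribution
from protoflux.population.kernel import PopulationDistribution


def _point_mass(counts, N, g):
    lat = enumerate_compositions(N, g)
    F = np.zeros(lat.size)
    F[lat.index_of(counts)] = 1.0
    return PopulationDistribution(lattice=lat, frequencies=F, mean_fitness=0.0)


class TestCoexistence:
    def test_point_mass_boundary(self):
        assert coexistence_fraction(_point_mass((5, 0, 0), 5, 2)) == 0.0

    def test_omega_does_not_disqualify(self):
        assert coexistence_fraction(_point_mass((1, 1, 3), 5, 2)) == 1.0

    def test_uniform_small_lattice(self):
        lat = enumerate_compositions(2, 2)
        F = np.full(lat.size, 1 / lat.size)
        dist = PopulationDistribution(lattice=lat, frequencies=F, mean_fitness=0.0)
        assert coexistence_fraction(dist) == pytest.approx(1 / 6)

    def test_agent_matrix_input(self):
        pop = np.array([[1, 1, 0], [2, 0, 0], [1, 1, 0], [0, 2, 0]])
        assert coexistence_fraction(pop) == pytest.approx(0.5)

    def test_min_copies_threshold(self):
        dist = _point_mass((1, 1, 3), 5, 2)
        assert coexistence_fraction(dist, min_copies=2) == 0.0

    def test_relabeling_invariance(self):
        pop = np.array([[3, 1, 2, 0], [1, 0, 5, 0]])
        swapped = pop[:, [0, 2, 1, 3]]
        assert coexistence_fraction(pop) == coexistence_fraction(swapped)


class TestMeanFluxAndDefective:
    def test_point_mass_flux(self):
        flux = FluxFunction(get_fixture("keystone_recycler"))
        assert mean_flux(_point_mass((3, 4, 0), 7, 2), flux) == 9.0  # 3 + 2*min(3, 4)

    def test_neutral_constant(self):
        dist = _point_mass((2, 2, 1), 5, 2)
        assert mean_flux(dist, lambda c: np.full(c.shape[0], 7.0)) == 7.0

    def test_defective_point_masses(self):
        assert defective_frequency(_point_mass((0, 0, 5), 5, 2)) == 1.0
        assert defective_frequency(_point_mass((3, 2, 0), 5, 2)) == 0.0

    def test_defective_two_state_chain(self):
        # N=1, g=1, neutral fitness, q<1: 2x2 chain with leading
        # eigenvector on the all-omega state
        q = 0.8
        params = LifecycleParams(N=1, q=q, g=1)
        neutral = lambda c: np.ones(c.shape[0])
        kernel = build_kernel(neutral, params)
        np.testing.assert_allclose(
            kernel.matrix, np.array([[q, 0.0], [1 - q, 1.0]]), atol=1e-12
        )
        vals, vecs = scipy.linalg.eig(kernel.matrix)
        lead = np.abs(vecs[:, np.argmax(vals.real)].real)
        lead /= lead.sum()
        dist = stationary_distribution(kernel, tol=1e-12)
        assert defective_frequency(dist) == pytest.approx(lead[1], abs=1e-9)
        assert defective_frequency(dist) == pytest.approx(1.0, abs=1e-9)

    def test_error_free_start_stays_functional(self):
        flux = FluxFunction(get_fixture("keystone_recycler_far"))
        params = LifecycleParams(N=10, q=1.0, g=2)
        dist = stationary_distribution(build_kernel(flux, params), tol=1e-12)
        assert defective_frequency(dist) == pytest.approx(0.0, abs=1e-9)


class TestTernary:
    def test_examples(self):
        pop = np.array([[1, 1, 1, 0], [2, 0, 0, 0], [0, 0, 0, 3]])
        df = ternary_projection(pop, axes=(0, 1, 2))
        np.testing.assert_allclose(df.loc[0, ["f1", "f2", "f3"]].astype(float), [1 / 3] * 3)
        np.testing.assert_allclose(df.loc[1, ["f1", "f2", "f3"]].astype(float), [1, 0, 0])
        assert not df.loc[2, "defined"]
        defined_mass = df.loc[df["defined"], "weight"].sum()
        assert defined_mass == pytest.approx(1.0 - df.loc[~df["defined"], "weight"].sum())

    def test_axis_count_validated(self):
        with pytest.raises(ValueError):
            ternary_projection(np.array([[1, 1, 0]]), axes=(0, 1))

    def test_plot_smoke(self, tmp_path):
        from protoflux.observables import plot_ternary

        pop = np.array([[1, 1, 1, 0], [2, 0, 1, 0], [0, 0, 0, 3]])
        df = ternary_projection(pop)
        out = tmp_path / "ternary.svg"
        plot_ternary(df, out, title="smoke")
        assert out.stat().st_size > 0


class TestSymmetry:
    def test_parallel3_beta_gamma_symmetric_stationary(self):
        flux = FluxFunction(get_fixture("parallel3"))
        params = LifecycleParams(N=9, q=1.0, g=3)
        dist = stationary_distribution(build_kernel(flux, params), tol=1e-12)
        lat = dist.lattice
        for idx in range(lat.size):
            a, b, c, w = lat.counts[idx]
            sw = lat.index_of((a, c, b, w))
            assert dist.frequencies[idx] == pytest.approx(dist.frequencies[sw], abs=1e-9)


class TestScan:
    def test_single_point_matches_direct_run(self):
        df = scan("keystone_recycler_far", N_values=[8], q_values=[1.0], solver="exact")
        assert len(df) == 1
        flux = FluxFunction(get_fixture("keystone_recycler_far"))
        dist = stationary_distribution(
            build_kernel(flux, LifecycleParams(N=8, q=1.0, g=2)), tol=1e-10
        )
        assert df.loc[0, "coexistence_fraction"] == pytest.approx(coexistence_fraction(dist))

    def test_exact_scan_seed_independent(self):
        a = scan("keystone_recycler", N_values=[5, 10], solver="exact", seed=1)
        b = scan("keystone_recycler", N_values=[5, 10], solver="exact", seed=99)
        assert np.allclose(
            a["coexistence_fraction"].to_numpy(), b["coexistence_fraction"].to_numpy()
        )

    def test_abm_scan_reproducible(self):
        kwargs = dict(
            N_values=[6],
            solver="abm",
            pop_size=40,
            generations=50,
            replicates=2,
            seed=5,
        )
        a = scan("keystone_recycler_far", **kwargs)
        b = scan("keystone_recycler_far", **kwargs)
        assert a.equals(b)
        assert len(a) == 2

    def test_cache_round_trip(self, tmp_path):
        kwargs = dict(
            N_values=[6], solver="abm", pop_size=40, generations=50, seed=5,
            cache_dir=tmp_path,
        )
        a = scan("keystone_recycler_far", **kwargs)
        assert len(list(tmp_path.glob("*.json"))) == 1
        b = scan("keystone_recycler_far", **kwargs)
        assert a.equals(b)

    def test_failed_point_recorded_and_scan_continues(self):
        df = scan("keystone_recycler", N_values=[4, 2000], solver="exact", state_cap=100)
        assert df.loc[0, "status"] == "ok"
        assert df.loc[1, "status"].startswith("error")

    def test_distribution_frame_schema(self):
        flux = FluxFunction(get_fixture("keystone_recycler"))
        dist = stationary_distribution(
            build_kernel(flux, LifecycleParams(N=4, q=1.0, g=2)), tol=1e-10
        )
        frame = distribution_frame(dist, flux)
        assert list(frame.columns) == ["index", "alpha", "beta", "omega", "frequency", "flux"]
        assert frame["frequency"].sum() == pytest.approx(1.0)
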