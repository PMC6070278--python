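"""Life-cycle distributions: development, assortment, daughter marginal,
and the sampler, checked by brute-force enumeration at small sizes."""

import itertools
from math import comb

import numpy as np
import pytest

from protoflux.compositions import enumerate_compositions
from protoflux.lifecycle import (
    LifecycleParams,
    assortment_distribution,
    development_distribution,
    draw_probabilities,
    lifecycle_offspring_marginal,
    sample_lifecycle,
)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            LifecycleParams(N=0, q=1.0, g=1)
        with pytest.raises(ValueError):
            LifecycleParams(N=2, q=1.5, g=1)

    def test_accuracy_from_mutation_rate(self):
        p = LifecycleParams.from_mutation_rate(N=10, mu=0.01, L=50, g=2)
        assert p.q == pytest.approx(0.99**50)


class TestDevelopment:
    def test_error_free_pure_protocell(self):
        params = LifecycleParams(N=3, q=1.0, g=1)
        lat, probs = development_distribution([3, 0], params)
        assert probs[lat.index_of((6, 0))] == pytest.approx(1.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_accuracy_all_omega(self):
        params = LifecycleParams(N=3, q=0.0, g=2)
        lat, probs = development_distribution([1, 2, 0], params)
        assert probs[lat.index_of((0, 0, 6))] == pytest.approx(1.0)

    def test_direct_multinomial_value(self):
        # N=2, g=1, q=0.5, j=(2,0): per-draw p_alpha = 0.5, P(k_alpha=4) = 0.5^4
        params = LifecycleParams(N=2, q=0.5, g=1)
        lat, probs = development_distribution([2, 0], params)
        assert probs[lat.index_of((4, 0))] == pytest.approx(0.0625, abs=1e-15)

    @pytest.mark.parametrize("N,g,q", list(itertools.product([1, 2, 4], [1, 2], [0.0, 0.3, 1.0])))
    def test_normalization(self, N, g, q):
        params = LifecycleParams(N=N, q=q, g=g)
        j = np.zeros(g + 1, dtype=int)
        j[0] = N - N // 2
        j[-1] = N // 2
        _, probs = development_distribution(j, params)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_wrong_total_rejected(self):
        params = LifecycleParams(N=3, q=1.0, g=1)
        with pytest.raises(ValueError, match="sum to N"):
            development_distribution([2, 0], params)


class TestAssortment:
    def test_pure_protocell(self):
        lat, probs = assortment_distribution([6, 0])
        assert probs[lat.index_of((3, 0))] == pytest.approx(1.0)

    def test_single_copy_splits_evenly(self):
        # k = (1, 2N-1): the lone alpha ends in either daughter w.p. 1/2
        lat, probs = assortment_distribution([1, 7, 0])
        with_alpha = sum(
            p for comp, p in zip(lat.counts, probs) if comp[0] == 1
        )
        assert with_alpha == pytest.approx(0.5)

    def test_enumerated_split(self):
        # k=(2,2), N=2: P(m=(1,1)) = C(2,1)C(2,1)/C(4,2) = 4/6
        lat, probs = assortment_distribution([2, 2])
        assert probs[lat.index_of((1, 1))] == pytest.approx(4 / 6)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_enumeration_oracle(self):
        # enumerate all C(2N, N) labelled splits of k = (2, 1, 1)
        k = np.array([2, 1, 1])
        labels = [0, 0, 1, 2]
        from itertools import combinations

        counts = {}
        for picked in combinations(range(4), 2):
            m = tuple(np.bincount([labels[i] for i in picked], minlength=3))
            counts[m] = counts.get(m, 0) + 1
        lat, probs = assortment_distribution(k)
        for m, c in counts.items():
            assert probs[lat.index_of(m)] == pytest.approx(c / comb(4, 2))

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError, match="even"):
            assortment_distribution([3, 0])


def _compose_marginal(j, params):
    """Brute-force daughter marginal: sum over development outcomes k of
    P_dev(k|j) * P_asst(m|k)."""
    lat2, pdev = development_distribution(j, params)
    latN = enumerate_compositions(params.N, params.g)
    marg = np.zeros(latN.size)
    for k, pk in zip(lat2.counts, pdev):
        if pk == 0.0:
            continue
        _, pas = assortment_distribution(k)
        marg += pk * pas
    return latN, marg


class TestOffspringMarginal:
    @pytest.mark.parametrize(
        "N,g,q,j",
        [
            (2, 1, 0.7, (1, 1)),
            (3, 2, 0.9, (2, 1, 0)),
            (4, 2, 0.5, (1, 2, 1)),
            (4, 1, 1.0, (3, 1)),
        ],
    )
    def test_equals_brute_force_composition(self, N, g, q, j):
        params = LifecycleParams(N=N, q=q, g=g)
        latN, want = _compose_marginal(np.array(j), params)
        lat, got = lifecycle_offspring_marginal(np.array(j), params)
        assert np.array_equal(lat.counts, latN.counts)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_error_free_point_mass(self):
        params = LifecycleParams(N=4, q=1.0, g=1)
        lat, probs = lifecycle_offspring_marginal([4, 0], params)
        assert probs[lat.index_of((4, 0))] == pytest.approx(1.0)

    def test_single_draw(self):
        params = LifecycleParams(N=1, q=0.8, g=1)
        lat, probs = lifecycle_offspring_marginal([1, 0], params)
        assert probs[lat.index_of((1, 0))] == pytest.approx(0.8)

    def test_expected_daughter_counts(self):
        # E[m_i] = q * j_i for functional types, exactly
        params = LifecycleParams(N=5, q=0.77, g=2)
        j = np.array([2, 3, 0])
        lat, probs = lifecycle_offspring_marginal(j, params)
        mean = probs @ lat.counts
        np.testing.assert_allclose(mean[:2], params.q * j[:2], atol=1e-12)

    def test_omega_absorbing(self):
        params = LifecycleParams(N=3, q=0.6, g=2)
        lat, probs = lifecycle_offspring_marginal([0, 0, 3], params)
        assert probs[lat.index_of((0, 0, 3))] == pytest.approx(1.0)

    def test_joint_factorizes_into_two_multinomials(self):
        # P_life(m, m'|j) = P_dev(m+m'|j) P_asst(m|m+m') must equal the
        # product of two independent N-draw multinomials
        params = LifecycleParams(N=3, q=0.7, g=2)
        j = np.array([2, 1, 0])
        lat2, pdev = development_distribution(j, params)
        latN, pmarg = lifecycle_offspring_marginal(j, params)
        for k, pk in zip(lat2.counts, pdev):
            lat_m, pas = assortment_distribution(k)
            for m, pm in zip(lat_m.counts, pas):
                if pm == 0.0 and np.any(m > k):
                    continue  # infeasible split enumerated with zero mass
                m2 = k - m
                joint = pk * pm
                product = pmarg[latN.index_of(m)] * pmarg[latN.index_of(tuple(m2))]
                assert joint == pytest.approx(product, abs=1e-12)


class TestSampler:
    def test_conservation_and_reproducibility(self):
        params = LifecycleParams(N=5, q=0.8, g=2)
        j = np.array([2, 2, 1])
        d1 = sample_lifecycle(j, params, np.random.default_rng(42))
        d2 = sample_lifecycle(j, params, np.random.default_rng(42))
        assert np.array_equal(d1[0], d2[0]) and np.array_equal(d1[1], d2[1])
        m1, m2 = d1
        assert m1.sum() == m2.sum() == 5
        assert np.all(m1 >= 0) and np.all(m2 >= 0)

    def test_empirical_marginal_matches_exact(self):
        params = LifecycleParams(N=3, q=0.9, g=2)
        j = np.array([2, 1, 0])
        lat, exact = lifecycle_offspring_marginal(j, params)
        rng = np.random.default_rng(7)
        n = 100_000
        freq = np.zeros(lat.size)
        for _ in range(n):
            m1, m2 = sample_lifecycle(j, params, rng)
            freq[lat.index_of(tuple(m1))] += 1
            freq[lat.index_of(tuple(m2))] += 1
        freq /= 2 * n
        # daughters of one cycle are correlated; use the conservative
        # n-sample sigma rather than 2n
        sigma = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freq - exact) <= 5 * sigma + 1e-9)

    def test_draw_probabilities_sum_to_one(self):
        params = LifecycleParams(N=4, q=0.85, g=2)
        p = draw_probabilities(np.array([[2, 1, 1], [0, 0, 4]]), params)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-15)
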