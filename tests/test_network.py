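import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from gapcpg.network import (GapNetwork, random_coupling, planar_coupling,
                            gap_currents, lattice_positions)


class TestRandomCoupling:
    def test_degenerate_probabilities(self):
        assert random_coupling(100, 0.0, seed=0).n_edges == 0
        assert random_coupling(100, 1.0, seed=0).n_edges == 4950

    def test_edge_count_in_binomial_band(self):
        # 100 seeds at C = 0.25: counts inside the exact 99.9% interval
        lo, hi = binom.ppf([0.0005, 0.9995], 4950, 0.25)
        counts = [random_coupling(100, 0.25, seed=s).n_edges
                  for s in range(100)]
        assert min(counts) >= lo and max(counts) <= hi

    def test_mean_degree(self):
        # empirical mean degree vs (n-1)*C within 3 standard errors
        n, C, reps = 60, 0.25, 200
        degs = [random_coupling(n, C, seed=s).degrees().mean()
                for s in range(reps)]
        exp = (n - 1) * C
        se = np.sqrt((n - 1) * C * (1 - C) / n) / np.sqrt(reps)
        assert abs(np.mean(degs) - exp) < 3 * se

    def test_determinism_and_validation(self):
        a = random_coupling(50, 0.3, seed=7)
        b = random_coupling(50, 0.3, seed=7)
        assert np.array_equal(a.edges, b.edges)
        with pytest.raises(ValueError):
            random_coupling(10, 1.5, seed=0)


class TestPlanarCoupling:
    def test_subunit_radius_gives_no_edges(self):
        assert planar_coupling(10, 10, 0.5, 1.0, seed=0).n_edges == 0

    @pytest.mark.parametrize("radius,expected", [(1.0, 4), (5.0, 80)])
    def test_interior_candidate_count(self, radius, expected):
        # brute-force lattice-point count as the oracle
        brute = sum(1 for dx, dy in itertools.product(range(-9, 10), repeat=2)
                    if (dx, dy) != (0, 0) and dx * dx + dy * dy <= radius ** 2)
        assert brute == expected
        net = planar_coupling(19, 19, radius, 1.0, seed=0)
        center = 9 * 19 + 9
        assert net.degrees()[center] == expected

    def test_hard_boundaries(self):
        net = planar_coupling(10, 10, 1.0, 1.0, seed=0)
        assert net.degrees()[0] == 2  # corner neuron: two lattice neighbours

    def test_edges_within_radius(self):
        net = planar_coupling(10, 10, 5.0, 0.5, seed=3)
        d = np.linalg.norm(net.positions[net.edges[:, 0]]
                           - net.positions[net.edges[:, 1]], axis=1)
        assert np.all(d <= 5.0 + 1e-9)


class TestGapCurrents:
    def test_equal_voltages_give_zero(self):
        net = random_coupling(30, 0.4, seed=1)
        assert np.allclose(gap_currents(np.full(30, -55.0), net), 0.0)

    def test_pair_antisymmetry(self):
        net = GapNetwork(2, [[0, 1]], g_gap=0.003)
        I = gap_currents(np.array([-50.0, -70.0]), net)
        assert I[0] == pytest.approx(0.06)
        assert I[1] == pytest.approx(-0.06)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 40), st.integers(0, 10_000))
    def test_global_conservation(self, n, seed):
        # charge conservation: the gap-current vector sums to zero exactly
        rng = np.random.default_rng(seed)
        net = random_coupling(n, 0.5, seed=seed)
        V = rng.uniform(-90, 30, n)
        assert abs(gap_currents(V, net).sum()) < 1e-9

    def test_dimension_mismatch_rejected(self):
        net = random_coupling(10, 0.5, seed=0)
        with pytest.raises(ValueError):
            gap_currents(np.zeros(9), net)


class TestPartitionCounts:
    def test_within_between_counts_match_expectation(self):
        # Monte-Carlo within/between edge counts vs C(S^2-S)/2 and C*S1*S2
        C, S1, S2 = 0.25, 60, 40
        g1, g2 = np.arange(S1), np.arange(S1, S1 + S2)
        within1, between = [], []
        for s in range(120):
            net = random_coupling(S1 + S2, C, seed=s)
            within1.append(net.count_edges_between(g1))
            between.append(net.count_edges_between(g1, g2))
        n1 = S1 * (S1 - 1) / 2
        nb = S1 * S2
        for obs, npairs in ((np.mean(within1), n1), (np.mean(between), nb)):
            se = np.sqrt(npairs * C * (1 - C) / 120)
            assert abs(obs - npairs * C) < 4 * se


class TestIO:
    def test_edgelist_roundtrip(self, tmp_path):
        net = planar_coupling(5, 5, 2.0, 0.6, seed=11, g_gap=0.0012)
        path = tmp_path / "net.edges"
        net.to_edgelist(path)
        back = GapNetwork.from_edgelist(path)
        assert back.n_neurons == net.n_neurons
        assert np.array_equal(back.edges, net.edges)
        assert back.g_gap == net.g_gap
        assert np.allclose(back.positions, net.positions)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GapNetwork(5, [[0, 0]])
        with pytest.raises(ValueError):
            GapNetwork(5, [[0, 7]])
        net = GapNetwork(5, [[3, 1]])
        assert tuple(net.edges[0]) == (1, 3)  # stored as unordered pair
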