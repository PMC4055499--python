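"""Small-world efficiency metrics against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpmri.cohort import CohortConfig, generate_cohort
from mpmri.efficiency import (compare_efficiency, efficiency_profile,
                              global_efficiency, local_efficiency,
                              read_profile, shortest_path_lengths,
                              structural_group_comparison, write_profile)
from mpmri.networks import BinaryGraph, ConnectivityMatrix, threshold_at_sparsity
from conftest import random_graph


def _complete(n):
    return BinaryGraph(np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8))


def _floyd_warshall(adj):
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    d[adj > 0] = 1
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


class TestShortestPaths:
    def test_path_graph(self):
        p3 = BinaryGraph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8))
        d = shortest_path_lengths(p3)
        assert d[0, 2] == 2

    def test_disconnected_pair_is_infinite(self):
        g = BinaryGraph(np.zeros((2, 2), dtype=np.uint8))
        assert np.isinf(shortest_path_lengths(g)[0, 1])

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            g = random_graph(rng, 30, float(rng.uniform(0.05, 0.4)))
            np.testing.assert_array_equal(shortest_path_lengths(g),
                                          _floyd_warshall(g.adjacency))


class TestEfficiencyClosedForms:
    def test_complete_graph(self):
        assert global_efficiency(_complete(4)) == pytest.approx(1.0)

    def test_empty_graph(self):
        assert global_efficiency(BinaryGraph(np.zeros((5, 5), dtype=np.uint8))) == 0.0

    def test_path_graph_p3(self):
        p3 = BinaryGraph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8))
        # brute force over the 6 ordered pairs: 4 at distance 1, 2 at distance 2
        assert global_efficiency(p3) == pytest.approx(5 / 6)

    def test_local_triangle_and_star(self):
        assert local_efficiency(_complete(3)) == pytest.approx(1.0)
        star = np.zeros((5, 5), dtype=np.uint8)
        star[0, 1:] = star[1:, 0] = 1
        assert local_efficiency(BinaryGraph(star)) == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(BinaryGraph(np.zeros((1, 1), dtype=np.uint8)))


class TestOracleEquivalence:
    def test_against_networkx_on_random_graphs(self):
        import networkx as nx
        rng = np.random.default_rng(1)
        for trial in range(30):
            g = random_graph(rng, int(rng.integers(4, 25)),
                             float(rng.uniform(0.1, 0.7)))
            G = nx.from_numpy_array(g.adjacency)
            assert global_efficiency(g) == pytest.approx(nx.global_efficiency(G), abs=1e-12)
            assert local_efficiency(g) == pytest.approx(nx.local_efficiency(G), abs=1e-12)

    def test_brute_force_neighbor_subgraph_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            g = random_graph(rng, 10, 0.4)
            total = 0.0
            for i in range(10):
                nb = np.nonzero(g.adjacency[i])[0]
                if nb.size < 2:
                    continue
                sub = g.adjacency[np.ix_(nb, nb)]
                d = _floyd_warshall(sub)
                with np.errstate(divide="ignore"):
                    inv = 1.0 / d
                inv[~np.isfinite(inv)] = 0
                np.fill_diagonal(inv, 0)
                total += inv.sum() / (nb.size * (nb.size - 1))
            assert local_efficiency(g) == pytest.approx(total / 10, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_adding_an_edge_never_decreases_global_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 10, 0.3)
        absent = [(i, j) for i in range(10) for j in range(i + 1, 10)
                  if not g.adjacency[i, j]]
        if not absent:
            return
        i, j = absent[int(rng.integers(len(absent)))]
        a2 = g.adjacency.copy()
        a2[i, j] = a2[j, i] = 1
        assert global_efficiency(BinaryGraph(a2)) >= global_efficiency(g) - 1e-12


@pytest.fixture(scope="module")
def er_matrix():
    rng = np.random.default_rng(3)
    w = np.corrcoef(rng.standard_normal((40, 60)))
    np.fill_diagonal(w, 0)
    return ConnectivityMatrix(w, [f"r{k}" for k in range(40)])


class TestEfficiencyProfile:

    def test_complete_matrix_relative_efficiency_is_one(self):
        w = np.full((8, 8), 0.9)
        np.fill_diagonal(w, 0)
        m = ConnectivityMatrix(w, [f"r{k}" for k in range(8)])
        p = efficiency_profile(m, grid=[1.0], n_random=5, seed=0)
        assert p.e_global_rel[0] == pytest.approx(1.0)
        assert p.e_global_abs[0] == pytest.approx(1.0)

    def test_global_efficiency_nondecreasing_in_sparsity(self, er_matrix):
        p = efficiency_profile(er_matrix, grid=[0.1, 0.2, 0.3, 0.4], n_random=3, seed=1)
        assert all(0 <= v <= 1 for v in p.e_global_abs + p.e_local_abs)
        assert np.all(np.diff(p.e_global_abs) >= -1e-12)

    def test_random_graph_relative_efficiency_near_one(self):
        # null self-consistency: an ER graph is statistically its own null
        g = random_graph(np.random.default_rng(10), 40, 0.2)
        from mpmri.networks import degree_matched_random
        eg = global_efficiency(g)
        nulls = [global_efficiency(degree_matched_random(g, seed=k)) for k in range(30)]
        mean, sd = np.mean(nulls), np.std(nulls, ddof=1)
        assert abs(eg - mean) <= 3 * max(sd, 1e-6)

    def test_seeded_determinism(self, er_matrix):
        a = efficiency_profile(er_matrix, grid=[0.15, 0.3], n_random=4, seed=5)
        b = efficiency_profile(er_matrix, grid=[0.15, 0.3], n_random=4, seed=5)
        assert a.e_global_rel == b.e_global_rel
        assert a.e_total_abs == b.e_total_abs

    def test_total_is_sum_of_local_and_global(self, er_matrix):
        p = efficiency_profile(er_matrix, grid=[0.2], n_random=3, seed=2)
        assert p.e_total_abs[0] == pytest.approx(p.e_global_abs[0] + p.e_local_abs[0])

    def test_threshold_errors_recorded_not_fatal(self):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 0.9   # single positive entry
        m = ConnectivityMatrix(w, [f"r{k}" for k in range(6)])
        p = efficiency_profile(m, grid=[0.1, 0.9], n_random=2, seed=0)
        assert 0.9 in p.errors and np.isnan(p.e_global_abs[1])
        assert not np.isnan(p.e_global_abs[0])

    def test_profile_io_roundtrip(self, tmp_path, er_matrix):
        p = efficiency_profile(er_matrix, grid=[0.2, 0.4], n_random=2, seed=3)
        write_profile(p, tmp_path / "p.tsv")
        back = read_profile(tmp_path / "p.tsv")
        assert back.sparsity_grid == p.sparsity_grid
        assert back.e_global_rel == pytest.approx(p.e_global_rel)


class TestGroupComparison:
    def _profiles(self, seed, shift=0.0, n=6):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            w = np.corrcoef(rng.standard_normal((20, 30)) + shift * rng.standard_normal((20, 1)))
            np.fill_diagonal(w, 0)
            m = ConnectivityMatrix(w, [f"r{k}" for k in range(20)])
            out.append(efficiency_profile(m, grid=[0.2, 0.3], n_random=2,
                                          seed=int(rng.integers(2**31))))
        return out

    def test_identical_groups_give_zero_t(self):
        a = self._profiles(0)
        table = compare_efficiency(a, a, mode="subject_level")
        assert (table["t"].abs() < 1e-12).all()
        assert (table["p"] > 0.999).all()

    def test_subject_level_needs_two_profiles(self):
        a = self._profiles(1, n=1)
        with pytest.raises(ValueError):
            compare_efficiency(a, a, mode="subject_level")

    def test_planted_covariance_difference_detected(self):
        # strong long-range vs. modular thickness covariance, 40 regions
        cfg = CohortConfig(n_per_group=50, n_cortical=40, seed=4)
        coh = generate_cohort(cfg, timeseries=False)
        td = pd.DataFrame(coh.thickness_matrix("TD"), columns=coh.cortical_regions)
        asd = pd.DataFrame(coh.thickness_matrix("ASD"), columns=coh.cortical_regions)
        table = structural_group_comparison(td, asd, grid=(0.10, 0.20),
                                            n_random=6, n_boot=10, n_perm=49, seed=5)
        sub = table[table.metric == "e_global_rel"]
        assert (sub["point_diff"] < 0).all()          # ASD lower
        assert (sub["p"] < 0.05).any()
        assert {"ci_low", "ci_high"} <= set(table.columns)
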