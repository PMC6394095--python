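"""Grid construction, neighbor networks, and genotype adjacency."""

import itertools

import numpy as np
import pytest
from scipy import stats

from regscape.landscape import (DEFAULT_RANGES, GridConfig, Landscape,
                                NeighborNetwork, ParamRange, build_grid,
                                build_neighbors, complete_network,
                                one_mutant_neighbors)


class TestBuildGrid:
    def test_endpoints_sorted_unique(self):
        grid = build_grid(GridConfig(n_levels=100, seed=5))
        for p, r in enumerate(DEFAULT_RANGES):
            v = grid.values[p]
            assert v[0] == r.min and v[-1] == r.max
            assert np.all(np.diff(v) > 0)
            assert len(v) == 100

    def test_three_levels_is_endpoints_plus_one_interior(self):
        rng = (ParamRange("x", 0.0, 1.0, "linear"),)
        grid = build_grid(GridConfig(ranges=rng, n_levels=3, seed=1))
        v = grid.values[0]
        assert v[0] == 0.0 and v[-1] == 1.0 and 0.0 < v[1] < 1.0

    def test_deterministic_given_seed(self):
        g1 = build_grid(GridConfig(n_levels=50, seed=9))
        g2 = build_grid(GridConfig(n_levels=50, seed=9))
        g3 = build_grid(GridConfig(n_levels=50, seed=10))
        assert np.array_equal(g1.values, g2.values)
        assert not np.array_equal(g1.values, g3.values)

    def test_log_scale_draws_are_log_uniform(self):
        rng = (ParamRange("k", 1e-4, 1e2, "log"),)
        grid = build_grid(GridConfig(ranges=rng, n_levels=1000, seed=3))
        interior = np.log(grid.values[0][1:-1])
        u = (interior - np.log(1e-4)) / (np.log(1e2) - np.log(1e-4))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            ParamRange("x", 2.0, 1.0)
        with pytest.raises(ValueError):
            ParamRange("x", -1.0, 1.0, "log")


class TestBuildNeighbors:
    def test_forced_complete_graphs(self):
        # n=3, K=2 and K = n-1 both force the complete graph
        for n, K in ((3, 2), (8, 7)):
            net = build_neighbors(n, K, sigma=20.0, seed=0)
            assert np.all(net.degree == n - 1)

    def test_symmetry_and_no_self_loops(self):
        net = build_neighbors(200, 10, sigma=5.0, seed=2)
        for i in range(200):
            nb = net.neighbors_of(i)
            assert i not in nb
            for j in nb:
                assert i in net.neighbors_of(j)

    def test_union_mode_degree_bounds(self):
        net = build_neighbors(1000, 50, sigma=20.0, seed=4)
        assert net.degree.min() >= 50
        assert 50 <= net.mean_degree <= 100

    def test_strict_mode_caps_degree(self):
        net = build_neighbors(1000, 50, sigma=20.0, seed=4, mode="strict")
        assert net.degree.max() <= 50
        # almost all nodes should attain the cap
        assert (net.degree == 50).mean() > 0.8

    def test_edge_distance_locality(self):
        net = build_neighbors(1000, 50, sigma=20.0, seed=6)
        e = net.edges()
        d = np.abs(e[:, 0] - e[:, 1])
        assert np.median(d) <= 2 * 20.0

    def test_single_draws_follow_truncated_gaussian_kernel(self):
        # with K=1 each interior node's draw is exactly kernel-distributed
        from regscape.landscape import _draw_proposals

        sigma, n = 20.0, 1000
        offsets = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            prop = _draw_proposals(n, 1, sigma, rng)
            i = np.arange(n)
            keep = (i >= 200) & (i < 800)  # interior: untruncated kernel
            offsets.extend((prop[keep, 0] - i[keep]).tolist())
        offsets = np.abs(offsets)
        edges = np.array([0.5, 5.5, 10.5, 15.5, 20.5, 30.5, 40.5, np.inf])
        obs, _ = np.histogram(offsets, bins=edges)
        d = np.arange(1, 200)
        pmf = np.exp(-0.5 * (d / sigma) ** 2)
        pmf = np.concatenate([pmf, pmf]) / (2 * pmf.sum())  # +/- symmetric
        dd = np.abs(np.concatenate([d, -d]))
        exp = np.array([np.sum(pmf[(dd > edges[k]) & (dd < edges[k + 1])])
                        for k in range(len(edges) - 1)]) * len(offsets)
        chi2 = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 0.01

    def test_reproducible_and_seed_sensitive(self):
        a = build_neighbors(300, 8, sigma=10.0, seed=7)
        b = build_neighbors(300, 8, sigma=10.0, seed=7)
        c = build_neighbors(300, 8, sigma=10.0, seed=8)
        assert a == b
        assert a != c

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            build_neighbors(10, 10, sigma=5.0, seed=0)
        with pytest.raises(ValueError):
            build_neighbors(10, 0, sigma=5.0, seed=0)


class TestOneMutantNeighbors:
    def test_complete_three_level_count(self):
        nets = [complete_network(3) for _ in range(6)]
        nbrs = one_mutant_neighbors((0, 1, 2, 0, 1, 2), nets)
        assert len(nbrs) == 12
        assert len(set(nbrs)) == 12

    def test_exhaustive_enumeration_matches(self):
        # brute force over a 3-parameter, 5-level toy
        nets = [build_neighbors(5, 2, sigma=1.5, seed=s) for s in range(3)]
        g = (2, 0, 4)
        got = set(one_mutant_neighbors(g, nets))
        expected = set()
        for h in itertools.product(range(5), repeat=3):
            diff = [p for p in range(3) if h[p] != g[p]]
            if len(diff) == 1 and h[diff[0]] in nets[diff[0]].neighbors_of(g[diff[0]]):
                expected.add(h)
        assert got == expected

    def test_genotype_adjacency_is_symmetric(self):
        nets = [build_neighbors(5, 2, sigma=1.5, seed=s) for s in range(3)]
        for g in itertools.product(range(5), repeat=3):
            for h in one_mutant_neighbors(g, nets):
                assert g in one_mutant_neighbors(h, nets)


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path):
        grid = build_grid(GridConfig(n_levels=40, seed=13))
        land = Landscape.from_grn(grid, K_conn=5, sigma=3.0, seed=13)
        land.save(tmp_path / "bundle")
        back = Landscape.load(tmp_path / "bundle")
        assert np.array_equal(back.grid.values, grid.values)
        for n1, n2 in zip(land.networks, back.networks):
            assert n1 == n2
        g = np.array([[0, 1, 2, 3, 4, 5], [39, 38, 0, 1, 2, 3]])
        assert np.array_equal(land.fitness_of(g), back.fitness_of(g))
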