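"""Ensemble drivers, peak estimation, scan statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regscape.experiments import (ExperimentDesign, _transition_K,
                                  critical_k_scan, estimate_global_peak,
                                  run_ensemble, speed_of_evolution,
                                  steps_to_peak_summary, variance_dynamics)
from regscape.grn import FitnessConstants
from regscape.landscape import GridConfig, Landscape, build_grid


class TestEstimateGlobalPeak:
    def test_exact_argmax_on_enumerable_grid(self, tiny_grid_landscape):
        land = tiny_grid_landscape
        est = estimate_global_peak(land, n_restarts=8, rng=1)
        all_g = np.array(list(itertools.product(range(5), repeat=6)))
        fits = land.fitness_of(all_g)
        assert est.fitness == pytest.approx(float(fits.max()), abs=0)
        assert tuple(all_g[int(np.argmax(fits))]) == est.genotype

    def test_costless_limit_maximizes_target_level(self, tiny_grid_landscape):
        land = tiny_grid_landscape.with_fitness_constants(
            FitnessConstants(a=1.0, b=10.0, alpha=0.0))
        est = estimate_global_peak(land, n_restarts=8, rng=2)
        from regscape.grn import batch_fitness
        all_g = np.array(list(itertools.product(range(5), repeat=6)))
        comp = batch_fitness(land.grid.params_of(all_g), components=True)
        T_max = comp["T"].max()
        assert est.fitness == pytest.approx(T_max / (T_max + 10.0), rel=1e-12)

    def test_grid_and_continuous_estimators_agree(self):
        grid = build_grid(GridConfig(n_levels=500, seed=21))
        land = Landscape.from_grn(grid, K_conn=10, seed=21)
        est = estimate_global_peak(land, n_restarts=12, rng=3)
        assert est.agree, est.message
        assert est.continuous_fitness >= est.fitness - 1e-12
        assert est.continuous_fitness - est.fitness <= 1e-3 * est.continuous_fitness


class TestRunEnsemble:
    def test_monte_carlo_matches_exact_chain(self, two_peak_toy):
        # reach probability and mean steps vs the absorbing-chain values,
        # within 3 Monte-Carlo standard errors at n = 1000
        land = two_peak_toy.landscape
        truth = two_peak_toy.truth
        start = (2, 1)
        p = truth.p_reach_global(start)
        assert 0.0 < p < 1.0  # genuinely stochastic basin
        res = run_ensemble(land, start, K=1, start_fitness_target=0.0,
                           global_fitness=truth.fitness.max(), n_replicates=1000,
                           master_seed=5, reach_tol=1e-12, resample_networks=False)
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(res.fraction_reached_global - p) <= 3 * se
        exp_steps = truth.expected_steps[truth.flat(start)]
        sd = res.steps_to_peak.std(ddof=1) / np.sqrt(1000)
        assert abs(res.steps_to_peak.mean() - exp_steps) <= 3 * sd

    def test_full_connectivity_single_peak_always_reaches(self, single_peak_toy):
        land = single_peak_toy.landscape
        gmax = single_peak_toy.global_optimum
        res = run_ensemble(land, (0, 0), K=4, start_fitness_target=0.0,
                           global_fitness=float(land.fitness_of(np.array(gmax))),
                           n_replicates=200, master_seed=6, reach_tol=1e-12,
                           resample_networks=False)
        assert res.fraction_reached_global == 1.0

    def test_carry_forward_padding(self, single_peak_toy):
        land = single_peak_toy.landscape
        res = run_ensemble(land, (0, 0), K=4, start_fitness_target=0.0,
                           global_fitness=1.0, n_replicates=50, master_seed=7,
                           resample_networks=False)
        # after termination each row holds its terminal fitness
        for r in range(50):
            row = res.fitness_matrix[r]
            assert row[-1] == res.terminal_fitness[r]
        assert np.all(np.diff(res.mean_fitness_series) >= 0)

    def test_replicates_reproducible_and_order_independent(self, two_peak_toy):
        land = two_peak_toy.landscape
        kw = dict(start_fitness_target=0.3, global_fitness=1.0,
                  master_seed=9, resample_networks=False)
        a = run_ensemble(land, (0, 4), K=2, n_replicates=30, **kw)
        b = run_ensemble(land, (0, 4), K=2, n_replicates=30, **kw)
        assert np.array_equal(a.terminal_fitness, b.terminal_fitness)
        # a shorter run is a prefix of a longer one (per-replicate child seeds)
        c = run_ensemble(land, (0, 4), K=2, n_replicates=10, **kw)
        assert np.array_equal(c.terminal_fitness, a.terminal_fitness[:10])


class TestSummaries:
    @staticmethod
    def _mk_result(K, f0, mat, reached):
        from regscape.experiments import EnsembleResult
        mat = np.asarray(mat, dtype=float)
        return EnsembleResult(
            K=K, start_fitness_target=f0, start_genotype=(0,),
            global_fitness=1.0, reach_tol=1e-9,
            terminal_fitness=mat[:, -1],
            steps_to_peak=np.full(mat.shape[0], mat.shape[1] - 1),
            reached_global=np.asarray(reached), fitness_matrix=mat)

    def test_flat_trajectories_have_zero_speed_and_variance(self):
        res = self._mk_result(3, 0.5, [[0.5, 0.5, 0.5]] * 4, [False] * 4)
        sp = speed_of_evolution({(3, 0.5): res})
        assert sp.loc[0, "peak_speed"] == 0.0
        vd = variance_dynamics({(3, 0.5): res})
        assert vd.loc[0, "peak_variance"] == 0.0
        assert vd.loc[0, "terminal_variance"] == 0.0

    def test_increasing_mean_series_gives_positive_speeds(self):
        res = self._mk_result(3, 0.1, [[0.1, 0.4, 0.9], [0.1, 0.5, 0.8]],
                              [True, True])
        assert np.all(res.speed_series > 0)

    def test_terminal_variance_zero_iff_terminals_coincide(self):
        same = self._mk_result(3, 0.1, [[0.1, 0.9], [0.3, 0.9]], [True, True])
        mixed = self._mk_result(3, 0.1, [[0.1, 0.9], [0.3, 0.6]], [True, False])
        assert variance_dynamics({(3, 0.1): same}).loc[0, "terminal_variance"] == 0
        assert variance_dynamics({(3, 0.1): mixed}).loc[0, "terminal_variance"] > 0

    def test_unreached_replicates_excluded_from_mean_steps(self):
        from regscape.experiments import EnsembleResult
        res = EnsembleResult(
            K=5, start_fitness_target=0.1, start_genotype=(0,),
            global_fitness=1.0, reach_tol=1e-9,
            terminal_fitness=np.array([1.0, 0.7, 1.0]),
            steps_to_peak=np.array([4, 50, 6]),
            reached_global=np.array([True, False, True]),
            fitness_matrix=np.tile([[0.1, 1.0]], (3, 1)))
        df = steps_to_peak_summary({(5, 0.1): res})
        assert df.loc[0, "mean_steps"] == pytest.approx(5.0)
        assert df.loc[0, "n_unreached"] == 1

    def test_zero_steps_when_starting_at_the_peak(self, single_peak_toy):
        land = single_peak_toy.landscape
        top = single_peak_toy.global_optimum
        res = run_ensemble(land, top, K=4, start_fitness_target=1.0,
                           global_fitness=float(land.fitness_of(np.array(top))),
                           n_replicates=5, master_seed=1, resample_networks=False)
        assert np.all(res.steps_to_peak == 0)
        assert res.fraction_reached_global == 1.0

    def test_transition_rule(self):
        table = pd.DataFrame({
            "K": [3, 3, 10, 10, 20, 20],
            "start_F": [0.1, 0.5] * 3,
            "fraction_reached_global": [0.0, 0.1, 0.9, 0.96, 1.0, 0.99],
        })
        assert _transition_K(table, 0.95) == 20
        assert _transition_K(table, 0.5) == 10
        assert _transition_K(table, 1.01) is None


class TestCriticalKScanSmall:
    def test_fraction_monotone_on_reduced_landscape(self):
        # reduced landscape: 200 levels, sigma 4 (same 2% locality), tiny design
        grid = build_grid(GridConfig(n_levels=200, seed=17))
        design = ExperimentDesign(K_values=(2, 10, 40), start_fitnesses=(0.3,),
                                  n_replicates=15, sigma=4.0, master_seed=17)
        scan = critical_k_scan(design, grid)
        fr = scan.table.sort_values("K")["fraction_reached_global"].to_numpy()
        assert fr[0] <= fr[1] + 0.2 and fr[1] <= fr[2] + 0.2  # binomial slack
        assert fr[-1] >= 0.8
        assert set(scan.table.columns) >= {"K", "start_F", "fraction_reached_global",
                                           "mean_steps_reached", "n_unreached"}
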