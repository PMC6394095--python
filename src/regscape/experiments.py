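"""Ensemble drivers and summary statistics for adaptive-walk experiments.

The central experiment sweeps the per-parameter connectivity ``K`` and the
starting fitness of the walk, running an ensemble of independently seeded
replicate walks for each design point, and asks: what fraction of replicates
reaches the landscape's global fitness peak, how many mutational events does
that take, how fast does mean fitness rise, and how variable are the
trajectories?  The fraction-reached-global exhibits a sharp transition from
~0 to ~1 at a critical connectivity of roughly 1% of the number of levels.

Reproducibility: every replicate's RNG is seeded by a
:class:`numpy.random.SeedSequence` built from
``(master_seed, tag, K, start_key, replicate)``, so any subset of design
points can be re-run in any order with identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .grn import EnvSignal, FitnessConstants
from .landscape import GridConfig, Landscape, ParameterGrid, build_grid
from .walk import Trajectory, adaptive_walk, find_start_genotype

__all__ = [
    "ExperimentDesign",
    "GlobalPeakEstimate",
    "EnsembleResult",
    "ScanResult",
    "estimate_global_peak",
    "run_ensemble",
    "critical_k_scan",
    "steps_to_peak_summary",
    "speed_of_evolution",
    "variance_dynamics",
    "fitness_function_sensitivity",
    "child_seed",
]

# seed-derivation tags (stable; part of the reproducibility contract)
_TAG_NETWORK = 0x6e657473   # per-parameter neighbor networks
_TAG_START = 0x73746172     # start-genotype search
_TAG_REPLICATE = 0x7265706c  # per-replicate walks
_TAG_PEAK = 0x7065616b      # global-peak estimation


def child_seed(master: int, tag: int, *key: int) -> np.random.SeedSequence:
    """Stable child seed for one component of an experiment."""
    return np.random.SeedSequence((int(master), int(tag), *(int(k) for k in key)))


def _start_key(target_F: float) -> int:
    """Encode a start-fitness design value for seed derivation."""
    return int(round(target_F * 1e6))


@dataclass(frozen=True)
class ExperimentDesign:
    """The full sweep: which connectivities, starts, and replicate counts.

    Defaults are the study conditions: eight connectivity values, five
    starting fitnesses spanning very low to very high on the base fitness
    scale, 100 replicates per design point.  Each replicate redraws its
    neighbor networks (``resample_networks=False`` freezes one realization
    per K instead, which measures a realization-specific quantity).  A
    replicate has "reached the global peak" when its terminal fitness equals
    the global-peak fitness to within ``reach_tol``; the default matches
    fitness values at four-decimal precision, the scale at which such
    fitnesses are conventionally reported.
    """

    K_values: tuple[int, ...] = (3, 5, 7, 10, 12, 15, 20, 50)
    start_fitnesses: tuple[float, ...] = (0.0826, 0.2251, 0.45, 0.6264, 0.8526)
    n_replicates: int = 100
    sigma: float = 20.0
    network_mode: str = "union"
    resample_networks: bool = True
    master_seed: int = 0
    start_tol: float = 1e-3
    reach_tol: float = 5e-5
    reach_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.K_values or not self.start_fitnesses:
            raise ValueError("design needs at least one K and one start fitness")


@dataclass
class GlobalPeakEstimate:
    """Best genotype/fitness found on the grid, with a continuous cross-check.

    ``fitness`` is the grid estimate (multi-start coordinate ascent with full
    per-parameter connectivity); ``continuous_fitness`` maximizes the same
    fitness over the continuous parameter box.  The continuous value bounds
    the grid value from above; ``agree`` records whether the gap is within
    the expected discretization error, and a disagreement warning is
    surfaced in ``message`` rather than raised.
    """

    genotype: tuple[int, ...]
    fitness: float
    continuous_fitness: float
    continuous_params: np.ndarray
    agree: bool
    message: str = ""


def estimate_global_peak(
    landscape: Landscape,
    n_restarts: int = 24,
    rng: np.random.Generator | int | None = None,
    rel_tol: float = 1e-3,
) -> GlobalPeakEstimate:
    """Locate the landscape's global fitness peak by two independent routes.

    Grid route: from each random restart, coordinate ascent in which every
    level of one parameter is scanned (full connectivity) and the best kept,
    cycling until a full sweep makes no change — a coordinate-wise global
    maximum of the discrete landscape.  Continuous route: quasi-Newton
    maximization of the same fitness over the log-parameter box, multi-start.
    The continuous optimum must be at least the grid optimum and close to it
    (the grid is dense); the two estimates' agreement is reported.
    """
    if landscape.grid is None:
        raise ValueError("estimate_global_peak needs a grid landscape")
    rng = np.random.default_rng(rng)
    grid = landscape.grid
    D, n = grid.n_params, grid.n_levels

    best_g, best_f = None, -np.inf
    for _ in range(n_restarts):
        g = rng.integers(n, size=D)
        f = float(landscape.fitness_of(g))
        while True:
            changed = False
            for p in range(D):
                cand = np.tile(g, (n, 1))
                cand[:, p] = np.arange(n)
                fits = landscape.fitness_of(cand)
                j = int(np.argmax(fits))
                if fits[j] > f:
                    f = float(fits[j])
                    g = cand[j]
                    changed = True
            if not changed:
                break
        if f > best_f:
            best_f, best_g = f, g.copy()

    # continuous cross-check in log space
    lo = np.log(grid.values[:, 0])
    hi = np.log(grid.values[:, -1])

    best_cont, best_x = -np.inf, None
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(lambda x: -_cont_f(landscape, x), x0, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)))
        if -res.fun > best_cont:
            best_cont, best_x = -float(res.fun), res.x
    # polish from the grid optimum as well
    res = minimize(lambda x: -_cont_f(landscape, x),
                   np.log(grid.params_of(best_g)), method="L-BFGS-B",
                   bounds=list(zip(lo, hi)))
    if -res.fun > best_cont:
        best_cont, best_x = -float(res.fun), res.x

    gap = best_cont - best_f
    scale = max(abs(best_cont), 1.0)
    agree = gap >= -1e-9 * scale and gap <= rel_tol * scale
    msg = "" if agree else (
        f"grid ({best_f:.6g}) and continuous ({best_cont:.6g}) peak estimates "
        f"differ by {gap:.3g} (> {rel_tol} relative)")
    return GlobalPeakEstimate(tuple(int(x) for x in best_g), best_f, best_cont,
                              np.exp(best_x), agree, msg)


def _cont_f(landscape: Landscape, logx: np.ndarray) -> float:
    from .grn import batch_fitness
    return float(batch_fitness(np.exp(logx)[None, :], landscape.env.S, landscape.fc,
                               landscape.kr_ratio)[0])


@dataclass
class EnsembleResult:
    """Replicate walks from one (connectivity, start) design point.

    ``fitness_matrix[r, t]`` is replicate ``r``'s fitness after ``t``
    accepted mutations; after a replicate terminates its terminal fitness is
    carried forward, so column means/variances describe a population sitting
    at its peak once evolution stops.
    """

    K: int
    start_fitness_target: float
    start_genotype: tuple[int, ...]
    global_fitness: float
    reach_tol: float
    terminal_fitness: np.ndarray   # (n_replicates,)
    steps_to_peak: np.ndarray      # (n_replicates,) accepted mutations at termination
    reached_global: np.ndarray     # (n_replicates,) bool
    fitness_matrix: np.ndarray     # (n_replicates, max_len+1)

    @property
    def n_replicates(self) -> int:
        return len(self.terminal_fitness)

    @property
    def fraction_reached_global(self) -> float:
        return float(self.reached_global.mean())

    @property
    def mean_fitness_series(self) -> np.ndarray:
        return self.fitness_matrix.mean(axis=0)

    @property
    def var_fitness_series(self) -> np.ndarray:
        """Between-replicate fitness variance at each mutational step."""
        return self.fitness_matrix.var(axis=0)

    @property
    def speed_series(self) -> np.ndarray:
        """Per-step gain of the ensemble-mean fitness."""
        return np.diff(self.mean_fitness_series)


def run_ensemble(
    landscape: Landscape,
    start_genotype,
    K: int,
    start_fitness_target: float,
    global_fitness: float,
    n_replicates: int = 100,
    master_seed: int = 0,
    reach_tol: float = 5e-5,
    resample_networks: bool = True,
) -> EnsembleResult:
    """Run ``n_replicates`` independently seeded walks from one genotype.

    Replicate ``r`` uses the child seed ``(master, K, start, r)``, for its
    walk and (when ``resample_networks``) for its own neighbor-network draw;
    a replicate counts as having reached the global peak when its terminal
    fitness is within ``reach_tol`` of ``global_fitness``.
    """
    skey = _start_key(start_fitness_target)
    # the tolerance is relative to the fitness scale (with an absolute floor
    # for sub-unit fitness), so rescaled benefit constants compare fairly
    reach_eps = reach_tol * max(1.0, abs(global_fitness))
    net0 = landscape.networks[0]
    trajs: list[Trajectory] = []
    for r in range(n_replicates):
        land_r = landscape
        if resample_networks:
            land_r = Landscape.from_grn(
                landscape.grid, K_conn=K, sigma=net0.sigma,
                seed=(master_seed, skey, r), mode=net0.mode,
                env=landscape.env, fc=landscape.fc, kr_ratio=landscape.kr_ratio)
        rng = np.random.default_rng(child_seed(master_seed, _TAG_REPLICATE, K, skey, r))
        trajs.append(adaptive_walk(start_genotype, land_r, rng))

    series = [t.fitness_series() for t in trajs]
    L = max(len(s) for s in series)
    mat = np.empty((n_replicates, L))
    for r, s in enumerate(series):
        mat[r, : len(s)] = s
        mat[r, len(s):] = s[-1]
    terminal = np.array([t.final.fitness for t in trajs])
    steps = np.array([t.n_steps for t in trajs], dtype=np.int64)
    reached = np.abs(terminal - global_fitness) <= reach_eps
    return EnsembleResult(
        K=K, start_fitness_target=start_fitness_target,
        start_genotype=tuple(int(x) for x in np.asarray(start_genotype)),
        global_fitness=global_fitness, reach_tol=reach_tol,
        terminal_fitness=terminal, steps_to_peak=steps, reached_global=reached,
        fitness_matrix=mat,
    )


@dataclass
class ScanResult:
    """Outcome of a full (K x start) sweep on one landscape.

    Two transition statistics are reported.  ``transition_K`` is the
    smallest tested K whose reach fraction meets the saturation threshold
    (default 0.95) for every start — "from here on, walks essentially always
    arrive".  ``midpoint_K`` is the 50% crossing of the start-averaged reach
    curve, linearly interpolated between tested K values — the standard
    estimator of a transition's location from a sampled sigmoid, and much
    less sensitive to the arbitrary choice of what counts as "near one".
    """

    table: pd.DataFrame               # columns: K, start_F, fraction_reached_global, ...
    transition_K: int | None          # smallest K with fraction >= threshold for all starts
    midpoint_K: float | None          # interpolated 50% crossing of the mean curve
    ensembles: dict[tuple[int, float], EnsembleResult]
    peak: GlobalPeakEstimate
    start_genotypes: dict[float, tuple[int, ...]]
    mean_degrees: dict[int, float]


def critical_k_scan(
    design: ExperimentDesign,
    grid: ParameterGrid,
    env: EnvSignal = EnvSignal(),
    fc: FitnessConstants = FitnessConstants(),
    start_genotypes: dict[float, tuple[int, ...]] | None = None,
    keep_ensembles: bool = True,
    progress: bool = False,
) -> ScanResult:
    """Sweep connectivity and starting fitness; tabulate peak-reaching rates.

    One neighbor network per (parameter, K) is frozen and shared by all
    replicates and starts of that K; one start genotype per starting fitness
    is shared across all K values so connectivity comparisons are not
    confounded by start choice.  The inferred transition connectivity is the
    smallest tested K whose reach fraction is at least
    ``design.reach_threshold`` for every start.
    """
    base = Landscape.from_grn(grid, K_conn=max(design.K_values), sigma=design.sigma,
                              seed=design.master_seed, mode=design.network_mode,
                              env=env, fc=fc)
    peak = estimate_global_peak(
        base, rng=np.random.default_rng(child_seed(design.master_seed, _TAG_PEAK)))

    if start_genotypes is None:
        start_genotypes = {}
        for f0 in design.start_fitnesses:
            rng = np.random.default_rng(
                child_seed(design.master_seed, _TAG_START, _start_key(f0)))
            start_genotypes[f0] = find_start_genotype(
                f0, base, tol=design.start_tol, rng=rng)

    rows = []
    ensembles: dict[tuple[int, float], EnsembleResult] = {}
    mean_degrees: dict[int, float] = {}
    for K in design.K_values:
        land = Landscape.from_grn(grid, K_conn=K, sigma=design.sigma,
                                  seed=design.master_seed, mode=design.network_mode,
                                  env=env, fc=fc)
        mean_degrees[K] = float(np.mean([n.mean_degree for n in land.networks]))
        for f0 in design.start_fitnesses:
            res = run_ensemble(land, start_genotypes[f0], K, f0, peak.fitness,
                               design.n_replicates, design.master_seed,
                               design.reach_tol, design.resample_networks)
            if keep_ensembles:
                ensembles[(K, f0)] = res
            reached = res.reached_global
            rows.append({
                "K": K,
                "start_F": f0,
                "fraction_reached_global": res.fraction_reached_global,
                "n_replicates": res.n_replicates,
                "n_unreached": int((~reached).sum()),
                "mean_steps_reached": float(res.steps_to_peak[reached].mean())
                if reached.any() else np.nan,
                "mean_terminal_fitness": float(res.terminal_fitness.mean()),
            })
            if progress:
                print(f"K={K:3d} start_F={f0:.4f} "
                      f"fraction={rows[-1]['fraction_reached_global']:.2f}")
    table = pd.DataFrame(rows)
    transition = _transition_K(table, design.reach_threshold)
    midpoint = _midpoint_K(table)
    return ScanResult(table, transition, midpoint, ensembles, peak,
                      start_genotypes, mean_degrees)


def _transition_K(table: pd.DataFrame, threshold: float) -> int | None:
    by_k = table.groupby("K")["fraction_reached_global"].min().sort_index()
    ok = by_k[by_k >= threshold]
    return int(ok.index[0]) if len(ok) else None


def _midpoint_K(table: pd.DataFrame) -> float | None:
    """Interpolated K at which the start-averaged reach fraction crosses 1/2."""
    by_k = table.groupby("K")["fraction_reached_global"].mean().sort_index()
    ks = by_k.index.to_numpy(dtype=float)
    fr = by_k.to_numpy()
    above = np.flatnonzero(fr >= 0.5)
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(ks[0])
    k0, k1, f0, f1 = ks[i - 1], ks[i], fr[i - 1], fr[i]
    return float(k0 + (0.5 - f0) * (k1 - k0) / (f1 - f0))


def steps_to_peak_summary(results: dict[tuple[int, float], EnsembleResult]) -> pd.DataFrame:
    """Mean accepted mutations to the global peak per design point.

    Replicates that terminate on a local optimum never reach the global
    peak (their mutation count to it is infinite); they are excluded from
    the mean and reported in ``n_unreached``.
    """
    rows = []
    for (K, f0), res in sorted(results.items()):
        reached = res.reached_global
        rows.append({
            "K": K, "start_F": f0,
            "mean_steps": float(res.steps_to_peak[reached].mean()) if reached.any() else np.nan,
            "n_reached": int(reached.sum()),
            "n_unreached": int((~reached).sum()),
        })
    return pd.DataFrame(rows)


def speed_of_evolution(results: dict[tuple[int, float], EnsembleResult]) -> pd.DataFrame:
    """Peak per-step gain of ensemble-mean fitness per design point.

    The returned frame has one row per design point with the peak speed and
    the step at which it occurs; the full series is in ``EnsembleResult``.
    """
    rows = []
    for (K, f0), res in sorted(results.items()):
        sp = res.speed_series
        if len(sp) == 0:
            peak_speed, at = 0.0, 0
        else:
            at = int(np.argmax(sp))
            peak_speed = float(sp[at])
        rows.append({"K": K, "start_F": f0, "peak_speed": peak_speed, "peak_speed_step": at})
    df = pd.DataFrame(rows)
    df["is_fastest_start"] = False
    for K, sub in df.groupby("K"):
        df.loc[sub["peak_speed"].idxmax(), "is_fastest_start"] = True
    return df


def variance_dynamics(results: dict[tuple[int, float], EnsembleResult]) -> pd.DataFrame:
    """Between-replicate fitness variance dynamics per design point."""
    rows = []
    for (K, f0), res in sorted(results.items()):
        v = res.var_fitness_series
        rows.append({
            "K": K, "start_F": f0,
            "peak_variance": float(v.max()),
            "peak_variance_step": int(np.argmax(v)),
            "terminal_variance": float(v[-1]),
            "initial_variance": float(v[0]),
        })
    return pd.DataFrame(rows)


#: The sensitivity scan's scenarios: multipliers applied to (a, b, alpha).
SENSITIVITY_SCENARIOS: dict[str, tuple[float, float, float]] = {
    "base": (1.0, 1.0, 1.0),
    "a_x10": (10.0, 1.0, 1.0),
    "alpha_x10": (1.0, 1.0, 10.0),
    "b_x10": (1.0, 10.0, 1.0),
    "b_div10": (1.0, 0.1, 1.0),
}


def fitness_function_sensitivity(
    design: ExperimentDesign,
    grid: ParameterGrid,
    env: EnvSignal = EnvSignal(),
    fc: FitnessConstants = FitnessConstants(),
    scenarios: dict[str, tuple[float, float, float]] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Repeat the critical-K scan under rescaled benefit/cost constants.

    Each scenario multiplies ``(a, b, alpha)``; the walk starts from the
    same genotypes as the base scan (the same points in parameter space,
    re-scored under the new constants), and the question is whether the
    inferred transition connectivity moves.  Returns one row per scenario
    with its transition K and per-K minimum reach fractions.
    """
    if scenarios is None:
        scenarios = SENSITIVITY_SCENARIOS
    base_scan = critical_k_scan(design, grid, env, fc, keep_ensembles=False,
                                progress=progress)
    rows = []
    for name, (am, bm, cm) in scenarios.items():
        if (am, bm, cm) == (1.0, 1.0, 1.0):
            scan = base_scan
        else:
            scan = critical_k_scan(
                design, grid, env, fc.scaled(am, bm, cm),
                start_genotypes=base_scan.start_genotypes,
                keep_ensembles=False, progress=progress)
        fr = scan.table.groupby("K")["fraction_reached_global"].min()
        row = {"scenario": name, "a_mult": am, "b_mult": bm, "alpha_mult": cm,
               "transition_K": scan.transition_K,
               "midpoint_K": scan.midpoint_K,
               "global_fitness": scan.peak.fitness}
        row.update({f"min_fraction_K{K}": float(v) for K, v in fr.items()})
        rows.append(row)
    return pd.DataFrame(rows)
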