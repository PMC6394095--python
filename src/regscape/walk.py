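"""Greedy adaptive walks on the genotype graph.

A walk starts from a genotype, evaluates the fitness of every one-mutant
neighbor, and moves to one chosen uniformly at random among the *strictly*
beneficial ones.  It halts when no neighbor improves fitness — a local (or
the global) optimum.  The regime is selection-dominated: no drift, no
fixation of deleterious or neutral mutations, and the chance of fixing a
beneficial mutation does not depend on its effect size.

Termination is guaranteed: fitness takes finitely many values on the finite
grid and increases strictly at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape, neighbor_genotype_array

__all__ = ["WalkStep", "Trajectory", "StartSearchError", "adaptive_walk",
           "find_start_genotype"]


@dataclass(frozen=True)
class WalkStep:
    """One accepted mutation (or the start, for ``step_index`` 0)."""

    genotype: tuple[int, ...]
    fitness: float
    mutated_param: int | None
    step_index: int


@dataclass
class Trajectory:
    """An adaptive walk's record: strictly increasing fitness, ending at a
    genotype with no beneficial one-mutant neighbor."""

    steps: list[WalkStep]
    terminal: bool
    seed: object = None

    @property
    def n_steps(self) -> int:
        """Number of accepted mutations (the start is step 0)."""
        return len(self.steps) - 1

    @property
    def final(self) -> WalkStep:
        return self.steps[-1]

    def fitness_series(self) -> np.ndarray:
        return np.array([s.fitness for s in self.steps])


def trajectory_table(traj: Trajectory, landscape: Landscape):
    """Tabulate a trajectory: one row per accepted step, with the genotype's
    level indices, parameter values, steady state and fitness components."""
    import pandas as pd

    from .grn import batch_fitness
    from .landscape import PARAM_NAMES

    G = np.array([s.genotype for s in traj.steps], dtype=np.int64)
    rows = {"step_index": [s.step_index for s in traj.steps],
            "mutated_param": [s.mutated_param for s in traj.steps]}
    for p in range(landscape.n_params):
        rows[f"level_{p}"] = G[:, p]
    if landscape.grid is not None:
        P = landscape.grid.params_of(G)
        for p, name in enumerate(landscape.grid.names):
            rows[name] = P[:, p]
        comp = batch_fitness(P, landscape.env.S, landscape.fc, landscape.kr_ratio,
                             components=True)
        for key in ("R", "R_star", "T", "B", "C", "F"):
            rows[key] = comp[key]
    else:
        rows["F"] = [s.fitness for s in traj.steps]
    return pd.DataFrame(rows)


class StartSearchError(RuntimeError):
    """No genotype with fitness near the requested target was found."""

    def __init__(self, target: float, best_genotype, best_fitness: float):
        self.target = target
        self.best_genotype = best_genotype
        self.best_fitness = best_fitness
        super().__init__(
            f"no genotype within tolerance of target fitness {target}; "
            f"best found F={best_fitness} at {tuple(best_genotype)}"
        )


def adaptive_walk(
    start,
    landscape: Landscape,
    rng: np.random.Generator | int | None = None,
    max_steps: int = 1_000_000,
) -> Trajectory:
    """Run one greedy adaptive walk from ``start`` to a fitness optimum.

    At each step all one-mutant neighbors are evaluated; the move target is
    drawn uniformly among those with strictly greater fitness.  Equal-fitness
    neighbors are neither moves nor obstacles to termination.  Identical
    ``(landscape, start, rng seed)`` give bit-identical trajectories.

    ``max_steps`` is a safety guard only; strictly increasing fitness on a
    finite graph halts every walk long before a correctly sized budget.
    """
    rng = np.random.default_rng(rng)
    g = np.asarray(start, dtype=np.int64).copy()
    if g.shape != (landscape.n_params,):
        raise ValueError(f"genotype must have {landscape.n_params} coordinates")
    for p, net in enumerate(landscape.networks):
        if not 0 <= g[p] < net.n_levels:
            raise ValueError(f"coordinate {p} out of range: {g[p]}")
    f = float(landscape.fitness_of(g))
    steps = [WalkStep(tuple(int(x) for x in g), f, None, 0)]
    for step_index in range(1, max_steps + 1):
        G, param_idx = neighbor_genotype_array(g, landscape.networks)
        fits = landscape.fitness_of(G)
        better = np.flatnonzero(fits > f)
        if better.size == 0:
            return Trajectory(steps, terminal=True)
        choice = better[rng.integers(better.size)]
        g = G[choice]
        f = float(fits[choice])
        assert f > steps[-1].fitness
        steps.append(WalkStep(tuple(int(x) for x in g), f, int(param_idx[choice]),
                              step_index))
    raise RuntimeError(f"walk exceeded the {max_steps}-step budget (implementation bug)")


def find_start_genotype(
    target_F: float,
    landscape: Landscape,
    tol: float = 1e-3,
    rng: np.random.Generator | int | None = None,
    n_samples: int = 200_000,
    batch: int = 20_000,
    max_refine_rounds: int = 50,
) -> tuple[int, ...]:
    """Find a genotype whose fitness is within ``tol`` of ``target_F``.

    Rejection-samples random genotypes, then refines the best candidate by
    coordinate descent on ``|F - target|`` (each round scans every level of
    every parameter, all other coordinates held fixed).  Deterministic given
    the seeded ``rng``.  Raises :class:`StartSearchError`, reporting the
    best candidate, if the target cannot be approached within budget.
    """
    rng = np.random.default_rng(rng)
    shape = landscape.shape
    D = landscape.n_params

    best_g = None
    best_err = np.inf
    for _ in range(max(1, n_samples // batch)):
        G = np.column_stack([rng.integers(n, size=batch) for n in shape])
        err = np.abs(landscape.fitness_of(G) - target_F)
        i = int(np.argmin(err))
        if err[i] < best_err:
            best_err = float(err[i])
            best_g = G[i].copy()
        if best_err <= tol:
            break

    # coordinate descent: replace one coordinate at a time by the level that
    # brings fitness closest to the target
    for _ in range(max_refine_rounds):
        if best_err <= tol:
            break
        improved = False
        for p in rng.permutation(D):
            n = shape[p]
            cand = np.tile(best_g, (n, 1))
            cand[:, p] = np.arange(n)
            err = np.abs(landscape.fitness_of(cand) - target_F)
            j = int(np.argmin(err))
            if err[j] < best_err:
                best_err = float(err[j])
                best_g = cand[j].copy()
                improved = True
        if not improved:
            break

    if best_err > tol:
        raise StartSearchError(target_F, best_g, float(landscape.fitness_of(best_g)))
    return tuple(int(x) for x in best_g)
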