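"""Tiny, exhaustively analyzable landscapes used as test oracles.

Each fixture bundles a toy landscape (at most a few hundred genotypes) with
the exact truth about greedy walks on it — local optima, basins, reach
probabilities and expected step counts from the absorbing-chain analysis —
so Monte-Carlo ensemble code can be validated against closed-form answers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grn import EnvSignal, FitnessConstants
from .landscape import (GridConfig, Landscape, NeighborNetwork, ParamRange,
                        build_grid, complete_network)
from .markov import ChainAnalysis, analyze_chain

__all__ = ["ToyLandscapeFixture", "make_toy_fixture", "TOY_KINDS"]

#: Exhaustive-analysis budget for fixtures (genotypes).
MAX_FIXTURE_STATES = 20_000


@dataclass
class ToyLandscapeFixture:
    """A small landscape plus its precomputed exhaustive walk truth."""

    name: str
    landscape: Landscape
    truth: ChainAnalysis

    @property
    def local_optima(self) -> list[tuple[int, ...]]:
        return self.truth.optima

    @property
    def global_optimum(self) -> tuple[int, ...]:
        return self.truth.global_optimum


def _single_peak_table(shape: tuple[int, ...]) -> np.ndarray:
    """Concave, single-peaked table: fitness falls with distance from the
    centre genotype, with a small index-dependent tie-breaking tilt."""
    centre = np.array([(n - 1) / 2 for n in shape])
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    tilt = sum(g * 10.0 ** (-4 - i) for i, g in enumerate(grids))
    return 1.0 - 0.01 * dist2 + tilt


def _two_peak_table(shape: tuple[int, ...]) -> np.ndarray:
    """Two unequal peaks at opposite corners, separated by a valley."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    lo_corner = sum(((n - 1 - g) / (n - 1)) ** 2 for g, n in zip(grids, shape))
    hi_corner = sum((g / (n - 1)) ** 2 for g, n in zip(grids, shape))
    major = 1.0 * np.exp(-1.5 * lo_corner)
    minor = 0.6 * np.exp(-1.5 * hi_corner)
    return np.maximum(major, minor)


def _path_network(n: int) -> NeighborNetwork:
    """Nearest-index adjacency: levels form a path graph."""
    adj = []
    for i in range(n):
        nb = [j for j in (i - 1, i + 1) if 0 <= j < n]
        adj.append(np.array(nb, dtype=np.int64))
    return NeighborNetwork(adj, K_conn=1, sigma=0.5, mode="union", seed=None)


TOY_KINDS = ("three_level_1d", "single_peak", "two_peak", "grn_tiny")


def make_toy_fixture(
    kind: str = "single_peak",
    shape: tuple[int, ...] = (5, 5),
    complete: bool = True,
    seed: int = 0,
) -> ToyLandscapeFixture:
    """Build a named toy landscape with its exhaustive walk analysis.

    Kinds: ``three_level_1d`` (one parameter, fitness 0.1/0.3/0.2 — the
    middle level is the unique optimum); ``single_peak`` (concave table,
    unique optimum); ``two_peak`` (major and minor peak at opposite corners;
    with nearest-neighbor connectivity some starts are trapped at the minor
    peak); ``grn_tiny`` (the transcription-network fitness on a tiny grid).
    """
    if int(np.prod(shape)) > MAX_FIXTURE_STATES:
        raise ValueError(f"{shape} exceeds the fixture enumeration budget")
    if kind == "three_level_1d":
        land = Landscape.from_table(np.array([0.1, 0.3, 0.2]))
    elif kind == "single_peak":
        table = _single_peak_table(shape)
        nets = [complete_network(n) if complete else _path_network(n) for n in shape]
        land = Landscape.from_table(table, nets)
    elif kind == "two_peak":
        table = _two_peak_table(shape)
        nets = [(complete_network(n) if complete else _path_network(n)) for n in shape]
        land = Landscape.from_table(table, nets)
    elif kind == "grn_tiny":
        if len(shape) > 3:
            raise ValueError("grn_tiny supports at most 3 evolvable parameters")
        # evolve the first len(shape) parameters on a tiny grid, freeze the rest
        from .landscape import DEFAULT_RANGES
        ranges = tuple(DEFAULT_RANGES[: len(shape)])
        cfg = GridConfig(ranges=ranges, n_levels=max(shape), seed=seed)
        grid = build_grid(cfg)
        # mixed shapes are not needed for the oracle; use a uniform tiny grid
        table = _grn_table(grid, shape)
        land = Landscape.from_table(table)
    else:
        raise ValueError(f"unknown toy kind {kind!r}; one of {TOY_KINDS}")
    return ToyLandscapeFixture(kind, land, analyze_chain(land))


def _grn_table(grid, shape: tuple[int, ...]) -> np.ndarray:
    """Transcription-network fitness on a tiny grid, the non-evolved
    parameters pinned at mid-range defaults."""
    from .grn import batch_fitness
    from .landscape import DEFAULT_RANGES

    fixed = {r.name: float(np.sqrt(r.min * r.max)) for r in DEFAULT_RANGES}
    idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    flat = np.stack([i.ravel() for i in idx], axis=-1)
    P = np.empty((flat.shape[0], 6))
    for col, r in enumerate(DEFAULT_RANGES):
        if col < len(shape):
            P[:, col] = grid.values[col, flat[:, col]]
        else:
            P[:, col] = fixed[r.name]
    return batch_fitness(P).reshape(shape)
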