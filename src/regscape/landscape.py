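"""Discretized parameter grid and per-parameter mutational neighbor networks.

Each biochemical parameter is restricted to ``n_levels`` discrete values
(default 1000) drawn once, at random, between a physiological minimum and
maximum and then sorted.  A mutation moves one parameter to one of the
levels adjacent to its current level in that parameter's *neighbor network*:
an undirected graph over level indices in which each level draws ``K_conn``
distinct partners with probability proportional to a Gaussian kernel (width
``sigma``, in index units) centred on itself, and edges are then
symmetrized.  ``K_conn`` — the connectivity — is the central control
variable of the simulations: it sets how coarse or fine the mutational steps
along each parameter axis can be.

A :class:`Landscape` bundles the value grid and the six networks (or, for
toy landscapes used as exhaustive test oracles, an explicit fitness table)
and exposes vectorized genotype-fitness evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .grn import (
    DEFAULT_KR_RATIO,
    EnvSignal,
    FitnessConstants,
    PARAM_NAMES,
    ParamSet,
    batch_fitness,
)

__all__ = [
    "ParamRange",
    "GridConfig",
    "ParameterGrid",
    "NeighborNetwork",
    "Landscape",
    "DEFAULT_RANGES",
    "build_grid",
    "build_neighbors",
    "one_mutant_neighbors",
]

Genotype = tuple[int, ...]


@dataclass(frozen=True)
class ParamRange:
    """Permissible range for one parameter and its sampling scale."""

    name: str
    min: float
    max: float
    scale: str = "log"  # "log" or "linear"

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"{self.name}: need min < max, got [{self.min}, {self.max}]")
        if self.scale not in ("log", "linear"):
            raise ValueError(f"{self.name}: scale must be 'log' or 'linear'")
        if self.scale == "log" and self.min <= 0:
            raise ValueError(f"{self.name}: log scale needs min > 0")


#: Default ranges for the six evolvable parameters (nM / minute units),
#: spanning the decades reported for bacterial transcription networks:
#: production rates from leaky expression (~1e-3 nM/min) to strong-promoter
#: output (~2 nM/min), first-order removal rates from dilution-dominated
#: (half-life ~70 min) to actively degraded (half-life ~40 s), operator
#: affinities from tight (1 nM) to weak (100 nM) sites.  Rate constants vary
#: over orders of magnitude, so all are sampled log-uniformly.  These spans
#: keep steady-state protein levels within physiological abundances (up to a
#: few hundred nM) and give the fitness a unique, well-separated optimum on
#: the grid, so "reached the global peak" is a sharp event.  Fully
#: overridable from configuration.
DEFAULT_RANGES: tuple[ParamRange, ...] = (
    ParamRange("bas", 1e-3, 0.1, "log"),
    ParamRange("k_act", 1e-2, 1.0, "log"),
    ParamRange("k_d", 1e-2, 1.0, "log"),
    ParamRange("beta", 2e-2, 2.0, "log"),
    ParamRange("K_m", 1.0, 1e2, "log"),
    ParamRange("k_dT", 1e-2, 1.0, "log"),
)


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the discrete value grid."""

    ranges: tuple[ParamRange, ...] = DEFAULT_RANGES
    n_levels: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 3:
            raise ValueError("n_levels must be >= 3")
        names = [r.name for r in self.ranges]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in ranges")


@dataclass(frozen=True)
class ParameterGrid:
    """Sorted tables of permissible discrete values, one row per parameter.

    ``values[p]`` is strictly increasing, of length ``n_levels``, and its
    first/last entries are the configured min/max.
    """

    names: tuple[str, ...]
    values: np.ndarray  # shape (n_params, n_levels)
    config: GridConfig

    @property
    def n_params(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]

    def params_of(self, genotypes: np.ndarray) -> np.ndarray:
        """Map an ``(..., n_params)`` array of level indices to values."""
        g = np.asarray(genotypes)
        return self.values[np.arange(self.n_params), g]


def build_grid(cfg: GridConfig) -> ParameterGrid:
    """Draw the discrete value tables: endpoints plus ``n_levels - 2`` unique
    uniform draws on each parameter's sampling scale, sorted ascending."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x67726964)))
    rows = []
    for pr in cfg.ranges:
        lo, hi = pr.min, pr.max
        if pr.scale == "log":
            lo, hi = np.log(lo), np.log(hi)
        interior: set[float] = set()
        # collision re-draws; measure-zero event for float uniforms
        while len(interior) < cfg.n_levels - 2:
            draws = rng.uniform(lo, hi, size=cfg.n_levels - 2 - len(interior))
            interior.update(float(d) for d in draws if lo < d < hi)
        vals = np.sort(np.array([lo, hi] + list(interior)))
        if pr.scale == "log":
            vals = np.exp(vals)
            vals[0], vals[-1] = pr.min, pr.max  # exact endpoints
        if not np.all(np.diff(vals) > 0):
            raise RuntimeError(f"grid for {pr.name} not strictly increasing")
        rows.append(vals)
    return ParameterGrid(tuple(r.name for r in cfg.ranges), np.vstack(rows), cfg)


class NeighborNetwork:
    """Undirected adjacency among the discrete levels of one parameter.

    Stored in compressed sparse row form for fast lookup in the walk's inner
    loop: ``indices[indptr[i]:indptr[i+1]]`` are the (sorted) neighbors of
    level ``i``.
    """

    def __init__(self, adjacency: Sequence[np.ndarray], K_conn: int, sigma: float,
                 mode: str, seed: object):
        sorted_rows = [np.sort(np.asarray(a, dtype=np.int64)) for a in adjacency]
        self._init_csr(
            np.concatenate([[0], np.cumsum([len(a) for a in sorted_rows])]),
            np.concatenate(sorted_rows) if sorted_rows else np.empty(0, np.int64),
            K_conn, sigma, mode, seed)

    @classmethod
    def from_csr(cls, indptr: np.ndarray, indices: np.ndarray, K_conn: int,
                 sigma: float, mode: str, seed: object) -> "NeighborNetwork":
        self = cls.__new__(cls)
        self._init_csr(indptr, indices, K_conn, sigma, mode, seed)
        return self

    def _init_csr(self, indptr, indices, K_conn, sigma, mode, seed) -> None:
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64)
        self.n_levels = len(self.indptr) - 1
        self.K_conn = K_conn
        self.sigma = sigma
        self.mode = mode
        self.seed = seed
        self.degree = np.diff(self.indptr)

    def neighbors_of(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]: self.indptr[i + 1]]

    @property
    def mean_degree(self) -> float:
        return float(self.degree.mean())

    def edges(self) -> np.ndarray:
        """Undirected edge list, each edge once, as an (m, 2) array."""
        src = np.repeat(np.arange(self.n_levels), self.degree)
        keep = self.indices > src
        return np.stack([src[keep], self.indices[keep]], axis=1)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NeighborNetwork)
            and self.n_levels == other.n_levels
            and np.array_equal(self.indptr, other.indptr)
            and np.array_equal(self.indices, other.indices)
        )


def _kernel_probs(n_levels: int, i: int, sigma: float) -> np.ndarray:
    """Truncated, renormalized Gaussian kernel over levels j != i."""
    j = np.arange(n_levels)
    # floor the exponent so far tails stay nonzero (drawn only when K_conn
    # exceeds the number of levels with non-underflowing weight)
    w = np.exp(np.maximum(-0.5 * ((j - i) / sigma) ** 2, -700.0))
    w[i] = 0.0
    return w / w.sum()


def _draw_proposals(n_levels: int, K_conn: int, sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Each level's K_conn kernel-weighted draws without replacement.

    Uses the Gumbel top-k equivalence (the k largest ``log w + Gumbel``
    perturbations are an exact sample of sequential weighted draws without
    replacement), vectorized over all levels.  Only a band of ±8 sigma
    around each level is materialized; the kernel tail beyond it underflows
    the floored weight used by :func:`_kernel_probs`, so the band is only
    widened — never re-weighted — when K_conn exceeds the band size.
    """
    # boundary levels see only W candidates, so the band must cover K_conn;
    # 6 sigma covers the kernel to relative mass < 1e-8
    W = min(n_levels - 1, max(int(np.ceil(6 * sigma)), K_conn))
    offsets = np.arange(-W, W + 1)
    centers = np.arange(n_levels)[:, None]
    j = centers + offsets[None, :]
    valid = (j >= 0) & (j < n_levels) & (offsets[None, :] != 0)
    keys = rng.gumbel(size=(n_levels, 2 * W + 1))
    keys += np.maximum(-0.5 * (offsets / sigma) ** 2, -700.0)[None, :]
    keys[~valid] = -np.inf
    top = np.argpartition(-keys, K_conn - 1, axis=1)[:, :K_conn]
    return np.take_along_axis(j, top, axis=1)


def _build_union_networks(n_levels: int, K_conn: int, sigma: float,
                          rng: np.random.Generator, n_params: int
                          ) -> list["NeighborNetwork"]:
    """Draw all parameters' union-mode networks in one vectorized pass.

    Distributionally identical to ``n_params`` independent
    :func:`build_neighbors` calls; batched so per-replicate network
    resampling in large ensembles stays cheap.
    """
    W = min(n_levels - 1, max(int(np.ceil(6 * sigma)), K_conn))
    offsets = np.arange(-W, W + 1)
    kernel = np.maximum(-0.5 * (offsets / sigma) ** 2, -87.0).astype(np.float32)

    # Gumbel top-k with inverted sign (smallest K keys win), float32 for
    # throughput; ties are measure-zero and only permute valid draws
    u = rng.random(size=(n_params * n_levels, 2 * W + 1), dtype=np.float32)
    with np.errstate(divide="ignore"):  # u == 0 yields +inf: candidate skipped
        keys = np.log(-np.log(u))
    keys -= kernel[None, :]
    keys[:, W] = np.inf  # no self-loops
    for p in range(n_params):  # out-of-range columns of the boundary rows
        base = p * n_levels
        for r in range(W):
            keys[base + r, : W - r] = np.inf
            keys[base + n_levels - 1 - r, W + 1 + r:] = np.inf
    top = np.argpartition(keys, K_conn - 1, axis=1)[:, :K_conn]
    centers = np.repeat(np.arange(n_levels)[None, :], n_params, axis=0).reshape(-1, 1)
    proposals = centers + offsets[top]

    src = np.tile(np.repeat(np.arange(n_levels), K_conn), n_params)
    par = np.repeat(np.arange(n_params), n_levels * K_conn)
    dst = proposals.reshape(n_params, -1).ravel()
    n2 = n_levels * n_levels
    key = np.concatenate([par * n2 + src * n_levels + dst,
                          par * n2 + dst * n_levels + src])
    key.sort()
    keep = np.empty(len(key), dtype=bool)
    keep[0] = True
    np.not_equal(key[1:], key[:-1], out=keep[1:])
    key = key[keep]

    nets = []
    bounds = np.searchsorted(key, np.arange(n_params + 1) * n2)
    for p in range(n_params):
        sub = key[bounds[p]: bounds[p + 1]] - p * n2
        row, col = np.divmod(sub, n_levels)
        indptr = np.concatenate([[0], np.cumsum(np.bincount(row, minlength=n_levels))])
        nets.append(NeighborNetwork.from_csr(indptr, col, K_conn, sigma,
                                             "union", None))
    return nets


def build_neighbors(
    n_levels: int,
    K_conn: int,
    sigma: float = 20.0,
    seed: object = 0,
    mode: str = "union",
) -> NeighborNetwork:
    """Build one parameter's mutational neighbor network.

    Each level ``i`` draws ``K_conn`` distinct partner levels with
    probability proportional to a Gaussian of width ``sigma`` (index units)
    centred on ``i``, truncated to the grid and renormalized.  Because
    adjacency must be symmetric, the per-level draws are then merged:

    - ``mode="union"`` (default): an edge exists if either endpoint drew it;
      degrees fall in ``[K_conn, ~2*K_conn]``.
    - ``mode="strict"``: the union's proposals are visited in random order
      and an edge is kept only if both endpoints still have degree below
      ``K_conn``; final degrees are <= K_conn, almost all exactly K_conn.
    """
    if not 1 <= K_conn <= n_levels - 1:
        raise ValueError(f"need 1 <= K_conn <= n_levels - 1, got {K_conn}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if mode not in ("union", "strict"):
        raise ValueError("mode must be 'union' or 'strict'")
    rng = np.random.default_rng(seed)
    proposals = _draw_proposals(n_levels, K_conn, sigma, rng)

    if mode == "union":
        src = np.repeat(np.arange(n_levels), K_conn)
        dst = proposals.ravel()
        a = np.concatenate([src, dst])
        b = np.concatenate([dst, src])
        # deduplicate mutually-drawn edges via a scalar key; sorting the key
        # also groups by source and sorts each adjacency row
        key = a * n_levels + b
        key.sort()
        keep = np.empty(len(key), dtype=bool)
        keep[0] = True
        np.not_equal(key[1:], key[:-1], out=keep[1:])
        key = key[keep]
        row, col = np.divmod(key, n_levels)
        indptr = np.concatenate([[0], np.cumsum(np.bincount(row, minlength=n_levels))])
        return NeighborNetwork.from_csr(indptr, col, K_conn, sigma, mode, seed)
    # strict mode: greedy degree-capped edge acceptance in random order
    adj: list[set[int]] = [set() for _ in range(n_levels)]
    edges = {(min(i, int(j)), max(i, int(j)))
             for i in range(n_levels) for j in proposals[i]}
    edge_list = sorted(edges)
    for idx in rng.permutation(len(edge_list)):
        i, j = edge_list[idx]
        if len(adj[i]) < K_conn and len(adj[j]) < K_conn:
            adj[i].add(j)
            adj[j].add(i)
    arrays = [np.fromiter(s, dtype=np.int64, count=len(s)) for s in adj]
    return NeighborNetwork(arrays, K_conn, sigma, mode, seed)


@dataclass
class Landscape:
    """A frozen fitness landscape: value grid + per-parameter networks.

    Fitness is either the transcription-network fitness evaluated on the
    grid (the production configuration) or an explicit per-genotype table
    (tiny toy landscapes used as exhaustive oracles in tests).
    """

    networks: list[NeighborNetwork]
    grid: ParameterGrid | None = None
    table: np.ndarray | None = None
    env: EnvSignal = field(default_factory=EnvSignal)
    fc: FitnessConstants = field(default_factory=FitnessConstants)
    kr_ratio: float = DEFAULT_KR_RATIO

    def __post_init__(self) -> None:
        if (self.grid is None) == (self.table is None):
            raise ValueError("exactly one of grid / table must be given")
        for p, net in enumerate(self.networks):
            if net.n_levels != self.shape[p]:
                raise ValueError(f"network {p} has {net.n_levels} levels, grid expects {self.shape[p]}")

    @property
    def n_params(self) -> int:
        return len(self.networks)

    @property
    def shape(self) -> tuple[int, ...]:
        if self.table is not None:
            return self.table.shape
        return (self.grid.n_levels,) * self.grid.n_params

    @classmethod
    def from_grn(
        cls,
        grid: ParameterGrid,
        K_conn: int,
        sigma: float = 20.0,
        seed: int | tuple[int, ...] = 0,
        mode: str = "union",
        env: EnvSignal = EnvSignal(),
        fc: FitnessConstants = FitnessConstants(),
        kr_ratio: float = DEFAULT_KR_RATIO,
    ) -> "Landscape":
        """Build the production landscape: one network per parameter, with
        per-parameter child seeds derived from ``(seed, K_conn, param)``."""
        entropy = seed if isinstance(seed, tuple) else (seed,)
        if mode == "union":
            rng = np.random.default_rng(
                np.random.SeedSequence((*entropy, 0x6e657473, K_conn)))
            nets = _build_union_networks(grid.n_levels, K_conn, sigma, rng,
                                         grid.n_params)
        else:
            nets = [
                build_neighbors(
                    grid.n_levels, K_conn, sigma,
                    seed=np.random.SeedSequence((*entropy, 0x6e657473, K_conn, p)),
                    mode=mode,
                )
                for p in range(grid.n_params)
            ]
        return cls(networks=nets, grid=grid, env=env, fc=fc, kr_ratio=kr_ratio)

    @classmethod
    def from_table(cls, table: np.ndarray, networks: list[NeighborNetwork] | None = None
                   ) -> "Landscape":
        """Toy landscape over an explicit fitness table; complete per-axis
        networks unless given."""
        table = np.asarray(table, dtype=float)
        if networks is None:
            networks = [complete_network(n) for n in table.shape]
        return cls(networks=networks, table=table)

    def fitness_of(self, genotypes: np.ndarray) -> np.ndarray:
        """Vectorized fitness of an ``(..., n_params)`` index array."""
        g = np.asarray(genotypes, dtype=np.int64)
        if self.table is not None:
            return self.table[tuple(g[..., p] for p in range(self.n_params))]
        return batch_fitness(self.grid.params_of(g), self.env.S, self.fc, self.kr_ratio)

    def genotype_paramset(self, genotype: Sequence[int]) -> ParamSet:
        if self.grid is None:
            raise ValueError("toy table landscape has no biochemical parameters")
        vals = self.grid.params_of(np.asarray(genotype))
        return ParamSet.from_evolvable(*vals, kr_ratio=self.kr_ratio)

    def with_fitness_constants(self, fc: FitnessConstants) -> "Landscape":
        """Same geometry, different benefit/cost constants."""
        return Landscape(self.networks, self.grid, self.table, self.env, fc, self.kr_ratio)

    # -- serialization ----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Freeze the landscape to a JSON/CSV bundle (values table + per-
        parameter edge lists) so it can be reloaded bit-exactly."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.grid is None:
            raise ValueError("only grid landscapes are serializable")
        meta = {
            "names": list(self.grid.names),
            "n_levels": self.grid.n_levels,
            "networks": [
                {"K_conn": n.K_conn, "sigma": n.sigma, "mode": n.mode,
                 "mean_degree": n.mean_degree}
                for n in self.networks
            ],
            "env": {"S": self.env.S},
            "fitness_constants": {"a": self.fc.a, "b": self.fc.b, "alpha": self.fc.alpha},
            "kr_ratio": self.kr_ratio,
        }
        (d / "landscape.json").write_text(json.dumps(meta, indent=2))
        np.savetxt(d / "grid_values.csv", self.grid.values.T, delimiter=",",
                   header=",".join(self.grid.names), comments="", fmt="%.17g")
        for p, net in enumerate(self.networks):
            np.savetxt(d / f"edges_{self.grid.names[p]}.csv", net.edges(),
                       delimiter=",", header="i,j", comments="", fmt="%d")

    @classmethod
    def load(cls, directory: str | Path) -> "Landscape":
        d = Path(directory)
        meta = json.loads((d / "landscape.json").read_text())
        values = np.loadtxt(d / "grid_values.csv", delimiter=",", skiprows=1).T
        names = tuple(meta["names"])
        n_levels = meta["n_levels"]
        ranges = tuple(
            ParamRange(nm, float(values[p, 0]), float(values[p, -1]), "linear")
            for p, nm in enumerate(names)
        )
        grid = ParameterGrid(names, values, GridConfig(ranges, n_levels, seed=-1))
        nets = []
        for p, nm in enumerate(names):
            ed = np.loadtxt(d / f"edges_{nm}.csv", delimiter=",", skiprows=1,
                            dtype=np.int64).reshape(-1, 2)
            adj: list[set[int]] = [set() for _ in range(n_levels)]
            for i, j in ed:
                adj[i].add(int(j))
                adj[int(j)].add(int(i))
            nm_meta = meta["networks"][p]
            nets.append(NeighborNetwork(
                [np.fromiter(s, dtype=np.int64, count=len(s)) for s in adj],
                nm_meta["K_conn"], nm_meta["sigma"], nm_meta["mode"], seed=None))
        env = EnvSignal(**meta["env"])
        fc = FitnessConstants(**meta["fitness_constants"])
        return cls(networks=nets, grid=grid, env=env, fc=fc, kr_ratio=meta["kr_ratio"])


def complete_network(n_levels: int) -> NeighborNetwork:
    """Fully connected adjacency (every other level one mutation away)."""
    adj = [np.array([j for j in range(n_levels) if j != i], dtype=np.int64)
           for i in range(n_levels)]
    return NeighborNetwork(adj, K_conn=n_levels - 1, sigma=np.inf, mode="union", seed=None)


def one_mutant_neighbors(genotype: Sequence[int], networks: Sequence[NeighborNetwork]
                         ) -> list[Genotype]:
    """All genotypes one accepted mutation away from ``genotype``.

    A one-mutant neighbor differs in exactly one coordinate, whose new level
    is adjacent to the old one in that parameter's network; there are
    ``sum_p degree(g_p)`` of them.
    """
    g = tuple(int(x) for x in genotype)
    out: list[Genotype] = []
    for p, net in enumerate(networks):
        for j in net.neighbors_of(g[p]):
            out.append(g[:p] + (int(j),) + g[p + 1:])
    return out


def neighbor_genotype_array(genotype: np.ndarray, networks: Sequence[NeighborNetwork]
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized neighbor enumeration for the walk's inner loop.

    Returns ``(G, param_idx)`` where ``G`` is an ``(m, n_params)`` index
    array of all one-mutant neighbors and ``param_idx[r]`` is the mutated
    coordinate of row ``r``.
    """
    D = len(networks)
    blocks = []
    params = []
    for p, net in enumerate(networks):
        js = net.neighbors_of(int(genotype[p]))
        if len(js) == 0:
            continue
        block = np.tile(genotype, (len(js), 1))
        block[:, p] = js
        blocks.append(block)
        params.append(np.full(len(js), p, dtype=np.int64))
    if not blocks:
        return np.empty((0, D), dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.vstack(blocks), np.concatenate(params)
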