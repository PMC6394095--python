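"""Exact analysis of the adaptive walk as an absorbing Markov chain.

On landscapes small enough to enumerate, the greedy walk is a Markov chain
on the genotype set: from a non-optimum, the chain moves to each strictly
beneficial one-mutant neighbor with equal probability; local optima are
absorbing.  Absorption probabilities and expected hitting times then follow
from linear algebra, giving an exact, simulation-free ground truth for the
Monte-Carlo walk ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .landscape import Landscape

__all__ = ["ChainAnalysis", "enumerate_genotypes", "local_optima", "analyze_chain"]

#: Refuse exhaustive analysis above this many genotypes.
MAX_STATES = 200_000


@dataclass
class ChainAnalysis:
    """Exact walk statistics for every genotype of a small landscape.

    ``absorb_prob[s, m]`` is the probability that a walk started at genotype
    ``s`` (flat index) terminates at local optimum ``m`` (index into
    ``optima``); ``expected_steps[s]`` is the expected number of accepted
    mutations before absorption.
    """

    shape: tuple[int, ...]
    fitness: np.ndarray          # flat, length n_states
    optima: list[tuple[int, ...]]
    global_optimum: tuple[int, ...]
    absorb_prob: np.ndarray      # (n_states, n_optima)
    expected_steps: np.ndarray   # (n_states,)

    def flat(self, genotype: Sequence[int]) -> int:
        return int(np.ravel_multi_index(tuple(genotype), self.shape))

    def p_reach_global(self, genotype: Sequence[int]) -> float:
        m = self.optima.index(self.global_optimum)
        return float(self.absorb_prob[self.flat(genotype), m])

    def basin_of(self, genotype: Sequence[int]) -> tuple[int, ...]:
        """The almost-sure terminal optimum, when unique; else raises."""
        row = self.absorb_prob[self.flat(genotype)]
        m = int(np.argmax(row))
        if not np.isclose(row[m], 1.0):
            raise ValueError("genotype has a stochastic basin membership")
        return self.optima[m]


def enumerate_genotypes(shape: Sequence[int]) -> list[tuple[int, ...]]:
    return list(product(*(range(n) for n in shape)))


def local_optima(landscape: Landscape) -> list[tuple[int, ...]]:
    """All genotypes with no strictly fitter one-mutant neighbor."""
    from .landscape import one_mutant_neighbors

    shape = landscape.shape
    _check_size(shape)
    out = []
    for g in enumerate_genotypes(shape):
        f = float(landscape.fitness_of(np.asarray(g)))
        nbrs = one_mutant_neighbors(g, landscape.networks)
        if all(float(landscape.fitness_of(np.asarray(h))) <= f for h in nbrs):
            out.append(g)
    return out


def analyze_chain(landscape: Landscape) -> ChainAnalysis:
    """Exact absorption probabilities and expected step counts.

    Orders states so absorbing ones come last, then solves the standard
    absorbing-chain systems ``(I - Q) B = R`` and ``(I - Q) t = 1``.
    """
    from .landscape import neighbor_genotype_array

    shape = landscape.shape
    n_states = _check_size(shape)
    D = landscape.n_params

    all_g = np.array(enumerate_genotypes(shape), dtype=np.int64)
    fit = landscape.fitness_of(all_g)

    # transition structure
    rows_t: list[list[int]] = []
    absorbing: list[int] = []
    for s in range(n_states):
        G, _ = neighbor_genotype_array(all_g[s], landscape.networks)
        nf = landscape.fitness_of(G)
        better = G[nf > fit[s]]
        if better.shape[0] == 0:
            absorbing.append(s)
            rows_t.append([])
        else:
            rows_t.append([int(np.ravel_multi_index(tuple(h), shape)) for h in better])

    transient = [s for s in range(n_states) if rows_t[s]]
    t_index = {s: i for i, s in enumerate(transient)}
    a_index = {s: i for i, s in enumerate(absorbing)}
    nt, na = len(transient), len(absorbing)

    Q = np.zeros((nt, nt))
    R = np.zeros((nt, na))
    for s in transient:
        ts = rows_t[s]
        p = 1.0 / len(ts)
        for h in ts:
            if h in t_index:
                Q[t_index[s], t_index[h]] += p
            else:
                R[t_index[s], a_index[h]] += p

    ImQ = np.eye(nt) - Q
    B = np.linalg.solve(ImQ, R) if nt else np.zeros((0, na))
    t = np.linalg.solve(ImQ, np.ones(nt)) if nt else np.zeros(0)

    absorb = np.zeros((n_states, na))
    steps = np.zeros(n_states)
    for s in absorbing:
        absorb[s, a_index[s]] = 1.0
    for s in transient:
        absorb[s] = B[t_index[s]]
        steps[s] = t[t_index[s]]

    optima = [tuple(int(x) for x in all_g[s]) for s in absorbing]
    global_opt = optima[int(np.argmax([fit[s] for s in absorbing]))]
    return ChainAnalysis(tuple(shape), fit, optima, global_opt, absorb, steps)


def _check_size(shape: Sequence[int]) -> int:
    n = int(np.prod(shape))
    if n > MAX_STATES:
        raise ValueError(f"{n} genotypes exceeds the exhaustive-analysis budget")
    return n
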