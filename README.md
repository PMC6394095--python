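# regscape

Adaptive walks of a two-gene transcription network on a discretized
six-parameter fitness landscape.

## The problem

How connected must a genotype space be for natural selection to find the
global fitness optimum? `regscape` studies this question on the simplest
bacterial signal-response circuit: a regulator `R`, activated by a constant
signal into `R*`, which drives expression of a target protein `T`:

    dR/dt  = bas − k_act·R·S + k_r·R* − k_d·R
    dR*/dt = k_act·R·S − k_r·R* − k_d·R*
    dT/dt  = beta·R*²/(K_m² + R*²) − k_dT·T

Fitness is benefit minus expression cost at steady state,

    F = a·T/(T+b) − alpha·(T + R* + R),

so every point in the six-dimensional biochemical parameter space
(`bas, k_act, k_d, beta, K_m, k_dT`) has a fitness: a *fitness landscape over
parameters* rather than over sequences. Each parameter is restricted to 1000
discrete levels drawn between physiological bounds, and a mutation moves one
parameter to one of `K` levels adjacent under a Gaussian kernel (σ = 20
levels) — `K`, the *connectivity*, is the central control variable.
Evolution is modelled as a greedy adaptive walk: repeatedly jump to a
uniformly chosen strictly-fitter one-mutant neighbor until none exists.

The package is for researchers in molecular evolution and systems biology who
want a reproducible, exactly-testable implementation of this landscape class:
it provides the closed-form steady-state/fitness model (with an ODE
cross-check), landscape and neighbor-network construction, seeded walk
ensembles with summary statistics (reach fraction, steps to peak, speed of
evolution, between-replicate variance), exact absorbing-Markov-chain oracles
on enumerable toy landscapes, and a CLI.

## Worked example

```python
import numpy as np
import regscape as rs
from regscape.experiments import estimate_global_peak, run_ensemble

# one parameter set: steady state and fitness
p = rs.ParamSet.from_evolvable(bas=0.05, k_act=0.5, k_d=0.05,
                               beta=1.0, K_m=5.0, k_dT=0.1)
ss = rs.steady_state(p)          # R = 0.0917 nM, R* = 0.9083 nM, T = 0.3194 nM
comp = rs.fitness(ss)            # B = 0.0310, C = 0.000033, F = 0.0309

# the default landscape at connectivity K = 50
grid = rs.build_grid(rs.GridConfig(seed=0))
land = rs.Landscape.from_grn(grid, K_conn=50, seed=0)
peak = estimate_global_peak(land, rng=0)
# global peak: F = 0.9467 at levels (999, 999, 0, 999, 0, 0)
# continuous cross-check: 0.9467 (agree: True)

# one adaptive walk from starting fitness 0.45
start = rs.find_start_genotype(0.45, land, tol=1e-3, rng=0)
traj = rs.adaptive_walk(start, land, rng=0)
# 74 accepted mutations -> terminal F = 0.9467

# a 100-replicate ensemble from the same start
res = run_ensemble(land, start, K=50, start_fitness_target=0.45,
                   global_fitness=peak.fitness, n_replicates=100,
                   master_seed=0)
# fraction reached = 1.00, mean steps = 67.1
```

Reading the numbers: this parameter set expresses almost no target
(T ≈ 0.32 nM against a half-benefit level of 10 nM), so its fitness is near
zero. The landscape's global optimum pins every parameter at the range end
favouring maximal activated expression of a cheap, high-affinity circuit
(F ≈ 0.947). At K = 50 — each parameter able to reach ~50 of its 1000 levels
per mutation — every one of 100 replicate walks finds that optimum, in ~67
accepted mutations on average. At low connectivity (K ≈ 3–5) walks trap at
local optima instead; the fraction reaching the peak rises from ~0 to ~1
around a critical connectivity of roughly 1% of the levels.

The CLI exposes the same machinery:

```sh
regscape scan --seed 0 --out results/        # full K x start-fitness sweep
regscape simulate --k 50 --start-f 0.45      # one ensemble, trajectory CSVs
regscape peak                                # dual-route global-peak estimate
regscape fixture --kind two_peak --shape 5,5 # exact toy-landscape truth
regscape plot --scan-dir results/
```

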