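# Methods

## The model

`regscape` simulates Darwinian movement of a minimal bacterial signal-response
circuit through the space of its own biochemical parameters. The circuit has a
regulator `R`, produced at a basal rate `bas`, converted by a constant
environmental signal `S` into its active form `R*` (rate constant `k_act`,
reverse rate `k_r`), and a target protein `T` activated by an `R*` dimer:

    dR/dt  = bas − k_act·R·S + k_r·R* − k_d·R
    dR*/dt = k_act·R·S − k_r·R* − k_d·R*
    dT/dt  = beta·R*² / (K_m² + R*²) − k_dT·T

Both regulator forms share the first-order removal rate `k_d`; the target has
its own `k_dT`. Because the signal is constant, fitness is evaluated at steady
state, which is available in closed form: the (R, R*) subsystem is linear, and
T follows explicitly. The closed form is the production path (a walk evaluates
millions of genotypes); numerical integration of the same equations
(`integrate_dynamics`, LSODA) exists purely as an independent cross-check and
agrees to better than 1e-6 relative across the default ranges.

Fitness is benefit minus cost at steady state:

    B = a·T/(T + b),    C = alpha·(T + R* + R),    F = B − C

with defaults a = 1 (benefit ceiling), b = 10 nM (half-saturation), and
alpha = 2.5e-5 per molecule — expression is useful but not free. `k_r` is not
independently evolvable; it is slaved to the activation rate as
k_r = 0.001·k_act (`kr_ratio`, configurable). The signal level defaults to
S = 1 and is configurable; all qualitative results hold for any fixed S > 0.

## The landscape

Each of the six evolvable parameters (`bas`, `k_act`, `k_d`, `beta`, `K_m`,
`k_dT`) takes one of `n_levels = 1000` discrete values: the range endpoints
plus 998 unique values drawn uniformly on the parameter's sampling scale (log
for all defaults), sorted ascending. A genotype is the vector of six level
indices; the genotype space has 1000⁶ points.

Mutations are local in level space. Each level draws `K_conn` distinct partner
levels with probability proportional to a Gaussian kernel of width sigma = 20
levels (2% of the grid) centred on itself — the kernel lives in index/rank
space, truncated to the grid (support limited to ±6 sigma; the mass beyond is
< 1e-8) and renormalized, with no wraparound. Because mutational adjacency
must be symmetric, the draws are merged: in the default `union` mode an edge
exists if either endpoint drew it (degrees fall in [K, ~2K]); the `strict`
mode instead caps degrees at exactly K by greedy edge acceptance in random
order. Sampling without replacement is implemented by the Gumbel top-k device,
which is distributionally identical to sequential kernel draws with rejection
of repeats. Realized mean degree is reported in run metadata.

### Default parameter ranges

The shipped ranges (units: nM and minutes, log-uniform sampling) are

| parameter | range | reading |
|---|---|---|
| bas | 1e-3 – 0.1 nM/min | leaky to moderate constitutive TF expression |
| k_act | 0.01 – 1 /min | slow to fast signal activation |
| k_d | 0.01 – 1 /min | dilution-dominated to actively degraded regulator |
| beta | 0.02 – 2 nM/min | weak to strong induced promoter |
| K_m | 1 – 100 nM | tight to weak operator affinity |
| k_dT | 0.01 – 1 /min | dilution-dominated to actively degraded target |

These spans keep steady-state protein levels within bacterial abundances (T up
to ~200 nM, active regulator up to ~10 nM) and were additionally chosen so
that the fitness optimum is *well-posed on a discrete grid*: at the optimum
every coordinate is either pinned at a range end or has a unique interior
argmax, with per-level fitness discrimination of at least ~1e-6. Range tables
whose optimum fixes only parameter *combinations* (for example the ratio
bas/k_d, which sets the active-regulator level) put the summit on a neutral
ridge of many coordinatewise maxima that one-mutation-at-a-time walks cannot
traverse; the central statistic of the whole experiment — the fraction of
walks whose terminal fitness equals the global-peak fitness — is then
ill-defined. The ranges are fully overridable from the YAML configuration,
and the two-estimator global-peak diagnostic (below) flags ill-posed custom
ranges.

With the defaults, the global optimum pushes `bas`, `k_act` and `beta` to
their maxima and `k_d`, `K_m`, `k_dT` to their minima (maximal activated
expression of a cheap, high-affinity circuit), with fitness ≈ 0.947.

## Adaptive walks

A walk starts from a genotype, scores all one-mutant neighbors (one per edge
per coordinate, ~6K of them), moves to one drawn uniformly among those with
*strictly* greater fitness, and stops when there is none — a local or global
optimum. Neutral neighbors are neither moves nor obstacles; since fitness
takes finitely many values and increases strictly, termination is guaranteed
(a 1e6-step guard exists but can only trip on bugs). The regime is
selection-dominated: no drift, no deleterious fixation, no effect-size
weighting of which beneficial mutation wins.

Start genotypes for a prescribed starting fitness are found by vectorized
rejection sampling over random genotypes followed by coordinate descent on
|F − target| (tolerance 1e-3 by default); failure raises an error carrying the
best candidate found.

## Ensembles and statistics

The default experiment design is the full study grid: connectivity
K ∈ {3, 5, 7, 10, 12, 15, 20, 50}, starting fitnesses
{0.0826, 0.2251, 0.45, 0.6264, 0.8526}, 100 replicates per design point. One
start genotype per starting fitness is shared across all K so that
connectivity comparisons are not confounded by start choice.

Every replicate redraws its own neighbor networks and walk randomness from a
stable child seed `SeedSequence((master, tag, K, start_key, replicate))`, so
any subset of design points reruns identically in any order. Resampling the
networks per replicate is the default because the reach fraction under a
single frozen realization is dominated by that realization's quirks near the
summit (measured: non-monotone fraction-vs-K jumps of 0.6 between adjacent K);
averaged over realizations the fraction is smooth and monotone in K.
`resample_networks=False` restores the frozen behaviour.

A replicate has **reached the global peak** when its terminal fitness equals
the estimated global-peak fitness within `reach_tol = 5e-5` — equality at the
four-decimal precision at which such fitness values are conventionally
reported. Demanding machine equality (1e-9) instead measures a different
event, exact genotype attainment: the last mutation onto an extreme level is
available only with probability ~1 − (1 − 0.02·d)^degree per coordinate, so
machine-exact attainment stays incomplete until K ≈ 35–50 on any landscape
with this kernel, regardless of biology. Both tolerances are configurable.

Reported statistics per design point:

- fraction of replicates reaching the global peak, and the inferred
  *transition connectivity*: the smallest tested K whose fraction is at least
  `reach_threshold = 0.95` for every start (threshold configurable);
- mutational events (accepted mutations) to the peak, averaged over replicates
  that reach it; non-reaching replicates are counted separately (their count
  to the global peak is infinite);
- mean-fitness and between-replicate-variance series over mutational events,
  with terminated replicates carrying their terminal fitness forward (the
  population sits at its peak), so the variance of an all-reaching design
  point converges to ~0 and that of a mixed one to a positive value;
- speed of evolution: the per-step gain of the ensemble-mean fitness, its
  peak, and which starting fitness maximizes that peak.

Two caveats on the transition statistics, measured on the shipped ranges.
First, the ensemble-averaged reach curve is a smooth sigmoid, so its 50%
crossing (midpoint) and its 0.95-saturation point differ substantially
(midpoint ≈ 6–10, saturation ≈ 20–50); both are reported, and "the"
transition connectivity means the midpoint unless stated otherwise. Second,
the curve shifts between grid realizations: across eight independent grid
draws the midpoint ranged 5.5–9.8 (mean ≈ 7.5). The mechanism is that the
random spacing of the top few levels at each range corner decides whether a
walk stalled one level short of a corner is distinguishable from the peak at
the reach tolerance. Single-realization transition estimates should be
quoted with this spread in mind.

The global peak is estimated by two independent routes: multi-start coordinate
ascent on the grid with full per-parameter connectivity, and quasi-Newton
(L-BFGS-B) maximization of the same fitness over the continuous log-parameter
box. The continuous value must bound the grid value from above and agree with
it to 1e-3 relative; disagreement is surfaced as a warning in the result
metadata (and indicates an ill-posed or under-resolved grid).

The sensitivity scan repeats the connectivity sweep under rescaled fitness
constants (a×10, alpha×10, b×10, b÷10), walking from the same start genotypes
re-scored under the new constants, and reports whether the inferred transition
connectivity moves.

## Toy landscapes and exact oracles

Because the walk is a Markov chain that strictly increases fitness, on small
landscapes (≤ a few thousand genotypes) its behaviour can be computed exactly:
local optima are the absorbing states, and absorption probabilities and
expected step counts follow from the standard fundamental-matrix systems
(`markov.analyze_chain`). The fixture module ships hand-analyzable landscapes
(a 3-level single-parameter table; concave single-peak tables; two-peak tables
with nearest-index moves, whose minor peak genuinely traps some starts; the
transcription-network fitness restricted to tiny grids). Monte-Carlo ensemble
statistics are validated against these exact values to within three standard
errors. What the toys do not exercise: the 1000-level kernel geometry and the
corner structure of the real landscape, which only the full-scale runs probe.

## What the synthetic landscape does and does not emulate

The generator reproduces the study conditions: a six-parameter, 1000-level
discretized biophysical landscape with kernel-local mutation structure. It
does not emulate measured mutational spectra of real promoters/proteins,
epistasis beyond what the steady-state model induces, time-varying signals,
stochastic expression, or population-genetic effects (drift, clonal
interference). Passing tests therefore demonstrate properties of greedy
adaptation on this model class, not of any particular organism's landscape.
Where the original study conditions depend on a parameter-range table not
available here, results that hinge on the exact ranges (the numeric value of
the global-peak fitness, the exact location of the connectivity transition)
are expected to shift; the qualitative structure (monotone reach fraction,
sharp transition at K of order 1% of levels, fewer steps from fitter starts,
fastest evolution from intermediate starts, variance rise-and-collapse) is
range-robust.

## Numerical choices

- Steady-state residuals are verified at 1e-9 absolute after
  nondimensionalizing by the state's magnitude.
- Fitness comparisons inside the walk are strict float64 comparisons; the
  per-level fitness discrimination of the default landscape (≥ ~1e-6 near the
  summit) is far above float64 resolution.
- `estimate_global_peak` uses 24 restarts by default; on the default
  landscape all restarts converge to the same genotype.
- Grid draws that collide (measure-zero for float uniforms) are redrawn;
  degenerate ranges (min ≥ max) are configuration errors.
- Problem sizes in the shipped test suite are reduced (fewer replicates,
  3-point connectivity grids, 200-level landscapes for smoke tests) to keep
  the suite fast; the acceptance script runs the full design.
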