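# Methods

## Measurement model

All computations assume the two-parameter logistic (2PL) item response
model.  An examinee with ability `θ` answers an item with discrimination
`a > 0` and difficulty `b` correctly with probability

```
p(θ) = 1 / (1 + exp(−a(θ − b)))
```

The Fisher information contributed by the item at ability `θ` is
`a² p(θ)(1 − p(θ))`, which peaks at `a²/4` when `θ = b`.  Test
information is the sum of item informations; its inverse is the
asymptotic variance of the maximum-likelihood ability estimate for an
examinee at that ability.

## Growth design and estimand

Two test forms measure one population (or two groups) at two time
points.  Form 1 consists of `n1` unique items plus `nc` common (anchor)
items; Form 2 reuses the anchors and adds `n2` unique items — the
standard anchor-test (NEAT) layout that places both administrations on
one scale.  The estimand is the ability growth `d = μ2 − μ1`, the change
in the population mean (or, for the percentile criteria, the change in
selected distribution percentiles).  Populations at the two time points
are modeled as `N(−d/2, 1)` and `N(+d/2, 1)`.

With `N1` and `N2` examinees whose true abilities are `θ_i1`, `θ_i2`,
the asymptotic variance of the estimated growth `d̂` (difference of mean
ML ability estimates) is

```
Var(d̂) = (1/N1²) Σ_i 1/TIF1(θ_i1) + (1/N2²) Σ_i 1/TIF2(θ_i2)
```

where `TIF` is the test information function of the relevant form.

## Design criteria

True abilities are unknown at design time, so each continuous population
distribution is discretized into `l` equally spaced points spanning
`mean ± half_width` with weights proportional to the normal density
(normalized to 1 per population).  The design criterion is the weighted
sum of reciprocal test informations over both populations' grids:

```
Ψ = Σ_j w_j1 / TIF1(θ_j1) + Σ_j w_j2 / TIF2(θ_j2)
```

Minimizing `Ψ` over the item difficulties minimizes (a discretized
surrogate of) the growth variance.  Four criterion cases are provided:

1. **Mean growth** — normal-density weights on `l = 100` points per
   population.
2. **Mean and percentile growth combined** — equal-mass average of the
   case 1 criterion and a percentile criterion at the 25th and 75th
   percentiles.
3. **Percentile growth only** — point masses at the 25th, 50th and 75th
   percentiles of each population (six target abilities in total); the
   half unit of mass per population is split evenly across its
   percentile points.
4. **Two groups** — equal-mass average of the case 1 criterion for a
   reference group and for a second group whose ability distributions
   are shifted by `group_shift` (default +0.25).

Discriminations are held fixed at a common level `a` (continuous
problems) or at the calibrated pool values (discrete problems); only
difficulties are optimized.  Difficulty vectors are packed as
`(unique1, common, unique2)`.

### Optimum-in-average weights

When the population means are uncertain, the design integrates the
ability density over a normal prior on the mean.  The integral has a
closed form: if `θ | x ~ N(x, 1)` and `x ~ N(μ, σ²)`, then marginally
`θ ~ N(μ, 1 + σ²)`.  In-average grids therefore use `N(μ, 1 + σ²)`
density weights, which put strictly more mass in the tails than the
ordinary `N(μ, 1)` weights and yield designs robust to misspecified
growth.

## Optimizers

### Continuous difficulties: particle swarm

The criterion is non-convex in the difficulty vector (optimal solutions
collapse onto a few clusters), so a gradient-free particle swarm
minimizer is used, following the standard 2007 parameterization:
inertia `1/(2 ln 2)`, cognitive and social coefficients `0.5 + ln 2`,
200 particles, a random informer topology in which each particle
informs each other with probability 0.2 (rebuilt after any
non-improving iteration), and box constraints `[−6, 6]` enforced by
clamping with velocity reset.  Convergence is declared when the best
value improves by less than `1e−10` over a 50-iteration window
(5000-iteration cap).  Objective evaluation is batched over the whole
swarm: `exp(a(θ − b))` is factored as `exp(aθ)·exp(−ab)` so the
expensive transcendental is taken on small arrays, with exponents
clipped at ±60 (item information beyond that point is below 1e−25 and
numerically irrelevant inside the design box).

### Discrete selection: simulated annealing plus greedy refinement

Selecting `n1 + nc + n2` items from a calibrated pool is combinatorial.
The sampler starts from a random role assignment and proposes one-item
swaps between a selected slot and an unselected pool item, accepting
improvements always and worsenings with probability `exp(−Δ/t)`.  The
temperature follows the geometric schedule `t_k = t0 · α^k` (defaults
`t0 = 100`, `α = 0.8`, 5000 proposals per epoch, 100 epochs), after
which 100,000 strictly-improving greedy swap attempts polish the
solution.  Swap evaluation is incremental: per-item information tables
over the ability grids make a proposal an O(l) update instead of a full
criterion re-evaluation.  Reported solutions are re-evaluated from
scratch so the stored criterion value is exactly reproducible.  An
exhaustive enumerator (guarded at 10⁶ assignments, deterministic
lexicographic tie-breaking) serves as an oracle on small pools.

## Synthetic pool generator

`generate_synthetic_pool` mimics a large calibrated achievement-test
pool: discriminations are lognormal(0.09, 0.33) truncated by
resampling to `[0.40, 1.90]` (long-run mean ≈ 1.10), difficulties are
normal around the midpoint of `[−1.56, 1.60]` with SD a quarter of the
range, truncated to that range and then mean-centered.  Defaults
produce 248 items.  The generator is for experimentation only; real
applications should load a calibrated pool via `read_pool`
(CSV with columns `item_id,a,b`).

## Experiments

- **Case sweeps** optimize each criterion case over a grid of
  discrimination levels and growth distances; each run's seed is derived
  from `(case, a, d)` alone, so any subset reproduces the corresponding
  full-sweep entries.
- **Stability analysis** repeats one optimization from independent
  seeds and reports per-component means and SDs of the sorted
  solutions.  Variation concentrates at cluster edges (components that
  can trade places between adjacent clusters at nearly equal criterion
  value); `boundary_indices` identifies these as role edges plus both
  sides of jumps larger than 0.3 in the per-component means.
- **Uncertainty experiment** compares the ordinary design (optimized at
  a planned distance) with the optimum-in-average design under a
  `N(±d/2, σ_prior)` prior on the means.  Per replicate the item
  discriminations are resampled (`lognormal(0, 0.25)`) and both
  optimizations rerun; both designs are then scored on ordinary grids
  at each true distance and the SD ratio `σ_O/σ_A` recorded (sample
  sizes cancel in the ratio).
- **Monte-Carlo validation** draws one fixed set of `N` true abilities
  per population, repeatedly simulates dichotomous responses,
  ML-estimates every ability (damped Newton on the concave 2PL
  log-likelihood, estimates clamped to `[−6, 6]` with clamps counted),
  and compares the empirical variance of `d̂` across replicates with the
  asymptotic expression evaluated at the drawn abilities.  The
  abilities are held fixed because the asymptotic expression conditions
  on them; redrawing abilities each replicate would add a
  population-sampling term (`2σ²/N`) that is an order of magnitude
  larger than the estimation variance being validated.

## Reproducibility

All randomness flows from explicit integer seeds.  Sub-seeds are
derived with `numpy.random.SeedSequence` spawn keys built from scenario
values (case, discrimination, distance, replicate index), reduced
modulo 2³¹, so results are bit-reproducible and independent of
execution order.  Every CLI run writes its fully resolved configuration
(including a content hash) next to its outputs.

## Limitations

- Only the 2PL model is supported (no guessing parameter, no
  polytomous items).
- Ability distributions are assumed normal with unit variance at design
  time; the discretization is a fixed equally spaced grid.
- Discriminations are not optimized, only difficulties (continuous
  problems) or joint (a, b) selection from a fixed pool (discrete
  problems).
- The asymptotic variance expression ignores anchor-based linking
  error and treats ability estimates as independent across examinees.
- The synthetic pool generator is a stylized stand-in for a calibrated
  pool, not a model of any particular assessment.
- Exhaustive enumeration is feasible only for very small pools; for
  realistic pools the annealing solution has no optimality certificate
  (it is validated against the oracle at small scale).
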