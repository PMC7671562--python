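# Methods

## Model and assumptions

The process is the birth–death Moran model on a graph with
color-modulated, frequency-independent fitness. One individual
reproduces per time step with probability proportional to fitness
(times its total outgoing dispersal weight, in the weighted/directed
extension); the offspring replaces the occupant of a neighboring node
drawn from the reproducer's dispersal row. The state is the binary
occupancy vector x ∈ {0,1}^N; all-mutant and all-resident are the two
absorbing states. No mutation occurs during the process, and exactly
two types and two colors are supported (the data model stores colors as
a categorical vector so a k-color extension is possible, but every
formula requires exactly two and validates this).

The closed forms hold under three structural assumptions, which the
constructors and dispatch code enforce rather than assume: the graph is
connected; the coloring is proper (no same-colored neighbors); and the
graph is biregular (per-color degrees k_G, k_R, which forces
N_G·k_G = N_R·k_R by edge counting). For weighted/directed graphs the
analogue is uniform per-color weighted in/out degrees plus the
edge-ratio condition w_ji/w_ij = w_G_in/w_G_out on every green→red
edge (`check_weight_condition`); when it fails the closed form is
refused and the exact chain or simulation must be used.

## Parameters

- `FitnessScheme(a_G, a_R, b_G, b_R)` — dimensionless positive fitness
  values; 1.0 is the conventional resident baseline.
- Heterogeneity parametrizations. Two are provided and coincide when
  N_G = N_R:
  - `FitnessScheme.from_sigma(r, sigma)` — the symmetric table
    (r+σ, r−σ, 1+σ, 1−σ); feasible for 0 ≤ σ < min(r, 1) on any graph.
  - `fitness_from_heterogeneity(HeterogeneityParams(...))` — the
    mean-preserving map a_G = r_A + σ_A, a_R = r_A − N_G σ_A / N_R,
    keeping each type's population-mean fitness fixed when color counts
    are unequal.
  Coloring-permutation sweeps default to the mean-preserving map
  because the single-green-node star and the asymmetric complete
  bipartite graph admit a wide feasible σ range under it, and because
  it is the natural "fixed total resources" convention for comparing
  colorings; with the symmetric table the K_{3,7} argmax-switching
  behavior does not appear in the feasible σ range at r = 1.5,
  while under the mean-preserving map it does (observed at r = 0.9,
  σ ∈ [0, 2]).
- Dynamic coloring: shuffle probability p ∈ [0, 1] per time step. A
  shuffle replaces the assignment with a uniform draw from all
  assignments with the same color counts (equivalent to a uniformly
  random permutation of node labels, but cheaper to sample). Default
  event ordering is shuffle-then-reproduce, so p = 1 means every
  reproduction event sees a freshly randomized environment; the
  opposite ordering is available via `shuffle_first=False`. Both
  orderings coincide at p = 0 and were checked to give equal
  absorption probabilities there.
- Initial condition everywhere: one mutant placed uniformly at random;
  dynamic runs start from the graph's own (proper) coloring.

## Numerical choices

- ζ products are never formed directly: ρ_A is evaluated from
  N_G·log ζ_G + N_R·log ζ_R with `expm1`, which is accurate near
  neutrality and does not overflow for populations of hundreds of
  nodes (exponents above 700 short-circuit to ρ = 0).
- Neutrality (the 0/0 case of the ρ formulas) is detected as
  |a_G a_R − b_G b_R| ≤ 1e-12 · max(a_G a_R, b_G b_R) and returns the
  drift value 1/N. At the state level the limit of ρ_A(x) is
  Σ x_i λ_i / Σ λ_i with per-color weights λ_G = a_G·k_R,
  λ_R = b_R·k_G; the direction of approach is unique at neutrality
  (differentiating log ζ along independent perturbations of a_G and
  a_R gives weight ratios a_G k_R / (b_R k_G) and b_G k_R / (a_R k_G),
  equal exactly when a_G a_R = b_G b_R). `fixation_from_state` takes
  these weights as an optional argument and otherwise falls back to the
  unweighted count fraction.
- The symmetric-heterogeneity formula is evaluated as
  ρ_A = r(r−1) / [(r²−σ²)(1 − ((1−σ²)/(r²−σ²))^{N/2})]; this grouping
  is the one that reduces to the classical Moran probability
  (1−1/r)/(1−r^{−N}) at σ = 0 and to 1/N as r → 1, and it is
  cross-checked against the general formula in the tests.
- ρ_B is computed by role-swapping the fitness table through the ρ_A
  code path; a test compares the swap against an independent
  transcription of the ρ_B formula.
- Exact chains are assembled vectorized over all 2^N states (the
  loss/gain numerators are two dense matrix products) and stored as
  sparse CSR; absorption probabilities come from a sparse LU solve of
  (I − Q)u = r on the transient block. Caps: N ≤ 14 static; the dynamic
  product chain is capped by its assembled non-zero count (≈ 2·10⁷),
  which admits K_{3,3} with its full 20-coloring family but not
  K_{3,7}; beyond the caps the Monte Carlo engine is the intended tool.
- `distribution_power` reproduces the brute-force alternative
  (iterating the transition matrix and reading the absorbing masses)
  with early exit once the transient mass drops below 1e-12; tests
  require agreement with the linear solve to 1e-6.
- Monte Carlo: per-replicate seeds are spawned from the root seed via
  `numpy.random.SeedSequence`, so estimates are bit-reproducible and
  order-independent. The embedded-chain sampler (default for static
  colorings) draws only occupancy *changes* — statistically exact for
  absorption probabilities — and accumulates the expected number of
  wall steps per change, so its reported mean absorption time is a
  conditional expectation rather than a sampled count. Direct stepping
  is the default (and only) sampler for dynamic colorings because
  shuffles occur on wall-step cadence. A max-steps guard (default 10⁸)
  censors pathological runs; censored counts are reported so bias is
  visible.
- Coloring orbits are computed by grouping all C(N, N_G) assignments
  under colored-graph isomorphism (VF2 with a color node-match,
  pre-bucketed by a degree/color invariant), capped at N ≤ 12; the
  canonical representative is the lexicographically minimal color
  string of the orbit, and orbit sizes are checked to sum to C(N, N_G).

## What the built-in generators emulate

The graph families (even cycles, complete bipartite graphs, stars,
periodic square and hexagonal lattices) are idealized regular dispersal
structures with canonical proper two-colorings. Periodic boundaries and
even side lengths are imposed on the lattices so they stay regular and
two-colorable; free boundaries would break biregularity and with it the
closed form. Real populations have irregular degree distributions,
weighted and possibly asymmetric dispersal, and resource distributions
correlated with structure; of these, the exact-chain and Monte Carlo
engines handle arbitrary weights, directions and colorings, but
everything here remains frequency-independent two-type dynamics.
Passing tests therefore demonstrate internal consistency of the three
engines and the stated limit behaviors — not that any particular
biological population satisfies the model's assumptions.

## Problem sizes used in tests and the acceptance script

Engine-agreement checks run on eleven biregular fixtures with N ≤ 10
(up to 1024 chain states) with 15–50 random fitness tables each; the
trichotomy scan uses 500–1000 random tables; Monte Carlo calibration
uses 10⁵ replicates in the test suite and 2–5·10⁴ in the acceptance
script; the dynamic-chain analyses use K_{3,3} (1280 product states).
These sizes give worst-case engine disagreements at the 1e-14 level and
Monte Carlo z-scores well inside ±3, and keep a full run in the
minutes range on a single CPU.

## Known limitations

- Birth-death updating only; death-birth and other update rules change
  the formulas qualitatively and are out of scope.
- Two colors, two types, frequency-independent fitness; no mutation.
- The directed closed form requires the edge-ratio condition; graphs
  violating it are served only by the exact chain (N ≤ 14) or
  simulation.
- Exact dynamic chains scale as 2^N × C(N, N_G) states and are only
  practical for small symmetric graphs; larger dynamic problems rely on
  Monte Carlo.
- The embedded sampler's mean-step report is an expectation, not a
  sample, of the wall-step count (absorption *probabilities* are
  unaffected).
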