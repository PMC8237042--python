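# Methods

## Problem and model

Social distancing on a contact network is modelled as link removal: from a
social graph with `E` edges, a fraction `rho` (the contact reduction rate)
of edges is deleted and `(1 - rho) E` are kept. For discrete-time SIS
dynamics with per-contact infection probability `beta` and recovery
probability `delta`, the epidemic threshold of a graph is governed by the
largest eigenvalue of its adjacency matrix: outbreaks with
`beta/delta < 1/lambda_max` die out, above that ratio they become endemic.
Lowering `lambda_max` by choosing *which* links to remove therefore raises
the epidemic threshold without touching the disease parameters.

The package studies the canonical ensemble of link removals relative to the
generic (uniform) one,

    p(N) = exp(-nu * lambda_max(N)) * q^rho(N) / Z,

where `q^rho` is uniform over subgraphs with `(1 - rho) E` edges and the
inverse genericity `nu >= 0` interpolates between purely random removal
(`nu = 0`) and spectral-radius minimisation (`nu -> infinity`). Ensembles at
reasonably high `nu` (default 1000) are called well-controlling network
ensembles (WCNE).

## Metropolis sampler

State: a partition of the original edge set into kept and removed subsets
of fixed sizes (`round(rho*E)` removed, round-half-up applied once to the
original edge count). Proposal: swap one uniformly chosen kept edge with
one uniformly chosen removed edge. The proposal is symmetric, so plain
Metropolis acceptance

    min(1, exp(nu * (e_current - e_proposed))),    e = lambda_max(kept subgraph)

samples exactly the canonical ensemble; no Hastings correction is needed.
The initial partition is drawn from `q^rho`. Runs use a fixed length of
11,000 steps — the point at which the energy trace has visibly plateaued
for every `n = 100`, mean-degree-18 ensemble studied here — and ensemble
statistics use the *final* energy of each of `n_configs` independent runs
on independently generated starting graphs. `exact_stationary_distribution`
enumerates small state spaces (`C(E, kept) <= 1e5`) and computes the
Boltzmann weights and `Z` explicitly; it is the independent oracle against
which the sampler's long-run occupancy is chi-square-tested.

Numerical choices. The energy is computed to absolute tolerance `1e-8`:
dense `eigh` for graphs up to 64 nodes, otherwise Lanczos (`eigsh`, largest
algebraic) on a matrix-free operator whose matvec is two `bincount` calls
over the kept-edge endpoint arrays. Each Lanczos call is warm-started with
the eigenvector of the previous state, which the single-swap proposal
perturbs only slightly; this is what makes 11,000 evaluations per run cheap
(≈0.5 ms at n=100, ≈1 ms at n=1062). On the rare ARPACK non-convergence
the solver falls back to a dense decomposition, so results never depend on
Lanczos restarts. Energies of an empty edge set are 0 and the epidemic
threshold is reported as infinity.

## Removal strategies

All rate-parameterised strategies delete exactly `round(rho*E)` edges so
that ensembles are comparable at equal link density.

- **random** — uniform subset; samples `q^rho` directly.
- **degree product** — iteratively deletes an edge maximising
  `deg(u)*deg(v)` with degrees *recomputed after every deletion*; ties are
  broken uniformly at random. Static degrees would concentrate all
  deletions on the initial hubs and is a different (worse) algorithm.
- **degree cap** — processes nodes in ascending id order (an option allows
  a shuffled order); a node whose current degree exceeds `k_max` loses a
  random selection of all but `k_max` of its links. For spatially random
  graphs id order is effectively random; for preferential-attachment graphs
  low ids correlate with high degree, so hubs are trimmed first.
- **degree cap at a rate** — the number of edges the cap deletes depends on
  `k_max`, not `rho`; to compare at equal density the package picks the
  smallest `k_max` whose removal stays within the `round(rho*E)` budget and
  tops up with uniformly random deletions. This matching policy is a design
  choice of this package (the correspondence is not otherwise defined).
- **edge betweenness** — iteratively deletes the highest-betweenness edge
  (recomputed each step, random tie-break). Included as a negative control:
  it fragments the graph along bridges but leaves dense cores — and hence
  `lambda_max` — largely intact, so it performs no better than random
  removal at raising the threshold.

## Graph generators

- **Barabási–Albert** `(n=100, m=10)`: growth from an m-node seed, m edges
  per new node, giving exactly 900 edges and mean degree 18. `m = 10` is
  the unique choice matching both the target edge count and mean degree at
  n = 100.
- **Random geometric** `(n=100)`: uniform points in the unit square, hard
  (non-periodic) boundary, edge iff distance <= radius. The default radius
  0.27228 solves `(n-1) * (pi r^2 - 8/3 r^3 + r^4/2) = 18` — the
  boundary-corrected expected-degree formula; the naive `pi r^2 (n-1)`
  calibration would undershoot the target mean degree by ~20% because discs
  near the boundary leave the square. `calibrate_rg_radius` exposes the
  inversion.
- **School-scale surrogate** `(n=1062)`: a planted-partition graph — 30
  near-equal communities, mean degree 8, 90% of expected degree within the
  community. It emulates only the size and community structure of a real
  friendship network; it reproduces no measured contact data, no degree
  assortativity beyond the block structure, and no temporal behaviour, so
  epidemic results on it support ordering claims between removal
  strategies, not absolute tipping values for any real school.

## Epidemic simulation

Synchronous discrete time (the reactive process for which the
`1/lambda_max` threshold is exact in the mean-field approximation): at each
step every infected node recovers with probability `delta` and every
susceptible node with `m` infected neighbours *at the start of the step*
becomes infected with probability `1 - (1-beta)^m`; a node infected at step
`t` cannot recover before `t+1`. SIS runs a fixed 1000-step horizon; SIR
runs to extinction (recovery is absorbing, so extinction is a.s. for
`delta > 0`; `delta = 0` is rejected). All realizations of a run are
simulated simultaneously as node-by-realization boolean matrices with one
sparse matvec per step.

Endemicity measure: the cumulative number of distinct nodes ever infected,
*seeds included*. The tipping point of a network is the smallest
`beta/delta` on a scan grid whose mean cumulative infected fraction exceeds
a threshold (default 1%). Because seeds count, the 1% threshold is
meaningful only when `seeds/n < 1%`; the default scan uses 10 seeds on
n = 1062 (0.94%). Scan defaults: `delta = 0.5`, grid 0.04 to 1.0 in steps
of 0.04 — declared choices of this package, since the tipping comparison is
about the ordering of strategies, which is insensitive to them. With
`early_stop` the simulation of a grid point halts once the running mean
fraction exceeds the threshold; the cumulative count is non-decreasing in
time, so the detected crossing (and hence the critical ratio) is exact,
while reported fractions beyond it are lower bounds.

## Study scales

Defaults are desk scale: 10 sampler configurations per ensemble cell
(instead of 100) and 200 epidemic realizations (instead of 640), which keep
a full comparison run in minutes while leaving every qualitative comparison
intact; both are plain config fields. The tipping report uses 2 surrogate
networks per strategy/rate cell.

## Known limitations and observed deviations

- `lambda_max >= mean degree` for every graph. Consequently a *targeted*
  removal of 80% of a 900-edge, 100-node graph (180 kept edges, mean degree
  3.6) can never undercut the measured mean of *random* 90% removal
  (lambda ≈ 3.53): the often-quoted "80% targeted matches 90% random"
  equivalence holds approximately (3.67 vs 3.53) but not as a strict
  ordering at this size and density. The corresponding ordering test is
  expected to fail and is kept as an honest record of this bound.
- The BA random-removal baseline at `rho = 0.4` measures 14.04 ± 0.02 here,
  slightly above the commonly cited ≈13.5; the value depends on details of
  the BA seed-graph convention that are not pinned down by `n`, `E` and
  mean degree alone. The RG baseline lands at 13.46.
- Metropolis at `nu = 1000` is near-greedy; it samples the WCNE, it does
  not certify the optimal removal. `nu > 1000` would need longer runs for
  proper mixing and adds little, and is deliberately out of scope.
- Strategies operate on static, unweighted, undirected graphs; no node
  removal (vaccination), edge weights (masking), or temporal contact
  patterns.
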