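# Methods

## The process being modelled

`patrolspread` simulates the community-level receipt of one piece of
information — "ranger patrols are present" — through the social network of a
single 40-person hunting community. It models receipt only: believing the
information and changing hunting behaviour are downstream processes outside
the model's scope. Agents differ only in their network position; the
information is never forgotten, never distorted, and never disbelieved.

## Network generator

Communities are undirected simple graphs whose degree distributions vary in
how strongly they are skewed towards the star-graph extreme (one hub tied to
everyone, no other ties).

* **Degree family.** Per-node target degrees are lognormal draws with mean
  degree 4, rounded to the nearest integer and truncated to [1, n−1]. The
  presets differ only in the lognormal shape σ: `light` 0.2, `moderate` 0.6,
  `high` 1.2. Low σ gives a near-symmetric histogram (degrees 3–5); high σ
  gives a heavy hub tail with a median degree of ~2. Mean sample skewness of
  the generated sequences is strictly ordered light < moderate < high
  (asserted in the tests with a ≥3-standard-error margin over 200 seeds).
  These presets are configuration values (`SkewPreset`), not constants, so an
  alternative family can be swapped in without touching the simulator.
* **Parity and graphicality.** An odd degree sum is repaired by incrementing
  the smallest entry. A sequence failing the Erdős–Gallai condition — common
  for `high` draws, where a 39-degree hub plus many leaves is infeasible —
  is repaired by decrementing its two largest entries by 1 until graphical.
  This shrinks hubs as little as possible while preserving parity.
* **Wiring.** Graphical sequences are realised exactly by Havel–Hakimi
  construction and then randomised by 4·m accepted double edge swaps (two
  random edges (u,v), (x,y) rewired to (u,x), (v,y) unless that would create
  a self-loop or duplicate). Swaps preserve every degree, so realisation
  fidelity is exact by construction.
* **Connectivity.** Enforced by default (a flag disables it): components are
  merged by the same cross-component swap, which cannot create duplicates
  because the components are disjoint. A heavily skewed draw occasionally
  has fewer than n−1 edges, which no connected graph can carry; the
  generator then redraws the degree sequence (at most 100 attempts) rather
  than failing.
* **Skewness statistic.** Bias-corrected sample skewness of the degree
  sequence (`scipy.stats.skew(bias=False)`); undefined (NaN sentinel) for
  zero-variance sequences.

## Contagion rule

* **Seeding.** `round(E·n)` individuals (half away from zero) are seeded, in
  ascending degree order by default — first-hand patrol knowledge
  concentrates in marginalised, poorly connected people at forest edges — or
  descending order as a variant. Degree ties are broken uniformly at random.
* **Update.** Synchronous discrete time. An individual uninformed at step
  start with ≥ T informed neighbours (counted at step start) becomes
  informed with probability L, applied once per node per step, not per
  informed neighbour: L is read as a property of the listener, while the
  threshold T carries the requirement for repeated independent transmission.
  A per-contact variant (`DiffusionParams(per_contact=True)`, uptake
  probability 1 − (1−L)^k for k informed contacts) is available for
  sensitivity analysis and is covered by the same exact-enumeration oracle.
* **AUC.** The informed count is recorded at the end of each of the 50
  steps; the seeded state is not a separate curve point. AUC is the plain
  sum of the 50 counts, making the saturation bound exactly 50 × 40 = 2000.

## Verification oracle

`exact_expected_counts` propagates the full probability distribution over
knowledge states (bitmasks; knowledge is absorbing, so only supersets of the
seed set are reachable) and returns exact per-step expected informed counts.
It refuses networks above 12 nodes. `monte_carlo_expected_counts` is the
vectorised simulator run at fixed seed sets; the tests require agreement
within 3 standard errors at every step on path, star, cycle and skewed
fixtures for T ∈ {1,2} and L ∈ {0.25, 0.5, 1.0} at 10⁵ replicates.

## Experiment and seeding scheme

The default grid crosses 3 structures × T ∈ {1,2} × L ∈ {0.1,…,1.0} ×
E ∈ {0.05,…,0.30} × 100 replicates (36,000 runs; 12,000 fresh networks per
structure). Every run's seed is a SHA-256 hash of
(base_seed, structure, T, L, E, replicate) folded to 31 bits, so the table
is bit-for-bit reproducible and independent of execution order. The exact L
and E grid values are a design choice constrained only by the documented
total of 120 (T, L, E) combinations and the interior point (T=2, E=0.25,
L=0.4); both grids are fully configurable.

## Regression sign analysis

Within each (structure, T) stratum, AUC is regressed by OLS (statsmodels) on
E, L and E·L on their natural scales, pooling replicates as independent
observations. Two-sided t-test p-values map to codes: '+++'/'---' for
p ≤ 0.01, '+'/'-' for 0.01 < p ≤ 0.05, '0' otherwise; at the p = 0.05
boundary significance wins (the conventional reading of the overlapping
legend inequalities — a measure-zero case in practice). Signs are invariant
to positive rescaling of AUC, so the natural-scale choice is innocuous.

## What the generator does and does not emulate

The synthetic communities reproduce the qualitative structural axis of
interest — evenness of connectedness, from near-regular to hub-dominated —
at realistic size (n = 40) and mean degree (4). They are non-spatial,
unweighted, static, and not fitted to any empirical community. One
consequence matters for interpretation: under the `high` preset most
individuals have degree 1, and a degree-1 individual can never satisfy a
listening threshold of T = 2, so highly skewed communities largely freeze at
T = 2 (AUC stays near 50 × seeds at low E and L). The T = 1 conclusions —
E and L each speed information flow, with a significant negative interaction
because AUC saturates at its bound — are insensitive to this; the T = 2
interaction pattern across skew levels is generator-dependent, and with this
degree family the (high skew, T = 2) stratum shows a positive interaction
(complementarity far from saturation) rather than the saturation-driven
negative one. An alternative generator with a minimum degree of 2 would be
the natural sensitivity analysis and can be supplied as a custom
`SkewPreset`-realised degree sequence.

## Numerical and degenerate-input choices

* Seed counts use round-half-away-from-zero; E = 0 yields an empty seed set
  and E = 1 informs everyone (AUC exactly n_steps × n).
* L = 0 freezes the dynamics exactly (AUC = n_steps × seeds).
* Zero-variance degree sequences return NaN skewness rather than raising.
* Regression requires ≥ 2 distinct E and L values per stratum; otherwise the
  rank-deficient design is rejected with an explicit error.
* Problem sizes in the test-suite oracle checks use 15-step horizons and
  10⁵ Monte-Carlo replicates on ≤ 10-node fixtures; the factorial checks run
  the full 36,000-run default experiment, and the monotonicity probes use
  1,000 common-random-number replicates per parameter value, chosen as the
  smallest designs that make the stochastic assertions stable.

## Known limitations

No spatial structure, edge weights, dynamic rewiring, agent heterogeneity in
trust or risk, information decay, or behavioural response to knowledge;
empirically fitted networks are out of scope. Conclusions about real
communities depend on the degree family assumption discussed above.
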