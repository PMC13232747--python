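# Methods

## The model

A population of `d` types is distributed over `m` groups with carrying
capacity `n`, so the total size fluctuates between `2m` (every group at its
minimum of two members) and `mn`. Groups are well mixed; there is no space
within a group and no migration between groups. Each individual plays a
matrix game against every other member of its group: the payoff of type `j`
in group `g` is the mean of `a_jk` over the other `N_g − 1` members, with
the self-pairing removed, and fitness is `exp(β π_j)`. The exponential map
keeps fitness positive for negative payoffs and lets `β` interpolate from
neutral drift (`β = 0`) through intermediate (`β = 1`) to strong selection.

Time advances in discrete update events. Each event is an immigration with
probability `λ` (a uniformly random type from an environmental pool that
contains all `d` types equally, into a uniformly random group) or a birth
otherwise. A group pushed above `n` is resolved immediately — also when the
excess individual was an immigrant, since the overflow rule is a statement
about group size, not event kind. With probability `q` the group splits:
every individual is assigned to one of two offspring groups by an
independent fair coin, and the whole allocation is redrawn from scratch
until both offspring have at least two members (rejection sampling, so the
accepted allocation is a conditioned fair assignment). One group other than
the two offspring is then removed uniformly at random, keeping exactly `m`
groups. With probability `1 − q` a uniformly random member of the
overflowing group dies. Death is otherwise unselective; all selection acts
at birth.

**Parent selection.** The replicating parent is drawn
fitness-proportionally over *all* individuals in the population, so the
within-group replication probability of type `j` is
`n_jg f_j / Σ_k n_kg f_k` conditional on the parent's group, while groups
with fitter members accumulate births — and hence splits — faster. This
global weighting is the default because differential group growth is what
couples individual fitness to group-level selection; a `per_group` variant
(group chosen uniformly, then an individual within it
fitness-proportionally) is available through
`SimulationConfig.parent_selection` for comparison, since the choice of the
parent's group is a genuinely open modeling decision.

**Other conventions.**

- Single-group populations never split regardless of `q`: there is no
  other group to remove. The same suppression applies to any group too
  small to yield two offspring of size ≥ 2 (possible only for `n ≤ 2`).
- The group removed after a split excludes both offspring by default;
  `split_removal="any"` includes them, as the two readings of removing
  "another" group differ.
- A singleton group's payoff is defined as 0 (fitness 1). It is
  unreachable under the dynamics (minimum group size is 2) but keeps
  defensive code paths well defined.
- Time is measured in update events and snapshots are indexed by the event
  clock; events are the only well-defined clock in the process.
- All randomness in a run comes from one `numpy` PCG64 stream seeded by
  `SimulationConfig.seed`, consumed in a fixed order (event kind → actor →
  placement → overflow resolution). Runs are bit-reproducible; at `β = 0`
  they are also bit-identical across payoff matrices, a useful neutrality
  check.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `β` | 1.0 | intermediate selection: payoff differences matter, drift does not dominate |
| `λ` | 0.1 | immigration strong enough to reseed extinct types, weak enough that birth dominates |
| `q` | 0.001 | rare splitting: group-level events much slower than individual events |
| `μ, σ²` | 0, 1 | Gaussian payoff-matrix ensemble, giving a wide spread of interaction types |
| `last_k_snapshots` | 15 | window for long-run time-averaged abundances |

The studied population shapes keep the maximal size `N = mn = 120` and
vary the partition: `(m, n) ∈ {(1,120), (2,60), (3,40), (4,30), (6,20)}`,
plus a small single group `(1, 20)`; single groups use `q = 0`. Frequent
splitting is modeled by `q = 1.0`.

## Interaction classification

The classifier is a property of the payoff matrix alone. For pair `{i, j}`
it compares `a_ij` vs `a_jj` and `a_ji` vs `a_ii` with strict inequalities:
one-way invasion is dominance (oriented), no invasion is bistability,
mutual invasion is coexistence with interior equilibrium
`x* = (a_ij − a_jj)/(a_ij − a_jj + a_ji − a_ii)`. Exact ties are classified
`DEGENERATE`, excluded from frequency denominators and reported
separately: ties have measure zero under the Gaussian generator, but a
silent arbitrary assignment would corrupt baselines on hand-written
integer matrices. Dominance orientation is stored (needed for per-type
profiles) and pooled in frequency reports.

*Realized* interaction frequencies reweight these classes by co-residence:
a heterotypic pair in the same group at the same snapshot contributes
`n_ig · n_jg` interacting individual pairs (a presence-based estimator —
each co-occurring pair counted once — is available, as the weighting
underlying the reported frequencies is a free choice).

## Diversity metrics

Richness counts distinct types (population-wide or per group); the Shannon
index uses the natural logarithm, the ecology standard, as no base is
singled out by the model. Between-group similarity is the mean pairwise
Jaccard index of the groups' presence sets — a richness-based measure to
match the richness-based framing; abundance-weighted Bray–Curtis is
provided as an option. The most-abundant-type turnover statistic
run-length-encodes the population leader across snapshots with ties broken
deterministically toward the lowest type index.

## Synthetic data and what the tests show

The package generates all of its own inputs: payoff matrices are i.i.d.
Gaussian(0, 1) draws, and populations start with every group filled to
capacity with uniformly random types. This emulates the ensemble the model
is defined over, not any measured community: real microbiomes have sparse,
structured interaction matrices, non-uniform immigration pools, and
abundance distributions with far heavier tails. Passing tests therefore
validate the stochastic process and its statistics, not predictions about
any particular biological system.

Test and trend-check problem sizes are scaled to desk hardware: trend
comparisons use `d = 200` types (instead of 1000), 30,000 events, and 10
seed-paired replicates per configuration, with matched matrices and event
budgets across the arms being compared. Orderings (bistability up,
coexistence down, richness and Shannon up under rare splitting, richness
down under `q = 1`) are asserted as majorities over replicate pairs, not
as point values, because each arm's fractions vary strongly with the
matrix realization. Interaction-frequency trends are averaged over the
second half of each run's snapshots — the long-run average the trend is
about — while diversity and abundance statistics use the last-15-snapshot
window.

## Numerical choices

- Payoffs and weights are computed in double precision on the present
  types only (`O(k²)` per group for `k ≤ n` present types); classification
  compares matrix entries directly, never floating-point payoff sums, so
  no tolerance enters the classifier.
- Parent selection uses cumulative-sum inversion of one uniform draw per
  level (group, then type); per-group weight vectors are cached and
  recomputed only for groups mutated since the last event.
- The replicator-dynamics oracle used in tests integrates
  `dx/dt = x(1−x)[(a−c)x + (b−d)(1−x)]` with fixed-step RK4 (`dt = 0.02`),
  in chunks with an active set, until every trajectory's velocity falls
  below `1e−12` or `t = 10⁵`; the long horizon covers games whose invasion
  margins are small. Bistable games whose basin boundary lies outside the
  start frequencies (x* < 0.05 or > 0.95) are checked against the
  phase-line prediction for each start rather than the "different
  absorbers" shorthand.

## Known limitations

- No between-group migration (horizontal transmission), no selection at
  death, no alternative fragmentation modes, and no higher-order
  (beyond-pairwise) interactions; the environmental pool is uniform and
  static.
- The event-per-step clock means wall-clock comparisons across
  configurations with different `λ` mix immigration and birth timescales.
- `InteractionTable` stores a dense `d × d` class matrix (1 MB at
  `d = 1000`), which is wasteful for very large `d`.
- The trend assertions are stochastic by construction; with other seed
  sets a minority of replicate pairs can invert an ordering, which is why
  majorities over pairs are the tested property.
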