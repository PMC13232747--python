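# groupgames

Stochastic simulator for **multilevel selection in multitype populations**:
a community of `d` microbial types lives in `m` groups (hosts), each with
carrying capacity `n`, and evolves through within-group game dynamics,
immigration from an environmental pool, and group-level splitting and
extinction. The package targets researchers in microbial ecology and
evolutionary game theory who want to study how group structure shapes which
pairwise interactions are selected and how diverse the community stays.

## Model

Individuals interact only within their group. A type-`j` individual in
group `g` with composition `(n_1g, …, n_dg)` and size `N_g` receives the
mean payoff

```
π_j = (n_jg − 1)/(N_g − 1) · a_jj + Σ_{k≠j} n_kg/(N_g − 1) · a_jk
```

from the `d × d` payoff matrix `A = (a_ij)` (self-interaction excluded),
mapped to fitness `f_j = exp(β π_j)` with selection intensity `β`. One
update event is:

1. with probability `λ`, an immigrant of a uniformly random type joins a
   uniformly random group; otherwise a parent is chosen
   fitness-proportionally and its offspring joins the parent's group;
2. if the group now exceeds `n`: with probability `q` it splits in two
   (each individual assigned by a fair coin, redrawn until both offspring
   have ≥ 2 members) and one other group is removed to keep `m` constant;
   with probability `1 − q` one random group member dies.

Every unordered pair of types is also classified by the outcome of its 2×2
replicator subgame via the strict invasion conditions (`i` invades resident
`j` iff `a_ij > a_jj`): **dominance** (one type invades, the other cannot),
**bistability** (neither invades), or **coexistence** (both invade, stable
interior equilibrium at `x* = (a_ij − a_jj)/(a_ij − a_jj + a_ji − a_ii)`).
For an i.i.d. continuous random matrix the expected class fractions are
50% / 25% / 25%. Metrics modules compute realized interaction frequencies
among co-resident individuals, richness, Shannon diversity, between-group
Jaccard similarity, homogeneous-group fraction, abundance rankings, and
leader turnover.

## Worked example

```sh
groupgames all --d 50 --m 3 --n 10 --beta 1.0 --lam 0.1 --q 0.001 \
    --events 20000 --seed 7 --out run1/
groupgames classify --matrix run1/matrix.tsv --baseline
```

The `classify --baseline` call prints the class fractions of the generated
50-type Gaussian matrix:

```
dominance	0.521633
bistability	0.249796
coexistence	0.228571
```

i.e. of the 1225 type pairs, 52.2% are dominance, 25.0% bistability and
22.9% coexistence — close to the 50/25/25 random-matrix expectation.
`run1/summary.tsv` then reports the long-run state of the simulated
community (last 15 snapshots): total richness 7.7, Shannon index 1.61,
and realized interaction fractions among co-resident individuals of
0.46 / 0.47 / 0.06 (dominance / bistability / coexistence) for this seed:
group structure enriches bistability relative to the matrix baseline at the
expense of coexistence. All outputs are tab-separated text with 0-based
type and group indices, plus a `manifest.txt` sufficient to re-run the
simulation bit-identically.

The same pipeline is available as a library:

```python
import groupgames as gg

A = gg.generate_matrix(d=200, mu=0.0, sigma2=1.0, seed=1)
cfg = gg.SimulationConfig(d=200, m=6, n=20, beta=1.0, lam=0.1, q=0.001,
                          seed=1, n_events=30_000, sample_every=200)
traj, log = gg.run(cfg, A)
table = gg.classify_all(A)
print(gg.long_run_summary(traj, A, table))
```

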