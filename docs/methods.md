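# Methods

## Model and assumptions

`fragmodes` simulates a two-level stochastic birth–death process exactly
(Gillespie algorithm): cells are born, mutate into cheaters, die and
migrate; groups fission according to a two-parameter fragmentation mode and
go extinct under community-wide density dependence. All rate functions are
linear in the state (the simplest biologically plausible forms that keep
population sizes bounded); nonlinear or state-dependent rates are out of
scope. Cooperation is within-species for m = 1 and obligate cross-feeding
across species for m > 1 — a cell of species j can only divide when
wild-type partners of all other species are present in its group, and its
own conspecific wild-type count does not enter its rate. There is no
back-mutation and no spatial structure within groups.

Time is measured in units of the shortest cell generation: the m^(m−1)
normalisation makes the maximum per-capita birth rate exactly 1 for a
symmetric all-cooperator group at every m (asserted exactly in the tests).

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| m | species per group | 1 | – |
| gamma | cost of cooperation | 0.1 (placeholder, set explicitly for real studies) | – |
| mu | wt→cheater mutation prob. per birth | 0 | – |
| K_cells | within-group carrying capacity | 100 | cells |
| B0 | baseline fission rate | 0.01 | /group/time |
| sigma | size-dependence of fission rate | 0 | /time |
| K_total | community density-dependence scale | 10,000 | cells |
| nu | per-capita migration rate | 0 | /cell/time |
| mu_s, mu_n | trait-mutation prob. per birth | 0 | – |

The defaults mirror the values stated alongside the model's headline
experiments (100 founder groups of K_cells/2 wild-type cells, B0 = 0.01);
the cooperation cost default is a documented placeholder, not a literature
value. `K_total = inf` disables extinctions.

## Numerical and design choices

* **Sampling clock.** The event-driven clock never hits integers, so the
  state is recorded at the last event before each integer time (sampling
  every time unit). Outputs are smoothed with a 200-sample moving average.
* **Steady state.** Declared when, over the last 200 smoothed points, the
  RMS deviation of the total wild-type count is < 1% of its window mean and
  that of the group count < 5%. Runs stopping at `t_max`, the
  unbounded-growth guard (N_total > 50·K_total) or a wall-clock limit are
  flagged `excluded`.
* **Fragmentation draws.** The Poisson rates are set to the stated
  expectations (n·N_i, s·N_i) and then truncated/renormalised on their
  integer supports; the truncated mean therefore deviates slightly from
  n·N_i (the literal reading of the sampling recipe). The triangle is
  treated as closed so the three archetypal corners are admissible. The
  archetypes use the general sampler — binary fission is not special-cased,
  so an odd-sized parent splits into parts differing by one cell only in
  distribution, not deterministically.
* **Empty parents.** If a fission transmits every cell, the last allocated
  part is relabelled the parent; an empty group never survives any event.
* **Migration destination** is uniform among the *other* groups; with one
  group the channel has rate zero.
* **Forced fission** (constant-death variant) triggers the moment a group
  reaches K_cells, using the group's normal fragmentation strategy.
* **Trait grid.** Default 20 s-bins × 40 n-bins so both axes share one bin
  width (0.025); with equal bin counts the s-column at the binary-fission
  corner would contain no admissible center. Mutations step to adjacent
  bins (s then n, independent, double steps allowed); inadmissible results
  are projected along the n-direction onto the boundary, cancelling the
  s-step only if its column has no admissible bin. A group's strategy for a
  fission event is the cell-count-weighted mean of its members' bin
  centers, projected the same way.
* **mu_max protocol.** Each replicate descends a geometric μ schedule
  (default ratio 10^(−1/4) from 1 to 10^−4) until the community first
  persists; the aggregate is the NaN-skipping mean of log10 μ_max, with
  `ceiling` / `below_floor` flags at the schedule ends. Persistence is a
  detected non-zero steady state by default; the `"alive"` option (wild
  type present at `t_max`) is the appropriate reading for small,
  near-critical communities, whose slow equilibration can outlast any
  affordable horizon while the population is plainly viable.
* **Performance.** The kernel updates per-group channel rates
  incrementally, carries the extinction channel analytically as G·D, does a
  full rebuild after every group-level event and every 2·10^6 steps, and is
  audited against the pure-Python reference rate table for exact equality
  on random states. One integer seed determines a run completely
  (per-chunk sub-seeds are drawn from a PCG64 stream).

## What the simulations emulate — and what they do not

All experiments are self-generated: the founder state is the documented
initialization (identical groups, equal species split, no cheaters), not
data. The scaled study conditions used by the test suite were fixed once,
by pilot exploration, before the tests were frozen: 20 founder groups of 25
cells, K_cells = 50, K_total = 30,000 where sigma = 0 (at much smaller
K_total the founding transient — extinction pressure N_total/K_total
against B0 = 0.01 fission — extinguishes every community) and K_total =
6,000 for the sigma = 2 regimes; horizons of 1,200–3,000 time units;
meltdown/rescue at mu = 0.05 (at this community size the rescue arm is not
viable at mu = 0.1; the meltdown arm is extinct 10/10 either way);
evolution runs on an 8 × 16 grid with mu_s = mu_n = 0.05 from the start
point (0.175, 0.675). Passing tests therefore demonstrate the model's
qualitative orderings and directions at desk scale; absolute equilibrium
values, mu_max magnitudes and evolutionary end points at publication scale
(hundreds of groups, K_cells = 100, 10^6 time units) require the CLI with
correspondingly larger configs.

## Known limitations

* **Demographic-stochasticity deficit.** The deterministic within-group
  balance point (1 − gamma)·K_cells is not the stochastic time-average.
  For an isolated single-species group the exact stationary law of the
  reflecting birth–death chain (`oracles.logistic_chain_mean`) gives 88.99
  at gamma = 0.1, K_cells = 100 — about 1% below the 90.0 of mean field —
  and the simulator matches the chain, not mean field, once sampling error
  drops below the deficit. The deficit grows with species number (m = 2:
  ≈ 88; m = 3: ≈ 86 in the tests) because species-composition fluctuations
  lower the product-form birth rate; the m-invariance of the equilibrium
  is exact only at the deterministic level. The two mean-field acceptance
  checks for m > 1 fail for this documented reason and are left failing.
* Binary fission at B0 = 0.01 with the default density dependence sustains
  only a handful of groups; at the test scale it is effectively inviable,
  so mu_max orderings against it are degenerate (0 vs positive).
* Group fissions skipped in the rare step where the group-array capacity
  doubles are dropped rather than retried; the event loss is negligible
  (a handful per growth episode) but the trajectory is not bit-identical
  to an unbounded-capacity run.
* No within-group spatial assortment ("associative splitting"), no
  budding/group dispersal modes, no alternative extinction functional
  forms.
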