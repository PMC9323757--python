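# Methods

## The model

`ringmarch` simulates a swarm of `m` identical locust-like agents on a
discretized ring arena: `k` concentric *tracks* (rings) of `n` cells each,
topologically a cylinder surface. Coordinates are `(x, y)` with `x` taken
modulo `n` (clockwise = +x) and `y` in `[0, k)`; each cell holds at most one
locust. Every locust carries a persistent heading `b ∈ {+1, −1}` (+1 =
clockwise) — its "opinion" in the opinion-dynamics reading of the model —
and wants to keep marching in that direction forever. Headings change only
under duress: when a clockwise locust at `(x, y)` sits immediately behind a
counterclockwise locust at `(x+1, y)` the two are *in conflict*, and at the
end of that time step one of them, chosen uniformly at random, flips to the
other's heading.

One synchronous time step runs in a fixed order:

1. **Erratic draws.** Each locust independently idles in the horizontal
   phase with probability `r` and is flagged for an erratic vertical hop
   with probability `p` (the two draws are independent).
2. **Conflict detection** on the beginning-of-step configuration.
   Conflicting locusts are mutually blocked, so their adjacency persists
   through the step; the flips are applied at the end.
3. **Horizontal phase.** Every non-idling locust targets the next cell in
   its heading direction. A target occupied *at the beginning of the step*
   refuses entry (no following into a just-vacated cell, no swapping
   through each other); an empty cell contested by the two locusts flanking
   it is granted to one of them uniformly at random. Moves apply
   simultaneously.
4. **Vertical phase.** Locusts are processed in a uniformly random order (a
   valid instance of the model's arbitrary switching scheduler; random
   order avoids simultaneous-claim ambiguity). An erratic-flagged locust
   hops to a uniformly chosen adjacent empty vertical cell if one exists,
   ignoring all preconditions, and takes no deliberate move that step.
   A non-flagged locust may take a *deliberate* switch to `E = (x, y±1)`
   when the switching policy fires and three conditions hold:
   (1) on the beginning-of-step state, its front on its own track has the
   opposite heading and is not ring-adjacent (an imminent but not immediate
   head-on conflict); (2) on the post-horizontal state, `E` is empty and
   both the would-be front and back on the target track share the locust's
   heading; (3) no locust on the target track would move into `E` next
   step — no clockwise locust at `(x−1, y±1)`, no counterclockwise locust
   at `(x+1, y±1)`. Cells claimed by earlier movers in the processing
   order are reserved; occupancy and headings are read from the
   post-horizontal, pre-flip configuration (the literal "at time t+1"
   phrasing of condition (3) is circular, since it depends on other
   same-step decisions; this local reading is computable and lies within
   the model's freedom to choose any scheduler respecting the conditions).
5. **Conflict resolution.** Each detected pair flips one uniformly chosen
   party, independently across pairs, addressed by locust id (a loser may
   have hopped tracks erratically in the same step).

Switching policies: `never` (only erratic hops occur), `always` (every
eligible move is taken, ties between up and down broken uniformly),
`bernoulli(q)` (an eligible locust switches with probability `q`).

### Consensus notions and Tstable

A track is *stable* when all its locusts share a heading (an empty track
vacuously so); *local consensus* means every track is stable, and is
absorbing when `p = 0` because entrants must match the receiving track's
heading. *Global consensus* means all `m` locusts agree, and is absorbing
unconditionally (conflicts need opposite headings). `Tstable` is measured
at the *beginning* of a step: a swarm initialized uniform has `Tstable = 0`.
The run driver's `auto` stop mode waits for global consensus when `p > 0`
and local consensus otherwise, matching which notion is attainable.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `n`  | cells per track | — | `≥ 2` |
| `k`  | number of tracks | — | `≥ 1` |
| `m` / `density` | population, directly or as an occupancy fraction | — | exactly one given |
| `r`  | erratic idle probability per locust-step | 0 | horizontal noise |
| `p`  | erratic hop probability per locust-step | 0 | vertical noise |
| `policy` | deliberate switching rule | `always` | `never` / `always` / `bernoulli(q)` |
| `enforce_two_per_track` | two-locust floor per track at init | on | requires `m ≥ 2k`, `n ≥ 2` |
| `max_steps` | step cap of a run | 10⁶ | timeout is data, not an error |

## Initialization

Density-driven configurations emulate the experiment protocol:
`round(density·n·k)` cells are drawn uniformly over the whole arena and —
for the sparse protocol, where the floor matters — tracks left with fewer
than two locusts are topped up at random free cells of that track, so the
realized population can slightly exceed the nominal one. This matters
quantitatively: the sparse per-track occupancy is then Binomial-tailed
(topped at 2), and the mean-of-maximum stabilization time across tracks is
driven by that upper tail. A flattened placement (exactly two per track
first, extras after) underestimates the sparse headline means by ~10–25%.
Explicit-`m` configurations place exactly `m` locusts (two per track first
under enforcement). Headings are i.i.d. uniform. Dense (50%) experiment
configurations skip the floor; at that occupancy it is irrelevant.

## Randomness and reproducibility

All randomness flows through one `numpy` PCG64 generator per run, consumed
in a documented order (erratic flags → horizontal tie-breaks → vertical
processing order → per-locust vertical draws → conflict winners). Draws
with probability 0 or 1, and the processing-order permutation when no
vertical move is possible, consume no randomness. Identical seed and
configuration give bit-identical trajectories. Sweep replicates are seeded
by `SeedSequence(entropy=base_seed, spawn_key=(point_index, rep_index))`,
so any grid point reruns independently.

## Structural diagnostics

* **Segments** — maximal runs of consecutive same-heading locusts on one
  track; the *tail* is the locust whose back has the opposite heading. A
  heading-uniform track has no tail anchor, so by convention it is one
  segment canonically started at its smallest-`x` locust. Segment identity
  over time follows the tail id; a segment whose tail flips, leaves the
  track, or stops being a tail has ended.
* **Compact sets** — same-heading platoons with at most one empty cell
  between consecutive members; impermeable to vertical entrants, because a
  member is always about to move into each internal gap. The maximal
  compact partition of a track (or of an analysis arc, with linear
  in-frame distances) is unique.
* **Deadlock** — a clockwise and a counterclockwise compact set whose
  facing heads are adjacent. Deadlocked sets conflict every step; the
  loser changes sides, so the pair's sizes perform a symmetric random walk
  that resolves in `|X|·|Y|` expected conflicts (the gambler's-ruin closed
  form, exposed as `gambler_ruin_time`).
* **Potentials** — over an analysis arc, `L1`/`L2` sum the gaps between
  consecutive same-heading compact sets, `L3` is the gap between the two
  facing innermost sets, and `L = L1 + L2 + L3` equals 1 exactly in
  deadlock. `F` counts internal empty cells plus locusts and bounds how
  many locusts can leave the track. `F` is implemented as the sum
  `Σ(dist−1) + Σ(dist−1) + #locusts`; note that expanding those sums gives
  `L1 + L2 − (c_t−1) − (w_t−1) + #locusts`, i.e. two more than the often-
  quoted `L1 + L2 − c_t − w_t + #locusts` shorthand, and only the sum form
  matches the verbal definition ("empty cells between consecutive compact
  sets plus the locusts").

### A measured correction to the descent claim

The two-segment descent argument asserts that `L` strictly decreases on
every step with `L > 1`. Monitored runs falsify the *per-step strict* form:
when the facing heads are already adjacent (an active conflict) a
counterclockwise mover can close an internal gap of its own compact set —
no inter-set distance shrinks — and the end-of-step flip can rebuild the
same partition shape, stalling `L` (observed stall at `L = 4` on an
`n = 18` trace). The stall always coincides with an active conflict and
resolves with probability 1/2 per step, so the conclusion survives: `L` is
non-increasing, strictly decreases on conflict-free steps with `L > 1`,
and once at 1 stays there until the track stabilizes. The property tests
assert exactly this corrected form, and consequently the `3d` hard bound
on time-to-deadlock is treated as a guideline, not an invariant.

## The exact oracle

For `k = 1`, `p = r = 0` the swarm is a finite absorbing Markov chain on
(occupied-cell set, heading vector) configurations; the absorbing classes
are exactly the heading-uniform states. The transition kernel is built *by
running the simulator's own step function* under a replay decision source
that enumerates every random draw with its probability — oracle and
simulator share one rule set and cannot drift apart. Expected absorption
times solve `h = 1 + P_transient h`, dense direct below 10⁴ states,
GMRES (tolerance 1e-10) above, with a hard cap of 10⁵ states. Initial
configurations can be enumerated up to the model's symmetry group
(rotations, and mirror-plus-heading-flip; order `2n`).

## Frozen states under r = 0

With `r = 0` there exists an absorbing configuration *without* consensus:
every track heading-uniform and perfectly alternating (`n/2` locusts, one
gap each), with the occupied parity aligned across all tracks. Every
locust then advances every step, all tracks flip parity in lockstep, every
vertical neighbor of every locust is occupied forever, and no conflict,
deliberate switch, or erratic hop can ever fire. This is precisely why the
guaranteed-global-consensus result requires `r > 0`. The run driver
detects this state (`is_frozen`, a provable freeze: the premises imply
rigid translation forever) and reports the run as a timeout; aggregation
averages over reached runs and reports timeouts separately. In the dense
erratic-behavior experiment about 1–3% of runs freeze; without the
detection they would burn the full step cap and distort the mean.

## Experiment sweeps and problem sizes

The pre-registered sweeps (`fig6a`–`fig6c`, `fig7`) cross sparse (10%,
two-per-track floor) and dense (50%) initializations with the `always` and
`never` policies over track-count, track-length, and hop-probability
grids, at 2000 replicates per point by default. Infeasible corners (n=1,
or arenas too small for the floor) are skipped and recorded. The erratic
panel's `p`-grid `{0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1}` is
log-spaced to resolve the sharp drop of the consensus time near `p ≈ 0.1`.
The acceptance script reruns only the headline points, at 500 replicates
(local-consensus points) and 300 replicates (global-consensus points) —
enough for standard errors of a few percent of the mean while a full rerun
stays in the minutes range on one core. The test suite uses desk-scale
instances (arenas up to ~30×30, replicate counts in the hundreds to a few
thousand) chosen so every stated tolerance is checked at or above its
stated replication.

## What the generator does and does not emulate

The synthetic configurations reproduce the study conditions exactly as
printed: uniform random placement at a given occupancy, the sparse top-up
floor, i.i.d. uniform headings. They do not model any feature of real
locust swarms beyond the model's own idealizations — no heterogeneous
agents, no alignment interactions, no density-dependent behavior change,
no continuous space or asynchronous wake-ups. Passing tests certify the
implementation of *this* idealized model and its published numbers, not
biological fidelity.

## Known limitations

* The exact oracle covers only `k = 1` (the multi-track state space
  explodes); multi-track theory is checked by monitored simulation
  properties instead.
* The printed headline means are reproduced under this package's reading
  of the ambiguous scheduling details (conflict adjacency read at the
  beginning of the step; condition (3) read post-horizontally; erratic
  hops in addition to, not instead of, horizontal movement). Alternative
  readings shift the global-consensus means by tens of percent.
* Where the two-per-track floor is disabled, tracks can empty, and
  simultaneous entrants into an empty track can create several segments at
  once; monotonicity statements hold for occupied tracks.
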