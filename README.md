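# ringmarch

Collective marching of locust-inspired agents on a discretized ring arena:
a reproducible simulator with built-in structural diagnostics, exact
small-instance oracles, and stabilization-time experiment sweeps.

## The problem

Locusts placed at random positions and orientations on a ring-shaped arena
famously end up all marching the same way around. `ringmarch` studies a
minimal algorithmic mechanism for that: `m` agents on `k` concentric
tracks of `n` cells (a discretized cylinder), each with a persistent
heading `b ∈ {+1, −1}` (clockwise / counterclockwise), moving one cell per
synchronous step under exclusion (one locust per cell; moves into cells
occupied at the step's start are refused; a contested empty cell goes to a
uniformly random contender). Agents never *want* to turn: a heading flips
only when a clockwise locust at `(x, y)` meets a counterclockwise one at
`(x+1, y)` head-on — a *conflict*, resolved by a uniformly random party
adopting the other's heading. To dodge an imminent conflict a locust may
instead switch tracks, but only into a spot flanked by locusts already
marching its way; with probability `p` per step it may also hop tracks
erratically, and with probability `r` it idles.

Under these rules each track reaches *local consensus* (one heading per
track) in finite expected time — for a single track within
`E[Tstable] ≤ m² + 2(n − m)` — and any erratic noise `p > 0` drives the
whole swarm to *global consensus*. The interesting quantitative questions
are about `Tstable`: deliberate track-switching roughly halves the sparse
local-consensus time, yet it *slows* global consensus by an order of
magnitude, because conflict avoidance starves the conflicts that
cross-track agreement needs. This package reproduces those numbers.

Intended users: researchers in collective behavior, swarm robotics, and
interacting-particle / opinion-dynamics models who want a verified,
seeded, inspectable implementation of this model class.

## Worked example

Simulate a 3-track, 12-cell arena at 25% occupancy and look at the start:

```bash
$ ringmarch render --n 12 --k 3 --density 0.25 --seed 7
.<<<>..<....
......<.>...
.>.....<....
```

Top line is the outermost track; `>` marches clockwise, `<`
counterclockwise, `.` is empty. Running the same configuration to
consensus:

```bash
$ ringmarch run --n 12 --k 3 --density 0.25 --seed 7
{
 "config": { "n": 12, "k": 3, "density": 0.25, "policy": "always", ... },
 "stop_mode": "auto",
 "tstable": 22,
 "reached": true,
 "total_conflicts": 20,
 "total_switches_eligible": 1,
 "total_switches_erratic": 0,
 "seed": 7,
 "version": "ringmarch-0.1.0"
}
```

`tstable` is the first step at whose beginning every track is
heading-uniform (local consensus — the `auto` stop mode, since `p = 0`):
here 22 steps, during which 20 head-on conflicts occurred and one locust
made a deliberate track switch. Same seed, same record, bit for bit.

The exact oracle solves tiny single-track instances in closed form via the
absorbing Markov chain built from the simulator's own step rules. From the
library:

```python
>>> from ringmarch.oracle import ChainSpec, exact_expected_stabilization_k1
>>> spec = ChainSpec(n=6, m=4, initial=((0, 1), (1, -1), (3, 1), (5, -1)))
>>> r = exact_expected_stabilization_k1(spec)
>>> r["expected_time"], r["state_count"]
(4.125, 32)
```

— from that 6-cell configuration, heading uniformity takes exactly 4.125
steps in expectation over the 32 reachable configurations; the test suite
checks seeded simulation means against such values to 3 standard errors.

Sweeps reproduce the published panels (means ± sd of `Tstable` over
replicates, CSV output):

```bash
ringmarch sweep --experiment fig6a --reps 2000 --seed 0 --out fig6a.csv
```

## Package layout

| module | contents |
|--------|----------|
| `ringmarch.model` | configuration, swarm state, the synchronous step (horizontal / vertical / conflict phases), run driver |
| `ringmarch.structure` | segments, maximal compact sets, deadlock pairs, the potentials L and F |
| `ringmarch.observables` | stability predicates, `Tstable` bookkeeping, replicate aggregation |
| `ringmarch.oracle` | exact Markov-chain expectations, gambler's-ruin closed form, bound calculators, worst-case construction |
| `ringmarch.experiments` | pre-registered sweeps with splittable seeding |
| `ringmarch.iotools`, `ringmarch.cli` | snapshots, traces, CSV tables, the `ringmarch` command |

See `docs/methods.md` for the model's exact scheduling conventions, the
initialization protocol, the frozen-state caveat at `r = 0`, and known
limitations.
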