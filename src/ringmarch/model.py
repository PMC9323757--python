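"""Dynamics engine for locust-inspired collective marching on a ring arena.

The arena is a discretized cylinder: ``k`` concentric tracks (rings), each
with ``n`` cells, indexed by coordinates ``(x, y)`` with ``x`` taken modulo
``n`` (clockwise = +x) and ``y`` in ``[0, k)``.  ``m`` identical agents
("locusts") each occupy one cell — at most one locust per cell — and carry a
persistent heading ``b`` in ``{+1, -1}`` (+1 = clockwise), their "opinion" in
the opinion-dynamics reading of the model.

One synchronous time step runs in a fixed order:

1. sample erratic-behavior flags (horizontal idling with probability ``r``,
   erratic vertical hops with probability ``p``),
2. detect *conflicts* on the beginning-of-step configuration — a clockwise
   locust at ``(x, y)`` immediately behind a counterclockwise locust at
   ``(x+1, y)``,
3. horizontal phase: each non-idling locust tries to advance one cell in its
   heading direction; cells occupied at the beginning of the step refuse
   entry, and an empty cell contested by two movers is granted to one of them
   uniformly at random,
4. vertical phase: locusts, processed in uniformly random order, may hop to
   an adjacent track — erratically (ignoring all preconditions) when flagged,
   or deliberately when the track-switching conditions (1)-(3) hold and the
   switching policy fires,
5. conflict resolution: in every conflict pair detected in (2), one party
   chosen uniformly at random flips its heading to the other's.

Randomness is funneled through a :class:`DecisionSource` so that the same
step code drives both seeded Monte-Carlo simulation and the exhaustive
branch enumeration used by the exact Markov-chain oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "ModelConfig",
    "SwarmState",
    "StepReport",
    "RunRecord",
    "DecisionSource",
    "RandomDecisions",
    "init_random_configuration",
    "front_locust",
    "detect_conflicts",
    "horizontal_phase",
    "vertical_eligibility",
    "vertical_phase",
    "apply_conflict_outcomes",
    "step",
    "simulate",
    "run_until_stable",
    "is_locally_stable",
    "is_global_consensus",
    "is_frozen",
    "make_rng",
]

POLICIES = ("never", "always", "bernoulli")


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent model configurations."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ModelConfig:
    """All parameters governing one simulation.

    Parameters
    ----------
    n, k
        Track length (cells per track, >= 2) and number of tracks (>= 1).
    m, density
        Population size, given either directly or as an occupancy fraction
        in (0, 1] from which ``m = max(2k*[enforce], round(density*n*k))``
        is derived (round half away from zero).  Exactly one must be set.
    r, p
        Per-locust, per-step probabilities of erratic horizontal idling and
        of an erratic vertical hop, each in [0, 1].
    policy
        Deliberate track-switching policy: ``"never"``, ``"always"`` (switch
        whenever conditions (1)-(3) allow), or ``"bernoulli"`` (switch with
        probability ``q`` when allowed).
    enforce_two_per_track
        Guarantee at least two locusts on every track at initialization
        (requires ``m >= 2k`` and ``n >= 2``).
    seed, max_steps
        Default RNG seed and the step cap for :func:`run_until_stable`.
    """

    n: int
    k: int
    m: Optional[int] = None
    density: Optional[float] = None
    r: float = 0.0
    p: float = 0.0
    policy: str = "always"
    q: Optional[float] = None
    enforce_two_per_track: bool = True
    seed: int = 0
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError(f"track length n must be >= 2, got {self.n}")
        if self.k < 1:
            raise ConfigError(f"track count k must be >= 1, got {self.k}")
        if (self.m is None) == (self.density is None):
            raise ConfigError("exactly one of m and density must be given")
        if self.density is not None and not (0.0 < self.density <= 1.0):
            raise ConfigError(f"density must be in (0, 1], got {self.density}")
        for name in ("r", "p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.policy not in POLICIES:
            raise ConfigError(
                f"policy must be one of {POLICIES}, got {self.policy!r}"
            )
        if self.policy == "bernoulli":
            if self.q is None or not (0.0 <= self.q <= 1.0):
                raise ConfigError("policy 'bernoulli' requires q in [0, 1]")
        elif self.q is not None:
            raise ConfigError("q is only meaningful with policy 'bernoulli'")
        if self.max_steps <= 0:
            raise ConfigError("max_steps must be positive")
        m = self.resolved_m
        if m > self.n * self.k:
            raise ConfigError(
                f"m={m} exceeds arena capacity n*k={self.n * self.k}"
            )
        if self.enforce_two_per_track and m < 2 * self.k:
            raise ConfigError(
                f"two-per-track guarantee needs m >= 2k = {2 * self.k}, got m={m}"
            )
        if m < 0:
            raise ConfigError(f"m must be non-negative, got {m}")

    @property
    def resolved_m(self) -> int:
        """Population size, derived from ``density`` when ``m`` is not set."""
        if self.m is not None:
            return self.m
        floor = 2 * self.k if self.enforce_two_per_track else 0
        return max(floor, _round_half_away(self.density * self.n * self.k))


class SwarmState:
    """Complete configuration at one time step.

    Locusts are stored as parallel lists ``xs``, ``ys``, ``bs`` indexed by
    locust id; ``grid`` is a flat occupancy map of length ``n*k`` holding the
    occupant id of cell ``(x, y)`` at index ``y*n + x``, or -1 when empty.
    """

    __slots__ = ("n", "k", "t", "xs", "ys", "bs", "grid")

    def __init__(
        self,
        n: int,
        k: int,
        xs: Sequence[int],
        ys: Sequence[int],
        bs: Sequence[int],
        t: int = 0,
    ) -> None:
        self.n = n
        self.k = k
        self.t = t
        self.xs = list(xs)
        self.ys = list(ys)
        self.bs = list(bs)
        grid = [-1] * (n * k)
        for i, (x, y, b) in enumerate(zip(self.xs, self.ys, self.bs)):
            if not (0 <= x < n and 0 <= y < k):
                raise ConfigError(f"locust {i} at ({x}, {y}) is out of bounds")
            if b not in (1, -1):
                raise ConfigError(f"locust {i} has invalid heading {b}")
            cell = y * n + x
            if grid[cell] != -1:
                raise ConfigError(
                    f"cell ({x}, {y}) occupied by both locusts {grid[cell]} and {i}"
                )
            grid[cell] = i
        self.grid = grid

    @property
    def m(self) -> int:
        return len(self.xs)

    def occupant(self, x: int, y: int) -> int:
        """Locust id at cell ``(x mod n, y)``, or -1 when empty."""
        return self.grid[y * self.n + (x % self.n)]

    def copy(self) -> "SwarmState":
        new = SwarmState.__new__(SwarmState)
        new.n, new.k, new.t = self.n, self.k, self.t
        new.xs = self.xs[:]
        new.ys = self.ys[:]
        new.bs = self.bs[:]
        new.grid = self.grid[:]
        return new

    def key(self) -> tuple:
        """Canonical label-free encoding (locust identities are exchangeable)."""
        return tuple(sorted(zip(self.xs, self.ys, self.bs)))

    def track_occupants(self, y: int) -> list[int]:
        """Ids of locusts on track ``y``, ordered by increasing ``x``."""
        base = y * self.n
        return [i for i in self.grid[base : base + self.n] if i >= 0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SwarmState):
            return NotImplemented
        return (
            self.n == other.n
            and self.k == other.k
            and self.t == other.t
            and self.xs == other.xs
            and self.ys == other.ys
            and self.bs == other.bs
        )

    def __repr__(self) -> str:
        return (
            f"SwarmState(n={self.n}, k={self.k}, t={self.t}, m={self.m})"
        )


@dataclass
class StepReport:
    """Everything that happened during one synchronous step."""

    horizontal_moves: list = field(default_factory=list)  # (id, (x,y), (x,y))
    blocked: list = field(default_factory=list)  # ids refused horizontally
    idled_erratically: list = field(default_factory=list)  # ids idling (prob r)
    conflicts: list = field(default_factory=list)  # (cw id, ccw id) pairs
    flips: list = field(default_factory=list)  # (id, new heading)
    switches: list = field(default_factory=list)  # (id, (x,y), (x,y), reason)


@dataclass
class RunRecord:
    """Outcome of one run-until-stable simulation."""

    config: ModelConfig
    stop_mode: str
    tstable: int
    reached: bool
    total_conflicts: int
    total_switches_eligible: int
    total_switches_erratic: int
    seed: Optional[int] = None
    final_state: Optional[SwarmState] = field(
        default=None, repr=False, compare=False
    )


# ---------------------------------------------------------------------------
# Randomness plumbing
# ---------------------------------------------------------------------------


class DecisionSource:
    """Interface through which the step consumes randomness.

    The documented draw order within one step is: erratic flags (idle, then
    vertical) -> horizontal tie-breaks (ascending contested-cell index) ->
    vertical processing order -> per-locust vertical draws (policy gate,
    direction ties) -> conflict winners (detection order).  Draws with
    probability 0 or 1 and the vertical processing order on arenas where no
    vertical move is possible consume no randomness.
    """

    def bernoulli_flags(self, count: int, prob: float) -> list[bool]:
        raise NotImplementedError

    def bernoulli(self, prob: float) -> bool:
        raise NotImplementedError

    def uniform_index(self, n_options: int) -> int:
        raise NotImplementedError

    def permutation(self, count: int) -> Sequence[int]:
        raise NotImplementedError


class RandomDecisions(DecisionSource):
    """Decision source backed by a seeded :class:`numpy.random.Generator`."""

    __slots__ = ("rng",)

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def bernoulli_flags(self, count: int, prob: float) -> list[bool]:
        if prob <= 0.0:
            return [False] * count
        if prob >= 1.0:
            return [True] * count
        return (self.rng.random(count) < prob).tolist()

    def bernoulli(self, prob: float) -> bool:
        if prob <= 0.0:
            return False
        if prob >= 1.0:
            return True
        return bool(self.rng.random() < prob)

    def uniform_index(self, n_options: int) -> int:
        if n_options == 1:
            return 0
        return int(self.rng.integers(n_options))

    def permutation(self, count: int) -> Sequence[int]:
        return self.rng.permutation(count).tolist()


def make_rng(seed) -> np.random.Generator:
    """Build a generator from a seed, SeedSequence, or pass one through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def init_random_configuration(
    cfg: ModelConfig, rng: np.random.Generator
) -> SwarmState:
    """Place locusts at distinct random cells with i.i.d. uniform headings.

    Density-driven configurations emulate the occupancy-fraction experiment
    protocol: ``round(density * n * k)`` cells are drawn uniformly over the
    whole arena, and — when ``enforce_two_per_track`` is set — tracks left
    with fewer than two locusts are topped up with extra locusts at random
    free cells of that track, so the realized population can slightly exceed
    the nominal ``resolved_m``.  Explicit-``m`` configurations place exactly
    ``m`` locusts: under enforcement, two per track first (uniform within
    each track), then the remainder uniformly over the free cells.
    """
    n, k = cfg.n, cfg.k
    cells: list[int] = []
    if cfg.density is not None:
        base = _round_half_away(cfg.density * n * k)
        taken = set(int(c) for c in rng.choice(n * k, size=base, replace=False))
        if cfg.enforce_two_per_track:
            for y in range(k):
                deficit = 2 - sum(1 for c in taken if c // n == y)
                if deficit > 0:
                    free = [y * n + x for x in range(n) if y * n + x not in taken]
                    for _ in range(deficit):
                        c = free.pop(int(rng.integers(len(free))))
                        taken.add(c)
        cells = sorted(taken)
    elif cfg.enforce_two_per_track:
        m = cfg.resolved_m
        taken = set()
        for y in range(k):
            for x in rng.choice(n, size=2, replace=False):
                cell = y * n + int(x)
                cells.append(cell)
                taken.add(cell)
        extra = m - 2 * k
        if extra > 0:
            free = [c for c in range(n * k) if c not in taken]
            for idx in rng.choice(len(free), size=extra, replace=False):
                cells.append(free[int(idx)])
    else:
        cells = [int(c) for c in rng.choice(n * k, size=cfg.resolved_m, replace=False)]
    m = len(cells)
    bs = (rng.integers(0, 2, size=m) * 2 - 1).tolist() if m else []
    xs = [c % n for c in cells]
    ys = [c // n for c in cells]
    return SwarmState(n, k, xs, ys, bs, t=0)


# ---------------------------------------------------------------------------
# Neighborhood queries
# ---------------------------------------------------------------------------


def front_locust(state: SwarmState, locust_id: int, which: str = "front") -> int:
    """Id of the first locust ahead of (or behind) ``locust_id`` on its track.

    "Front" scans in the heading direction, "back" against it, wrapping
    around the ring; a lone locust is its own front and back.
    """
    if which not in ("front", "back"):
        raise ValueError(f"which must be 'front' or 'back', got {which!r}")
    n = state.n
    x, y, b = state.xs[locust_id], state.ys[locust_id], state.bs[locust_id]
    direction = b if which == "front" else -b
    base = y * n
    for d in range(1, n + 1):
        occ = state.grid[base + (x + direction * d) % n]
        if occ >= 0:
            return occ
    return locust_id  # unreachable: the scan reaches x itself at d == n


# ---------------------------------------------------------------------------
# Phases of one synchronous step
# ---------------------------------------------------------------------------


def detect_conflicts(state: SwarmState) -> list[tuple[int, int]]:
    """All (clockwise id, counterclockwise id) pairs at cells (x, y), (x+1, y).

    Each locust appears in at most one pair: a clockwise locust's only
    conflict cell lies ahead of it, a counterclockwise locust's only conflict
    cell behind it.
    """
    n = state.n
    pairs = []
    for i in range(state.m):
        if state.bs[i] == 1:
            j = state.grid[state.ys[i] * n + (state.xs[i] + 1) % n]
            if j >= 0 and state.bs[j] == -1:
                pairs.append((i, j))
    return pairs


def horizontal_phase(
    state: SwarmState,
    idle_flags: Sequence[bool],
    decisions: DecisionSource,
    report: Optional[StepReport] = None,
) -> tuple[SwarmState, StepReport]:
    """Apply simultaneous horizontal movement with exclusion.

    Every non-idling locust targets the next cell in its heading direction.
    Targets occupied at the *beginning* of the step are refused (no
    follow-into-vacated-cell, no swaps); each contested empty cell is granted
    to one contender chosen uniformly at random.
    """
    if report is None:
        report = StepReport()
    n = state.n
    new = state.copy()
    wants: dict[int, list[int]] = {}
    for i in range(state.m):
        if idle_flags[i]:
            report.idled_erratically.append(i)
            continue
        target = state.ys[i] * n + (state.xs[i] + state.bs[i]) % n
        if state.grid[target] >= 0:
            report.blocked.append(i)
        else:
            wants.setdefault(target, []).append(i)
    for target in sorted(wants):
        contenders = wants[target]
        if len(contenders) == 1:
            winner = contenders[0]
        else:
            winner = contenders[decisions.uniform_index(len(contenders))]
            report.blocked.extend(c for c in contenders if c != winner)
        old_x, y = state.xs[winner], state.ys[winner]
        new.grid[y * n + old_x] = -1
        new_x = target - y * n
        new.xs[winner] = new_x
        new.grid[target] = winner
        report.horizontal_moves.append((winner, (old_x, y), (new_x, y)))
    return new, report


def vertical_eligibility(
    begin_state: SwarmState,
    mid_state: SwarmState,
    locust_id: int,
    direction: int,
    reserved: Optional[set] = None,
) -> bool:
    """Check the deliberate track-switching conditions (1)-(3) for one locust.

    Condition (1), read on the beginning-of-step configuration: the locust's
    front on its own track exists, has the opposite heading, and the two are
    not ring-adjacent (an imminent but not yet immediate head-on conflict).
    Conditions (2)-(3), read on the post-horizontal configuration: the target
    cell ``E = (x, y + direction)`` is empty (and unclaimed by an earlier
    vertical mover), the would-be front and back on the target track share
    the locust's heading, and no locust on the target track would attempt to
    move into ``E`` next step — no clockwise locust at ``x - 1`` and no
    counterclockwise locust at ``x + 1``.
    """
    n, k = mid_state.n, mid_state.k
    ty = mid_state.ys[locust_id] + direction
    if not (0 <= ty < k):
        return False  # edge tracks cannot leave the arena
    b = begin_state.bs[locust_id]
    # Condition (1): imminent conflict with the front, on the begin state.
    fr = front_locust(begin_state, locust_id, "front")
    if fr == locust_id or begin_state.bs[fr] == b:
        return False
    gap = (begin_state.xs[fr] - begin_state.xs[locust_id]) % n
    if min(gap, n - gap) <= 1:
        return False
    # Conditions (2)-(3): on the post-horizontal state.
    x = mid_state.xs[locust_id]
    target_cell = ty * n + x
    if mid_state.grid[target_cell] >= 0:
        return False
    if reserved is not None and target_cell in reserved:
        return False
    base = ty * n
    for scan_dir in (b, -b):  # front then back on the target track
        for d in range(1, n):
            occ = mid_state.grid[base + (x + scan_dir * d) % n]
            if occ >= 0:
                if mid_state.bs[occ] != b:
                    return False
                break
        # empty target track: vacuously acceptable neighbors
    left = mid_state.grid[base + (x - 1) % n]
    if left >= 0 and mid_state.bs[left] == 1:
        return False
    right = mid_state.grid[base + (x + 1) % n]
    if right >= 0 and mid_state.bs[right] == -1:
        return False
    return True


def vertical_phase(
    begin_state: SwarmState,
    mid_state: SwarmState,
    cfg: ModelConfig,
    erratic_flags: Sequence[bool],
    decisions: DecisionSource,
    report: Optional[StepReport] = None,
) -> tuple[SwarmState, StepReport]:
    """Apply track switches, erratic and deliberate.

    Locusts are processed in a uniformly random order (a valid instance of
    the model's arbitrary switching scheduler).  An erratic-flagged locust
    hops to a uniformly chosen adjacent empty vertical cell if one exists,
    ignoring conditions (1)-(3), and takes no deliberate move that step.
    Otherwise the switching policy decides whether an eligible move is taken,
    with two-way up/down ties broken uniformly.  Occupancy and headings are
    read from the post-horizontal configuration; cells claimed by earlier
    movers in the processing order are reserved.
    """
    if report is None:
        report = StepReport()
    m = mid_state.m
    n, k = mid_state.n, mid_state.k
    can_move = k > 1 and (cfg.policy != "never" or any(erratic_flags))
    if not can_move:
        return mid_state.copy(), report
    order = decisions.permutation(m)
    reserved: set[int] = set()
    planned: list[tuple[int, int, str]] = []  # (id, direction, reason)
    for i in order:
        y = mid_state.ys[i]
        if erratic_flags[i]:
            x = mid_state.xs[i]
            options = []
            for direction in (1, -1):
                ty = y + direction
                if 0 <= ty < k:
                    cell = ty * n + x
                    if mid_state.grid[cell] < 0 and cell not in reserved:
                        options.append(direction)
            if options:
                if len(options) == 2:
                    direction = options[decisions.uniform_index(2)]
                else:
                    direction = options[0]
                reserved.add((y + direction) * n + mid_state.xs[i])
                planned.append((i, direction, "erratic"))
            continue
        if cfg.policy == "never":
            continue
        if cfg.policy == "bernoulli" and not decisions.bernoulli(cfg.q):
            continue
        dirs = [
            d
            for d in (1, -1)
            if vertical_eligibility(begin_state, mid_state, i, d, reserved)
        ]
        if dirs:
            if len(dirs) == 2:
                direction = dirs[decisions.uniform_index(2)]
            else:
                direction = dirs[0]
            reserved.add((y + direction) * n + mid_state.xs[i])
            planned.append((i, direction, "eligible"))
    new = mid_state.copy()
    for i, direction, reason in planned:
        x, y = new.xs[i], new.ys[i]
        new.grid[y * n + x] = -1
        new.ys[i] = y + direction
        new.grid[new.ys[i] * n + x] = i
        report.switches.append((i, (x, y), (x, y + direction), reason))
    return new, report


def apply_conflict_outcomes(
    state: SwarmState,
    conflicts: Sequence[tuple[int, int]],
    decisions: DecisionSource,
    report: Optional[StepReport] = None,
) -> tuple[SwarmState, StepReport]:
    """Resolve each conflict: one party, chosen uniformly, flips its heading.

    Flips are independent across pairs, applied at end of step and addressed
    by locust id (a flipped locust may have moved erratically meanwhile).
    """
    if report is None:
        report = StepReport()
    new = state.copy()
    for pair in conflicts:
        loser = pair[decisions.uniform_index(2)]
        new.bs[loser] = -new.bs[loser]
        report.flips.append((loser, new.bs[loser]))
    return new, report


def step(
    state: SwarmState, cfg: ModelConfig, decisions: DecisionSource
) -> tuple[SwarmState, StepReport]:
    """Advance the swarm by one synchronous time step.

    Composition in fixed order: sample erratic flags, detect conflicts on the
    beginning-of-step state, horizontal phase, vertical phase, end-of-step
    conflict resolution, increment ``t``.  The input state is not mutated.
    """
    report = StepReport()
    m = state.m
    idle_flags = decisions.bernoulli_flags(m, cfg.r)
    erratic_flags = decisions.bernoulli_flags(m, cfg.p)
    conflicts = detect_conflicts(state)
    report.conflicts = conflicts
    mid, report = horizontal_phase(state, idle_flags, decisions, report)
    after_vertical, report = vertical_phase(
        state, mid, cfg, erratic_flags, decisions, report
    )
    new, report = apply_conflict_outcomes(
        after_vertical, conflicts, decisions, report
    )
    new.t = state.t + 1
    return new, report


# ---------------------------------------------------------------------------
# Run driver
# ---------------------------------------------------------------------------


def is_locally_stable(state: SwarmState) -> bool:
    """True when every track is heading-uniform (empty tracks vacuously so)."""
    seen = [0] * state.k
    for y, b in zip(state.ys, state.bs):
        if seen[y] == 0:
            seen[y] = b
        elif seen[y] != b:
            return False
    return True


def is_global_consensus(state: SwarmState) -> bool:
    """True when all locusts share one heading."""
    bs = state.bs
    return all(b == bs[0] for b in bs) if bs else True


def is_frozen(state: SwarmState, cfg: ModelConfig) -> bool:
    """Detect the parity-locked checkerboard, absorbing without consensus.

    With ``r = 0``, a configuration in which every track is heading-uniform
    and *perfectly alternating* (exactly ``n/2`` locusts, one empty cell
    between each pair), with the occupied parity identical across all
    tracks, can never change again: every locust advances every step, so
    each track's occupied parity flips in lockstep, every vertical neighbor
    of every locust stays occupied forever, and no conflict, deliberate
    switch, or erratic hop can ever fire.  When the tracks disagree on
    heading, such a state blocks global consensus permanently — this is why
    the guaranteed-consensus result for erratic behavior requires ``r > 0``.
    Returns False whenever the premises fail (``r > 0``, odd ``n``, any
    non-alternating track), in which case nothing is claimed.
    """
    if cfg.r > 0 or state.n % 2 or is_global_consensus(state):
        return False
    if not is_locally_stable(state):
        return False
    half = state.n // 2
    parity = None
    counts = [0] * state.k
    for x, y in zip(state.xs, state.ys):
        counts[y] += 1
        if parity is None:
            parity = x % 2
        elif x % 2 != parity:
            return False
    return all(c == half for c in counts)


def _stop_predicate(stop_mode: str, cfg: ModelConfig) -> Callable[[SwarmState], bool]:
    if stop_mode == "auto":
        stop_mode = "global" if cfg.p > 0 else "local"
    if stop_mode == "local":
        return is_locally_stable
    if stop_mode == "global":
        return is_global_consensus
    raise ValueError(f"stop_mode must be local, global or auto, got {stop_mode!r}")


def simulate(
    state: SwarmState,
    cfg: ModelConfig,
    decisions: DecisionSource,
    max_steps: Optional[int] = None,
) -> Iterator[tuple[SwarmState, StepReport]]:
    """Yield ``(state, report)`` after each step, up to ``max_steps`` steps."""
    limit = cfg.max_steps if max_steps is None else max_steps
    for _ in range(limit):
        state, report = step(state, cfg, decisions)
        yield state, report


def run_until_stable(
    cfg: ModelConfig,
    rng=None,
    stop_mode: str = "auto",
    initial_state: Optional[SwarmState] = None,
    keep_final_state: bool = False,
) -> RunRecord:
    """Run from a random (or given) initial configuration until consensus.

    The stop predicate — per-track uniformity ("local"), identical headings
    everywhere ("global"), or "auto" (global when ``p > 0``, else local) — is
    evaluated at the *beginning* of each step; a swarm initialized uniform
    has ``tstable = 0``.  Hitting ``max_steps`` is data, not an error: the
    record comes back with ``reached=False`` and ``tstable = max_steps``.
    A run waiting for global consensus that enters the provably-absorbing
    parity-locked checkerboard (see :func:`is_frozen`) is cut short and
    reported the same way, since no further step can ever change it.
    """
    seed = cfg.seed if rng is None else (rng if isinstance(rng, int) else None)
    generator = make_rng(cfg.seed if rng is None else rng)
    decisions = RandomDecisions(generator)
    state = (
        init_random_configuration(cfg, generator)
        if initial_state is None
        else initial_state.copy()
    )
    predicate = _stop_predicate(stop_mode, cfg)
    wants_global = predicate is is_global_consensus
    total_conflicts = 0
    eligible = 0
    erratic = 0
    while True:
        if predicate(state):
            tstable, reached = state.t, True
            break
        if state.t >= cfg.max_steps or (
            wants_global and is_frozen(state, cfg)
        ):
            tstable, reached = cfg.max_steps, False
            break
        state, report = step(state, cfg, decisions)
        total_conflicts += len(report.conflicts)
        for _, _, _, reason in report.switches:
            if reason == "eligible":
                eligible += 1
            else:
                erratic += 1
    return RunRecord(
        config=cfg,
        stop_mode=stop_mode,
        tstable=tstable,
        reached=reached,
        total_conflicts=total_conflicts,
        total_switches_eligible=eligible,
        total_switches_erratic=erratic,
        seed=seed,
        final_state=state if keep_final_state else None,
    )
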