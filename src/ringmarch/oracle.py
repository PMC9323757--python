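"""Exact and closed-form references for the marching dynamics.

For a single track without erratic behavior the swarm is a finite absorbing
Markov chain on (occupied-cell set, heading vector) configurations whose
absorbing classes are exactly the heading-uniform states.  This module
builds that chain *symbolically from the simulator's own step function*, by
enumerating every random draw a step can consume together with its
probability — so the oracle and the simulator share one set of movement
rules and cannot drift apart — and solves the expected-absorption-time
linear system exactly.

Also here: the gambler's-ruin closed form (a symmetric random walk between
absorbing barriers ``a`` and ``-b`` is absorbed in expected time ``a*b``,
the engine behind segment-size evolution under deadlock), the analytic
stabilization-time bound calculators, and the asymptotically-worst-case
two-segment initial configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log
from typing import Optional, Sequence

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .model import (
    ConfigError,
    DecisionSource,
    ModelConfig,
    SwarmState,
    step,
)

__all__ = [
    "ChainSpec",
    "ReplayDecisions",
    "enumerate_step_outcomes",
    "exact_expected_stabilization_k1",
    "enumerate_initial_classes",
    "state_from_key",
    "gambler_ruin_time",
    "theorem_bounds",
    "worst_case_configuration",
]

#: Refuse chain solves beyond this many configurations.
STATE_CAP = 100_000

#: Switch from a dense direct solve to an iterative one above this size.
DENSE_LIMIT = 10_000

#: Residual tolerance of the iterative solver.
SOLVE_TOL = 1e-10


# ---------------------------------------------------------------------------
# Branch enumeration of one step
# ---------------------------------------------------------------------------


class ReplayDecisions(DecisionSource):
    """Decision source that replays a recorded prefix, then defaults.

    Every consumed decision is appended to ``trace`` as
    ``(choice, n_options, probability_of_choice)``.  Running the step once
    per unexplored branch enumerates the full outcome distribution.
    """

    def __init__(self, prefix: Sequence[tuple] = ()) -> None:
        self.prefix = list(prefix)
        self.trace: list[tuple] = []

    def _next(self, n_options: int, probs: Optional[Sequence[float]] = None):
        pos = len(self.trace)
        if pos < len(self.prefix):
            choice = self.prefix[pos][0]
        else:
            choice = 0
        prob = (1.0 / n_options) if probs is None else probs[choice]
        self.trace.append((choice, n_options, prob, probs))
        return choice

    def bernoulli_flags(self, count: int, prob: float) -> list[bool]:
        if prob <= 0.0:
            return [False] * count
        if prob >= 1.0:
            return [True] * count
        return [self.bernoulli(prob) for _ in range(count)]

    def bernoulli(self, prob: float) -> bool:
        if prob <= 0.0:
            return False
        if prob >= 1.0:
            return True
        return self._next(2, (1.0 - prob, prob)) == 1

    def uniform_index(self, n_options: int) -> int:
        if n_options == 1:
            return 0
        return self._next(n_options)

    def permutation(self, count: int) -> Sequence[int]:
        if count <= 1:
            return list(range(count))
        raise NotImplementedError(
            "branch enumeration over processing orders is not supported; "
            "the exact chain covers k=1 where no vertical move exists"
        )


def enumerate_step_outcomes(
    state: SwarmState, cfg: ModelConfig
) -> dict[tuple, float]:
    """Exact one-step outcome distribution ``{state key: probability}``.

    Runs :func:`ringmarch.model.step` once per decision branch, depth-first
    over the tree of random draws it consumes.
    """
    outcomes: dict[tuple, float] = {}
    stack: list[list[tuple]] = [[]]
    while stack:
        prefix = stack.pop()
        ds = ReplayDecisions(prefix)
        new_state, _ = step(state, cfg, ds)
        prob = 1.0
        for _, _, p, _ in ds.trace:
            prob *= p
        key = new_state.key()
        outcomes[key] = outcomes.get(key, 0.0) + prob
        for pos in range(len(prefix), len(ds.trace)):
            choice, n_options, _, _probs = ds.trace[pos]
            head = [(t[0],) for t in ds.trace[:pos]]
            for alt in range(n_options):
                if alt != choice:
                    stack.append(head + [(alt,)])
    return outcomes


# ---------------------------------------------------------------------------
# Exact expected stabilization time (k = 1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainSpec:
    """A single-track, noise-free chain instance.

    The state space is all ``C(n, m) * 2**m`` (position-set, heading-vector)
    configurations; the initial condition is either one configuration key or
    a distribution ``{key: weight}``.  ``policy`` is irrelevant on one track
    (no vertical move exists) and erratic behavior is excluded so the chain
    stays finite-branching.
    """

    n: int
    m: int
    initial: object  # state key, SwarmState, or {key: weight}

    def __post_init__(self) -> None:
        if self.m < 1 or self.m > self.n:
            raise ConfigError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")
        if self.state_count > STATE_CAP:
            raise ConfigError(
                f"state space C({self.n},{self.m})*2^{self.m} = "
                f"{self.state_count} exceeds the cap of {STATE_CAP}"
            )

    @property
    def state_count(self) -> int:
        return comb(self.n, self.m) * 2**self.m


def state_from_key(key: Sequence[tuple], n: int, k: int = 1) -> SwarmState:
    """Rebuild a swarm configuration from its canonical key."""
    if k == 1:
        xs = [x for x, b in key]
        ys = [0] * len(key)
        bs = [b for x, b in key]
    else:
        xs = [x for x, y, b in key]
        ys = [y for x, y, b in key]
        bs = [b for x, y, b in key]
    return SwarmState(n, k, xs, ys, bs)


def _k1_key(state_key: tuple) -> tuple:
    """Project a (x, y, b) key onto (x, b) for the single-track chain."""
    return tuple((x, b) for x, y, b in state_key)


def _is_absorbing(key: tuple) -> bool:
    return len({b for _, b in key}) <= 1


def exact_expected_stabilization_k1(spec: ChainSpec) -> dict:
    """Exact expected time to heading uniformity for one track.

    Explores the chain reachable from the initial configuration(s), forms
    the expected-hitting-time system ``h = 1 + P h`` on the transient
    states, and solves it directly (dense below 10^4 states, iterative
    above, residual tolerance 1e-10).  Returns the expectation from the
    initial distribution together with the explored state count.
    """
    n = spec.n
    cfg = ModelConfig(
        n=n, k=1, m=spec.m, policy="never", enforce_two_per_track=False
    )

    if isinstance(spec.initial, SwarmState):
        initial = {_k1_key(spec.initial.key()): 1.0}
    elif isinstance(spec.initial, dict):
        initial = {tuple(k): float(v) for k, v in spec.initial.items()}
    else:
        initial = {tuple(spec.initial): 1.0}
    total = sum(initial.values())
    initial = {k: v / total for k, v in initial.items()}

    index: dict[tuple, int] = {}
    frontier = list(initial)
    transitions: dict[int, dict[int, float]] = {}
    for key in frontier:
        index[key] = len(index)
    while frontier:
        key = frontier.pop()
        i = index[key]
        if _is_absorbing(key):
            continue
        outs = enumerate_step_outcomes(state_from_key(key, n), cfg)
        row: dict[int, float] = {}
        for out_key3, prob in outs.items():
            out_key = _k1_key(out_key3)
            if out_key not in index:
                index[out_key] = len(index)
                if len(index) > STATE_CAP:
                    raise ConfigError("reachable state space exceeds the cap")
                frontier.append(out_key)
            j = index[out_key]
            row[j] = row.get(j, 0.0) + prob
        transitions[i] = row

    transient = sorted(transitions)
    pos = {i: t for t, i in enumerate(transient)}
    nt = len(transient)
    h = np.zeros(len(index))
    if nt:
        rows, cols, vals = [], [], []
        for i in transient:
            for j, prob in transitions[i].items():
                if j in pos:  # transient -> transient
                    rows.append(pos[i])
                    cols.append(pos[j])
                    vals.append(prob)
        P = scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(nt, nt)
        )
        A = scipy.sparse.identity(nt, format="csr") - P
        b = np.ones(nt)
        if nt <= DENSE_LIMIT:
            ht = np.linalg.solve(A.toarray(), b)
        else:
            ht, info = scipy.sparse.linalg.gmres(A, b, rtol=SOLVE_TOL)
            if info != 0:
                raise RuntimeError(f"iterative hitting-time solve failed ({info})")
        for i in transient:
            h[i] = ht[pos[i]]
    expected = sum(w * h[index[key]] for key, w in initial.items())
    return {
        "expected_time": float(expected),
        "state_count": len(index),
        "transient_count": nt,
        "hitting_times": {key: float(h[i]) for key, i in index.items()},
    }


def enumerate_initial_classes(n: int, m: int) -> list[tuple[tuple, int]]:
    """Representatives of all single-track configurations up to symmetry.

    The dynamics commute with ring rotations and with the mirror map
    (x -> -x combined with a global heading flip), a symmetry group of
    order ``2n``.  Returns ``(canonical key, class size)`` pairs covering
    every (position-set, heading-vector) configuration exactly once, the
    heading-uniform (absorbed) classes included.
    """
    from itertools import combinations, product

    def canonical(key: tuple) -> tuple:
        variants = []
        for flip in (False, True):
            pts = (
                [((-x) % n, -b) for x, b in key] if flip else list(key)
            )
            for s in range(n):
                variants.append(tuple(sorted(((x + s) % n, b) for x, b in pts)))
        return min(variants)

    seen: dict[tuple, int] = {}
    for cells in combinations(range(n), m):
        for headings in product((1, -1), repeat=m):
            key = tuple(zip(cells, headings))
            c = canonical(key)
            seen[c] = seen.get(c, 0) + 1
    return sorted(seen.items())


# ---------------------------------------------------------------------------
# Closed forms and bounds
# ---------------------------------------------------------------------------


def gambler_ruin_time(a: int, b: int) -> int:
    """Expected absorption time ``a * b`` of a symmetric +-1 random walk.

    The walk starts at 0 with absorbing barriers at ``+a`` and ``-b``; by
    first-step analysis its expected duration is exactly ``a * b``.  Under
    deadlock, each conflict shifts the sizes of the two facing segments by
    +-1, so the expected number of conflicts until one segment of size
    ``a`` or its opponent of size ``b`` is eliminated is ``a * b``.
    """
    if a < 1 or b < 1:
        raise ValueError(f"barriers must be positive integers, got {a}, {b}")
    return a * b


def theorem_bounds(n: int, m: int, k: int = 1) -> dict:
    """Analytic stabilization-time quantities for a given geometry.

    ``single_track_bound`` is the exact expected-time ceiling
    ``m**2 + 2*(n - m)`` for one track.  ``multi_track_quantities`` are the
    two asymptotic-order expressions ``log(k) * n**2`` and ``m * n`` whose
    minimum governs the multi-track expectation — diagnostic scales for
    ratio plots, not hard ceilings.
    """
    if n < 1 or k < 1 or m < 0 or m > n * k:
        raise ValueError(f"invalid dimensions n={n}, m={m}, k={k}")
    return {
        "single_track_bound": m**2 + 2 * (n - m),
        "multi_track_quantities": (log(k) * n**2 if k > 1 else 0.0, m * n),
    }


def worst_case_configuration(n: int, m: int) -> SwarmState:
    """The asymptotically slowest two-segment single-track start.

    Two opposing blocks of ``m/2`` locusts each: a clockwise block on cells
    ``0 .. m/2 - 1`` and a counterclockwise block on cells ``n-1`` down to
    ``n - m/2``, facing each other across the empty arc between them.  The
    heads approach at combined speed at most 2 (so any run needs at least
    ``ceil((n - m) / 2)`` steps), and once deadlocked the segment sizes
    perform a symmetric random walk whose resolution costs ``(m/2)**2``
    conflicts in expectation.
    """
    if m % 2 or m < 2:
        raise ConfigError(f"m must be a positive even integer, got {m}")
    if m >= n:
        raise ConfigError(f"need m < n for two separated segments, got m={m}, n={n}")
    half = m // 2
    xs = list(range(half)) + [(n - 1 - i) % n for i in range(half)]
    ys = [0] * m
    bs = [1] * half + [-1] * half
    return SwarmState(n, 1, xs, ys, bs)
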