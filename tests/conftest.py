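"""Shared fixtures and helpers for the ringmarch test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ringmarch import ModelConfig, RandomDecisions, SwarmState


def seeded_rng(entropy: int, *key: int) -> np.random.Generator:
    """Deterministic, splittable generator for replicate tests."""
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy, spawn_key=key))


def random_swarm(rng: np.random.Generator, n: int, k: int, m: int) -> SwarmState:
    """Uniform random configuration with i.i.d. headings (no track floor)."""
    cells = rng.choice(n * k, size=m, replace=False)
    return SwarmState(
        n,
        k,
        xs=[int(c) % n for c in cells],
        ys=[int(c) // n for c in cells],
        bs=(rng.integers(0, 2, size=m) * 2 - 1).tolist(),
    )


def track_state(n: int, placement: dict[int, int]) -> SwarmState:
    """Single-track state from a {x: heading} mapping."""
    xs = sorted(placement)
    return SwarmState(n, 1, xs, [0] * len(xs), [placement[x] for x in xs])


def two_segment_state(
    rng: np.random.Generator, n: int, a: int, b: int
) -> tuple[SwarmState, int]:
    """A single track holding one clockwise and one counterclockwise segment.

    The clockwise segment's tail sits at x=0 and the counterclockwise tail
    at x=d; members are spread with random gaps inside the arc [0, d].
    Returns the state and the tail-to-tail clockwise distance d.
    """
    while True:
        xs = [0]
        for _ in range(a - 1):
            xs.append(xs[-1] + 1 + int(rng.integers(0, 3)))
        xs.append(xs[-1] + 1 + int(rng.integers(1, 5)))  # inter-segment gap
        for _ in range(b - 1):
            xs.append(xs[-1] + 1 + int(rng.integers(0, 3)))
        d = xs[-1]
        if d <= n - 2:  # leave the complementary arc non-trivial
            bs = [1] * a + [-1] * b
            return SwarmState(n, 1, xs, [0] * (a + b), bs), d


@pytest.fixture
def rng() -> np.random.Generator:
    return seeded_rng(20260920)


@pytest.fixture
def decisions(rng) -> RandomDecisions:
    return RandomDecisions(rng)


@pytest.fixture
def small_cfg() -> ModelConfig:
    return ModelConfig(n=8, k=2, m=6, policy="always", enforce_two_per_track=False)
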