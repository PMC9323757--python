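"""Stability predicates, stabilization-time bookkeeping, and aggregation.

``Tstable`` is the first time step at whose *beginning* the relevant
consensus predicate holds — per-track heading uniformity ("local"
consensus) or a single heading across the whole swarm ("global" consensus,
the relevant notion once erratic track hopping makes every track mutually
reachable).  Replicate runs of one configuration aggregate into a sweep-
table row: mean/std/standard error of ``Tstable`` over the runs that
reached consensus, with timeouts counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

from .model import (
    ModelConfig,
    RunRecord,
    SwarmState,
    is_global_consensus,
    is_locally_stable,
)
from .structure import segment_counts

__all__ = [
    "StabilityStatus",
    "stability_status",
    "segment_count_summary",
    "aggregate_runs",
    "SWEEP_COLUMNS",
]

#: Fixed column order of a sweep-table row.
SWEEP_COLUMNS = [
    "experiment",
    "n",
    "k",
    "m",
    "density",
    "policy",
    "q",
    "p",
    "r",
    "stop_mode",
    "reps",
    "mean_tstable",
    "std_tstable",
    "se",
    "n_timeouts",
]


@dataclass(frozen=True)
class StabilityStatus:
    """Per-track and swarm-wide consensus flags at one instant."""

    track_uniform: tuple  # one flag per track; empty tracks are True
    local_stable: bool
    global_consensus: bool


def stability_status(state: SwarmState) -> StabilityStatus:
    """Evaluate the consensus predicates on one configuration."""
    flags = []
    for y in range(state.k):
        seen = 0
        uniform = True
        for i in state.track_occupants(y):
            b = state.bs[i]
            if seen == 0:
                seen = b
            elif seen != b:
                uniform = False
                break
        flags.append(uniform)
    return StabilityStatus(
        track_uniform=tuple(flags),
        local_stable=is_locally_stable(state),
        global_consensus=is_global_consensus(state),
    )


def segment_count_summary(state: SwarmState) -> tuple[list[int], int]:
    """Per-track segment counts and their maximum ``M_t``.

    ``M_t`` is non-increasing over a run without erratic vertical hops; a
    locally stable swarm has ``M_t <= 1``.
    """
    counts = segment_counts(state)
    return counts, max(counts) if counts else 0


def aggregate_runs(
    records: Sequence[RunRecord], experiment: str = ""
) -> dict:
    """Collapse replicate runs of one configuration into a sweep-table row.

    Mean and standard deviation (sample convention, ``ddof=1``) are computed
    over the runs that reached consensus; runs that timed out — or froze in
    a provably absorbing non-consensus state — are counted in
    ``n_timeouts`` and excluded from the moments.  With no reached runs the
    mean/std/se fields are ``None`` rather than raising.
    """
    if not records:
        raise ValueError("aggregate_runs needs at least one record")
    cfg = records[0].config
    if any(r.config != cfg for r in records):
        raise ValueError("all records must share one configuration")
    times = [r.tstable for r in records if r.reached]
    n_reached = len(times)
    mean = std = se = None
    if n_reached:
        mean = sum(times) / n_reached
        if n_reached > 1:
            var = sum((t - mean) ** 2 for t in times) / (n_reached - 1)
            std = sqrt(var)
        else:
            std = 0.0
        se = std / sqrt(n_reached)
    return {
        "experiment": experiment,
        "n": cfg.n,
        "k": cfg.k,
        "m": cfg.resolved_m,
        "density": cfg.density,
        "policy": cfg.policy,
        "q": cfg.q,
        "p": cfg.p,
        "r": cfg.r,
        "stop_mode": records[0].stop_mode,
        "reps": len(records),
        "mean_tstable": mean,
        "std_tstable": std,
        "se": se,
        "n_timeouts": len(records) - n_reached,
    }
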