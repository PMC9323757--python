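"""Structural decompositions of a track: segments, compact sets, potentials.

These are the analytical objects behind the stabilization proofs, exposed as
runtime diagnostics:

* a *segment* is a maximal run of consecutive same-heading locusts on one
  track, with a *tail* (rear locust, whose back has the opposite heading)
  and a *head* (front locust);
* a *compact set* is a platoon of same-heading consecutive locusts with at
  most one empty cell between each pair — impermeable to vertical entrants,
  because some member is always attempting to move into each internal gap;
* two opposite-heading compact sets whose facing ends sit on adjacent cells
  are *in deadlock*: the facing heads conflict every step until one set is
  absorbed into the other;
* the potential ``L = L1 + L2 + L3`` (sum of gaps between consecutive
  clockwise sets, between consecutive counterclockwise sets, and between the
  two facing innermost sets) strictly decreases while the two segments of a
  two-segment track approach each other, and equals 1 exactly when they are
  in deadlock; the companion potential ``F`` (internal empty cells plus
  locust count) bounds how many locusts can leave the track meanwhile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import SwarmState, front_locust

__all__ = [
    "Segment",
    "CompactSet",
    "PartitionSummary",
    "segments_of_track",
    "segment_counts",
    "maximal_compact_partition",
    "deadlock_pairs",
    "all_multi_segment_tracks_deadlocked",
    "potentials",
    "find_segment_by_tail",
]


@dataclass(frozen=True)
class Segment:
    """A maximal run of consecutive same-heading locusts on one track."""

    track: int
    members: tuple  # locust ids ordered tail -> head
    heading: int

    @property
    def tail_id(self) -> int:
        return self.members[0]

    @property
    def head_id(self) -> int:
        return self.members[-1]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CompactSet:
    """Same-heading locusts with gaps of at most one empty cell."""

    track: int
    members: tuple  # locust ids in compact-sequence order (tail -> head)
    heading: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PartitionSummary:
    """Maximal compact partition of an analysis interval, with potentials.

    ``C_sets`` are the clockwise maximal compact sets ordered by increasing
    position within the interval; ``W_sets`` the counterclockwise ones
    ordered by decreasing position.  ``L3`` (and hence ``L``) is ``None``
    for a one-sided interval, where the facing distance is undefined.
    """

    C_sets: list = field(default_factory=list)
    W_sets: list = field(default_factory=list)
    L1: int = 0
    L2: int = 0
    L3: Optional[int] = None
    F: int = 0

    @property
    def c_t(self) -> int:
        return len(self.C_sets)

    @property
    def w_t(self) -> int:
        return len(self.W_sets)

    @property
    def L(self) -> Optional[int]:
        if self.L3 is None:
            return None
        return self.L1 + self.L2 + self.L3


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------


def segments_of_track(state: SwarmState, y: int) -> list[Segment]:
    """Partition the locusts of track ``y`` into segments.

    Segment tails are the locusts whose back has the opposite heading;
    members are listed tail to head, following the front relation.  A
    heading-uniform track has no tail anchor, so by convention it forms one
    segment whose first member is the locust with smallest ``x``.  An empty
    track yields no segments.
    """
    occ = state.track_occupants(y)
    cnt = len(occ)
    if cnt == 0:
        return []
    headings = [state.bs[i] for i in occ]
    if all(b == headings[0] for b in headings):
        b = headings[0]
        # canonical order: start from the smallest-x locust, follow fronts
        members = [occ[0]]
        for _ in range(cnt - 1):
            members.append(front_locust(state, members[-1], "front"))
        return [Segment(track=y, members=tuple(members), heading=b)]
    segments = []
    for j in range(cnt):
        b = headings[j]
        # back of occ[j]: previous occupant against the heading direction
        back = headings[(j - 1) % cnt] if b == 1 else headings[(j + 1) % cnt]
        if back == b:
            continue  # not a tail
        members = [occ[j]]
        step_dir = 1 if b == 1 else -1
        pos = j
        while True:
            pos = (pos + step_dir) % cnt
            if headings[pos] != b:
                break
            members.append(occ[pos])
        segments.append(Segment(track=y, members=tuple(members), heading=b))
    return segments


def segment_counts(state: SwarmState) -> list[int]:
    """Number of segments on each track (0 for an empty track)."""
    return [len(segments_of_track(state, y)) for y in range(state.k)]


def find_segment_by_tail(state: SwarmState, tail_id: int) -> Optional[Segment]:
    """The segment whose tail is ``tail_id``, or None if it is not a tail.

    This is the persistent-identity convention for tracking a segment across
    steps: a segment whose tail flipped heading, changed tracks, or stopped
    being a tail (e.g. after a merge) has ended.
    """
    for seg in segments_of_track(state, state.ys[tail_id]):
        if seg.tail_id == tail_id:
            return seg
    return None


# ---------------------------------------------------------------------------
# Maximal compact partition
# ---------------------------------------------------------------------------


def _compact_runs(
    ids: Sequence[int], headings: Sequence[int], gaps: Sequence[int]
) -> list[tuple[list[int], int]]:
    """Group consecutive occupants into maximal compact runs.

    ``gaps[j]`` is the clockwise distance from occupant ``j`` to occupant
    ``j + 1``; a run breaks where the heading changes or the gap exceeds 2.
    Returns ``(member ids in +x order, heading)`` tuples.
    """
    runs = []
    cnt = len(ids)
    start = 0
    for j in range(cnt):
        last = j == cnt - 1
        if last or headings[j + 1] != headings[j] or gaps[j] > 2:
            runs.append((list(ids[start : j + 1]), headings[j]))
            start = j + 1
    return runs


def maximal_compact_partition(
    state: SwarmState, y: int, interval: Optional[tuple[int, int]] = None
) -> PartitionSummary:
    """Unique partition of a track (or arc) into maximal compact sets.

    ``interval = (x0, x1)`` restricts the analysis to the cells reached
    clockwise from ``x0`` to ``x1`` inclusive, with distances measured
    linearly inside the arc (the frame used to monitor a two-segment
    approach).  ``interval=None`` analyses the whole ring, where the
    partition may wrap: the scan is anchored at a break (a heading change or
    a gap larger than 2), and a uniform track whose gaps are all small is a
    single compact set.  Only the sets are filled in; use :func:`potentials`
    for the potential values.
    """
    n = state.n
    occ = state.track_occupants(y)
    summary = PartitionSummary()
    if interval is not None:
        x0, x1 = interval
        length = (x1 - x0) % n + 1
        sel = [
            (((state.xs[i] - x0) % n), i)
            for i in occ
            if (state.xs[i] - x0) % n < length
        ]
        sel.sort()
        positions = [p for p, _ in sel]
        ids = [i for _, i in sel]
        gaps = [positions[j + 1] - positions[j] for j in range(len(ids) - 1)]
    else:
        if not occ:
            return summary
        positions = [state.xs[i] for i in occ]
        ids = occ[:]
        cnt = len(ids)
        ring_gaps = [
            (positions[(j + 1) % cnt] - positions[j]) % n for j in range(cnt)
        ]
        headings_ring = [state.bs[i] for i in ids]
        # anchor the circular scan at a break, if one exists
        anchor = None
        for j in range(cnt):
            if ring_gaps[j] > 2 or headings_ring[(j + 1) % cnt] != headings_ring[j]:
                anchor = (j + 1) % cnt
                break
        if anchor is None:
            # whole ring is one compact loop of uniform heading
            b = headings_ring[0]
            members = ids if b == 1 else ids[::-1]
            cs = CompactSet(track=y, members=tuple(members), heading=b)
            (summary.C_sets if b == 1 else summary.W_sets).append(cs)
            return summary
        order = [(anchor + j) % cnt for j in range(cnt)]
        ids = [occ[j] for j in order]
        gaps = [ring_gaps[order[j]] for j in range(cnt - 1)]
    headings = [state.bs[i] for i in ids]
    for members, b in _compact_runs(ids, headings, gaps):
        if b == 1:
            summary.C_sets.append(
                CompactSet(track=y, members=tuple(members), heading=1)
            )
        else:
            # counterclockwise compact order runs against +x
            summary.W_sets.append(
                CompactSet(track=y, members=tuple(members[::-1]), heading=-1)
            )
    # W sets ordered by decreasing position (the set nearest the arc's
    # clockwise end first), mirroring the approach-frame indexing
    summary.W_sets.reverse()
    return summary


# ---------------------------------------------------------------------------
# Deadlock
# ---------------------------------------------------------------------------


def deadlock_pairs(state: SwarmState) -> list[tuple[CompactSet, CompactSet]]:
    """All (clockwise set, counterclockwise set) pairs in deadlock.

    Two maximal compact sets of opposite heading on the same track are in
    deadlock when their facing heads sit on adjacent cells — the clockwise
    head one step behind the counterclockwise head.
    """
    n = state.n
    pairs = []
    for y in range(state.k):
        summary = maximal_compact_partition(state, y)
        for C in summary.C_sets:
            cw_head_x = state.xs[C.members[-1]]
            for W in summary.W_sets:
                ccw_head_x = state.xs[W.members[-1]]
                if (cw_head_x + 1) % n == ccw_head_x:
                    pairs.append((C, W))
    return pairs


def all_multi_segment_tracks_deadlocked(state: SwarmState) -> bool:
    """True when every segment on every mixed-heading track is deadlocked.

    A segment counts as deadlocked when its locusts form one maximal compact
    set that belongs to a deadlock pair.  Heading-uniform (and empty) tracks
    are exempt: a lone segment has no partner to deadlock with.
    """
    locked = deadlock_pairs(state)
    locked_sets = {frozenset(C.members) for C, _ in locked}
    locked_sets |= {frozenset(W.members) for _, W in locked}
    for y in range(state.k):
        segs = segments_of_track(state, y)
        if len(segs) < 2:
            continue
        for seg in segs:
            if frozenset(seg.members) not in locked_sets:
                return False
    return True


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------


def _set_positions(state: SwarmState, cs: CompactSet, x0: int) -> list[int]:
    n = state.n
    return [(state.xs[i] - x0) % n for i in cs.members]


def potentials(
    state: SwarmState, y: int, interval: tuple[int, int]
) -> PartitionSummary:
    """Potential values of the maximal compact partition of an arc.

    ``L1`` sums the distances between consecutive clockwise sets, ``L2``
    between consecutive counterclockwise sets, and ``L3`` is the distance
    between the innermost facing sets (the last clockwise and the last
    counterclockwise set); distances between sets are minimal
    locust-to-locust cell distances within the interval frame.  ``L`` is
    their sum: it equals 1 exactly when the interval holds one clockwise and
    one counterclockwise compact set in deadlock.  ``F`` counts the empty
    cells between consecutive same-heading sets plus the locusts present —
    it is non-increasing and drops whenever a locust leaves the track.  With
    locusts of only one heading present, ``L3`` and ``L`` are ``None``.
    """
    summary = maximal_compact_partition(state, y, interval)
    x0 = interval[0]

    def dist(a: CompactSet, b: CompactSet) -> int:
        pa = _set_positions(state, a, x0)
        pb = _set_positions(state, b, x0)
        return min(abs(p - q) for p in pa for q in pb)

    C, W = summary.C_sets, summary.W_sets
    summary.L1 = sum(dist(C[i], C[i + 1]) for i in range(len(C) - 1))
    summary.L2 = sum(dist(W[i], W[i + 1]) for i in range(len(W) - 1))
    if C and W:
        summary.L3 = dist(C[-1], W[-1])
    locust_count = sum(len(cs) for cs in C) + sum(len(ws) for ws in W)
    summary.F = (
        sum(dist(C[i], C[i + 1]) - 1 for i in range(len(C) - 1))
        + sum(dist(W[i], W[i + 1]) - 1 for i in range(len(W) - 1))
        + locust_count
    )
    return summary
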