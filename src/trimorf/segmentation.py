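"""Sequence trisection, training-segment extraction and query sampling.

A residue at 1-based position ``j`` of a length-``n`` sequence is
*terminal* when ``j <= flank`` or ``j > n - flank`` (flank 20 by
default) and *middle* otherwise; sequences of length ``<= 2 * flank``
have no middle zone.  Training segments and per-residue query windows
both derive from this trisection: the terminal model is trained and
queried on terminal-zone material, the middle model on middle-zone
material.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import AnnotatedSequence, Polarity, QuerySample, Segment, Zone

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20


def zone_of(position: int, length: int, flank: int = DEFAULT_FLANK) -> Zone:
    """Zone of a 1-based residue position."""
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside 1..{length}")
    if position <= flank or position > length - flank:
        return Zone.TERMINAL
    return Zone.MIDDLE


def run_zones(start: int, end: int, length: int,
              flank: int = DEFAULT_FLANK) -> set[Zone]:
    """Zones touched by the 1-based inclusive interval [start, end]."""
    zones: set[Zone] = set()
    if start <= flank or end > length - flank:
        zones.add(Zone.TERMINAL)
    # the interval contains a middle residue iff it overlaps (flank, length-flank]
    if min(end, length - flank) >= max(start, flank + 1):
        zones.add(Zone.MIDDLE)
    return zones


def enumerate_query_samples(
    length: int, flank: int = DEFAULT_FLANK, seq_id: str = ""
) -> list[QuerySample]:
    """One truncated window per residue, in position order.

    Position ``j`` gets the window ``[max(1, j - flank),
    min(length, j + flank)]``; interior residues therefore get the full
    ``2 * flank + 1`` window and terminal residues a shorter one.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return [
        QuerySample(
            seq_id=seq_id,
            position=j,
            start=max(1, j - flank),
            end=min(length, j + flank),
            zone=zone_of(j, length, flank),
        )
        for j in range(1, length + 1)
    ]


def _feasible_negative_starts(
    seg_len: int, length: int, blocked: np.ndarray, zone: Zone, flank: int
) -> np.ndarray:
    """1-based start positions for a negative segment of ``seg_len``.

    A start is feasible when the segment fits in the sequence, shares
    no residue with any blocked (MoRF-plus-flank) position, and touches
    the requested zone.
    """
    if seg_len > length:
        return np.empty(0, dtype=int)
    free = ~blocked
    window_free = (
        np.convolve(free.astype(int), np.ones(seg_len, dtype=int), mode="valid")
        == seg_len
    )
    starts = np.flatnonzero(window_free) + 1
    if starts.size == 0:
        return starts
    ends = starts + seg_len - 1
    touches_terminal = (starts <= flank) | (ends > length - flank)
    touches_middle = np.minimum(ends, length - flank) >= np.maximum(starts, flank + 1)
    return starts[touches_terminal if zone is Zone.TERMINAL else touches_middle]


def extract_training_segments(
    seq: AnnotatedSequence,
    flank: int = DEFAULT_FLANK,
    rng: np.random.Generator | int | None = None,
) -> list[Segment]:
    """Balanced positive/negative training segments for one sequence.

    For each maximal MoRF run the positive segment is the run plus
    ``flank`` residues upstream and downstream, clipped to the sequence.
    A run whose residues touch both zones contributes its segment to
    both zones' training pools.  Each positive segment is paired with a
    negative segment of identical length and zone, drawn uniformly at
    random among placements disjoint from every run's flanked extent;
    when no placement exists the positive is kept alone and a warning
    is logged.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(seq)
    runs = seq.morf_runs()
    if not runs:
        return []

    blocked = np.zeros(n, dtype=bool)  # flanked extent of every run
    for start, end in runs:
        blocked[max(1, start - flank) - 1:min(n, end + flank)] = True

    segments: list[Segment] = []
    for start, end in runs:
        seg_start = max(1, start - flank)
        seg_end = min(n, end + flank)
        seg_len = seg_end - seg_start + 1
        for zone in sorted(run_zones(start, end, n, flank), key=lambda z: z.value,
                           reverse=True):  # terminal before middle, stable
            segments.append(Segment(seq.id, seg_start, seg_end,
                                    Polarity.POSITIVE, zone))
            starts = _feasible_negative_starts(seg_len, n, blocked, zone, flank)
            if starts.size == 0:
                logger.warning(
                    "no feasible negative placement for %s [%d, %d] (%s zone)",
                    seq.id, seg_start, seg_end, zone.value,
                )
                continue
            neg_start = int(rng.choice(starts))
            segments.append(Segment(seq.id, neg_start, neg_start + seg_len - 1,
                                    Polarity.NEGATIVE, zone))
    return segments
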