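"""Bout segmentation and fragmentation metrics.

A *bout* is a maximal contiguous run of one behavior. Fragmented care shows
up as more, shorter bouts of the same total duration, so the per-behavior
bout count and mean bout duration are the fragmentation measures.

Two same-behavior intervals separated by an unscored gap of at most
``merge_gap`` seconds are merged into one bout whose duration is the sum of
the scored time only (the gap is excluded). Gap-separated same-behavior
bouts that are *not* merged remain distinct bouts for fragmentation counts
but contribute no transition (see :mod:`behentropy.markov`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ParameterError
from .events import Session


@dataclass(frozen=True)
class Bout:
    behavior: str
    duration: int


@dataclass
class BoutSequence:
    """Run-length-encoded behavior sequence for one session."""

    session_id: str
    phase: str
    bouts: list[Bout] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)


def segment_bouts(session: Session, merge_gap: int = 0) -> BoutSequence:
    """Run-length encode a session's intervals into bouts.

    Contiguous intervals of the same behavior always merge (gap 0); a gap of
    ``1..merge_gap`` unscored seconds between same-behavior intervals also
    merges, with the gap time excluded from the bout duration.
    """
    if merge_gap < 0:
        raise ParameterError(f"merge_gap must be >= 0, got {merge_gap}")
    bouts: list[Bout] = []
    prev_end: int | None = None
    for iv in session.intervals:
        gap = None if prev_end is None else iv.start - prev_end
        if (
            bouts
            and bouts[-1].behavior == iv.behavior
            and gap is not None
            and gap <= merge_gap
        ):
            bouts[-1] = Bout(iv.behavior, bouts[-1].duration + iv.duration)
        else:
            bouts.append(Bout(iv.behavior, iv.duration))
        prev_end = iv.end
    return BoutSequence(session.session_id, session.phase, bouts)


@dataclass(frozen=True)
class FragmentationMetrics:
    """Per-behavior bout statistics pooled over the sessions in scope.

    ``bouts_per_observation`` equals ``n_bouts``: counts are reported per
    total observation period, not per session. ``mean_bout_duration`` is NaN
    when the behavior was never observed.
    """

    behavior: str
    n_bouts: int
    mean_bout_duration: float
    total_duration: int

    @property
    def bouts_per_observation(self) -> int:
        return self.n_bouts


def fragmentation_metrics(
    sequences: list[BoutSequence], behavior: str
) -> FragmentationMetrics:
    """Bout count, mean bout duration and total duration of one behavior."""
    durations = [
        b.duration for seq in sequences for b in seq.bouts if b.behavior == behavior
    ]
    n = len(durations)
    total = sum(durations)
    mean = total / n if n else math.nan
    return FragmentationMetrics(behavior, n, mean, total)


def total_scored_time(sequences: list[BoutSequence]) -> int:
    """Total scored seconds across all bouts (gap time excluded)."""
    return sum(b.duration for seq in sequences for b in seq.bouts)
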