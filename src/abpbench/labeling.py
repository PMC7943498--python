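"""Per-datapoint artifact labels derived from observed episode intervals.

Four label rules are supported:

* definition 1 — the stored minute had *any* overlap with an artifact
  episode;
* definition 2 — the minute had strictly more than 30 s of artifact;
* definition 3 — retrospective annotation of the stored data points
  (attached from the emulated annotator or a manual-annotation file);
* definition 4 — a 1/5 Hz sample falls inside an artifact episode.

Episodes are half-open ``[start, end)`` intervals on the monitor clock;
"any overlap" means strictly positive measure. When several causes touch
one minute, the cause covering the most seconds wins (majority vote),
ties broken by the earliest overlapping episode start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ArtifactEpisode

DEF2_THRESHOLD_S = 30.0


def _union_length(intervals: list[tuple[float, float]]) -> float:
    """Total measure of a union of half-open intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


@dataclass
class OverlapBreakdown:
    """Seconds of artifact overlap within one minute window, per cause."""

    seconds_by_cause: dict[str, float] = field(default_factory=dict)
    first_start_by_cause: dict[str, float] = field(default_factory=dict)
    total_overlap_s: float = 0.0


def overlap_breakdown(window: tuple[float, float],
                      episodes: list[ArtifactEpisode]) -> OverlapBreakdown:
    """Measure how much of ``window = [t0, t1)`` is covered by episodes.

    Per-cause seconds are the union of that cause's episode intersections
    with the window; the total is the union over *all* causes, so
    overlapping episodes are never double counted.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"window must satisfy t0 < t1, got [{t0}, {t1})")
    clipped_by_cause: dict[str, list[tuple[float, float]]] = {}
    first_start: dict[str, float] = {}
    all_clipped: list[tuple[float, float]] = []
    for ep in episodes:
        lo, hi = max(ep.start_s, t0), min(ep.end_s, t1)
        if hi > lo:
            clipped_by_cause.setdefault(ep.cause, []).append((lo, hi))
            all_clipped.append((lo, hi))
            if ep.cause not in first_start or ep.start_s < first_start[ep.cause]:
                first_start[ep.cause] = ep.start_s
    return OverlapBreakdown(
        seconds_by_cause={c: _union_length(v) for c, v in clipped_by_cause.items()},
        first_start_by_cause=first_start,
        total_overlap_s=_union_length(all_clipped),
    )


def label_def1_def2(b: OverlapBreakdown) -> tuple[bool, bool, str | None]:
    """Any-overlap (def 1) and >30 s (def 2) labels plus majority-vote cause.

    Definition 2 is strict: exactly 30 s of overlap does not qualify.
    """
    def1 = b.total_overlap_s > 0
    def2 = b.total_overlap_s > DEF2_THRESHOLD_S
    if not def1:
        return False, False, None
    best = max(
        b.seconds_by_cause,
        key=lambda c: (b.seconds_by_cause[c], -b.first_start_by_cause[c]),
    )
    return def1, def2, best


def label_minutes(minutes: pd.DataFrame,
                  episodes: list[ArtifactEpisode]) -> pd.DataFrame:
    """Label each stored minute under definitions 1 and 2.

    ``minutes`` must carry ``t_end_s``; episodes must already be on the
    monitor clock. Returns a copy with ``def1``, ``def2`` (bool) and
    ``cause`` (empty string when clean) columns appended.
    """
    def1s, def2s, causes = [], [], []
    for t_end in minutes["t_end_s"]:
        b = overlap_breakdown((t_end - 60.0, float(t_end)), episodes)
        d1, d2, c = label_def1_def2(b)
        def1s.append(d1)
        def2s.append(d2)
        causes.append(c or "")
    out = minutes.copy()
    out["def1"] = np.array(def1s, dtype=bool)
    out["def2"] = np.array(def2s, dtype=bool)
    out["cause"] = pd.Series(causes, index=out.index, dtype=object)
    return out


def label_def4(vitals: pd.DataFrame,
               episodes: list[ArtifactEpisode]) -> np.ndarray:
    """Flag 1/5 Hz samples falling inside any episode's ``[start, end)``."""
    t = vitals["t_s"].to_numpy(dtype=float)
    flagged = np.zeros(len(t), dtype=bool)
    for ep in episodes:
        flagged |= (t >= ep.start_s) & (t < ep.end_s)
    return flagged


def attach_retrospective(dataset: pd.DataFrame,
                         def3: np.ndarray | pd.Series) -> pd.DataFrame:
    """Attach retrospective annotations as the ``def3`` column."""
    def3 = np.asarray(def3, dtype=bool)
    if len(def3) != len(dataset):
        raise ValueError(
            f"def3 has {len(def3)} labels for {len(dataset)} minutes"
        )
    out = dataset.copy()
    out["def3"] = def3
    return out
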