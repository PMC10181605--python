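"""Sliding analysis grid, hands-off episodes and the sHOT metric.

The period of interest ``(-30 s, +10 s]`` is analysed by a classifier in
sliding windows shifted by 1 s. Decision times are aligned on the integer
grid [-15, ..., +10] (26 analyses) for every analysis duration D ∈ {5,
10, 15} s; the decision is taken at the last second of the window, so a
window with decision time t spans ``(t - D, t]``.

Hands-off time (HOT) is a chest-compression interruption strictly longer
than 1 s (insufflations, regular-analysis pauses). The sliding hands-off
time sHOT of a window is the cumulative overlap of qualifying
interruptions with the window span — the amount of artefact-free ECG the
classifier gets to see. An interruption qualifies on its full length;
its contribution is the clipped overlap, so sHOT ∈ [0, D].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    POI_POST_SECONDS,
    POI_PRE_SECONDS,
    CprShockError,
    EventTimeline,
    PeriodOfInterest,
)

__all__ = [
    "SUPPORTED_DURATIONS",
    "HOT_MIN_SECONDS",
    "DECISION_TIME_RANGE",
    "HOTEpisode",
    "AnalysisWindow",
    "decision_grid",
    "extract_window",
    "hot_episodes",
    "compute_shot",
    "analysis_windows",
]

SUPPORTED_DURATIONS = (5, 10, 15)
HOT_MIN_SECONDS = 1.0  #: interruptions must exceed this to count as HOT
DECISION_TIME_RANGE = (-15, 10)


@dataclass(frozen=True)
class HOTEpisode:
    """A chest-compression interruption exceeding 1 s, as ``[start, stop)``."""

    start: float
    stop: float

    @property
    def length(self) -> float:
        return self.stop - self.start


@dataclass(frozen=True)
class AnalysisWindow:
    """One sliding analysis: decision time ``t``, duration ``D``, and sHOT."""

    decision_time: int
    duration: int
    shot: float = 0.0
    fs: float = 125.0

    def __post_init__(self):
        if self.duration not in SUPPORTED_DURATIONS:
            raise CprShockError(
                f"analysis duration must be one of {SUPPORTED_DURATIONS}, "
                f"got {self.duration}"
            )
        if not (0.0 <= self.shot <= self.duration + 1e-9):
            raise CprShockError(f"sHOT {self.shot} outside [0, {self.duration}]")

    @property
    def span(self) -> tuple[float, float]:
        """Window extent ``(t - D, t]``."""
        return (self.decision_time - self.duration, self.decision_time)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def decision_grid(duration: int) -> list[int]:
    """The 26 integer decision times [-15, ..., +10], identical for all D.

    Decision times are aligned across durations so that windows of 5, 10
    and 15 s end at the same instants; the earliest 15 s window spans
    ``(-30, -15]``, exactly reaching the period start.
    """
    if duration not in SUPPORTED_DURATIONS:
        raise CprShockError(
            f"analysis duration must be one of {SUPPORTED_DURATIONS}, got {duration}"
        )
    return list(range(DECISION_TIME_RANGE[0], DECISION_TIME_RANGE[1] + 1))


def extract_window(poi: PeriodOfInterest, t: float, duration: int) -> np.ndarray:
    """ECG samples of the analysis window ``(t - D, t]``.

    Returns exactly ``D * fs`` samples, the last of which carries the
    timestamp ``t`` on the relative clock of the period.
    """
    if duration not in SUPPORTED_DURATIONS:
        raise CprShockError(
            f"analysis duration must be one of {SUPPORTED_DURATIONS}, got {duration}"
        )
    lo, hi = t - duration, t
    if lo < -POI_PRE_SECONDS - 1e-9 or hi > POI_POST_SECONDS + 1e-9:
        raise CprShockError(
            f"window ({lo}, {hi}] outside the period of interest (-30, 10]"
        )
    i0 = int(round((lo + POI_PRE_SECONDS) * poi.fs))
    i1 = int(round((hi + POI_PRE_SECONDS) * poi.fs))
    return poi.samples[i0:i1]


def hot_episodes(timeline: EventTimeline, region: tuple[float, float] | None = None,
                 ) -> list[HOTEpisode]:
    """Qualifying hands-off episodes intersecting ``region``.

    CC-free gaps are found over the timeline's full extent, clipped to
    that extent (no hands-off time is claimed outside recorded evidence),
    and qualify when their full length strictly exceeds 1 s. The
    qualifying episodes are then intersected with ``region`` — an episode
    straddling the region edge is returned clipped, even if the clipped
    part is ≤ 1 s.
    """
    if timeline.extent is None:
        raise CprShockError("timeline has no extent; cannot derive hands-off gaps")
    ext_lo, ext_hi = timeline.extent
    if region is None:
        region = (ext_lo, ext_hi)
    r_lo, r_hi = region
    if r_lo < ext_lo - 1e-9 or r_hi > ext_hi + 1e-9:
        raise CprShockError(
            f"region {region} outside timeline extent {timeline.extent}"
        )
    # maximal CC-free gaps over the full extent
    gaps = []
    cursor = ext_lo
    for s, e in timeline.cc_episodes:
        s, e = max(s, ext_lo), min(e, ext_hi)
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < ext_hi:
        gaps.append((cursor, ext_hi))
    out = []
    for s, e in gaps:
        if e - s <= HOT_MIN_SECONDS:  # "exceeding 1 s", strictly
            continue
        lo, hi = max(s, r_lo), min(e, r_hi)
        if hi > lo:
            out.append(HOTEpisode(lo, hi))
    return out


def compute_shot(timeline: EventTimeline, window: AnalysisWindow) -> float:
    """Cumulative hands-off seconds inside the window span ``(t - D, t]``.

    Sums the overlaps of qualifying interruptions with the window; the
    result lies in ``[0, D]`` and the contributing episodes need not be
    contiguous.
    """
    lo, hi = window.span
    episodes = hot_episodes(timeline, (lo, hi))
    total = sum(ep.length for ep in episodes)
    return float(min(total, window.duration))


def analysis_windows(poi: PeriodOfInterest, duration: int) -> list[AnalysisWindow]:
    """The 26 analysis windows of a period, each with its sHOT attached."""
    out = []
    for t in decision_grid(duration):
        w = AnalysisWindow(decision_time=t, duration=duration, fs=poi.fs)
        shot = compute_shot(poi.timeline, w)
        out.append(AnalysisWindow(decision_time=t, duration=duration,
                                  shot=shot, fs=poi.fs))
    return out
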