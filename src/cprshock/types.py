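"""Domain types shared across the pipeline.

Conventions
-----------
All times are seconds on a continuous clock. Intervals are half-open
``[start, stop)``. Sample ``i`` of a record starting at ``t0`` covers the
interval ``(t0 + i/fs, t0 + (i+1)/fs]``, i.e. its timestamp is the right
edge; a window ``(a, b]`` therefore maps to the slice
``[(a - t0) * fs : (b - t0) * fs]`` when the edges lie on the sample grid.
This keeps the 40 s period of interest ``(-30 s, +10 s]`` at exactly
``40 * fs`` samples with no off-by-one ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CprShockError",
    "MalformedTimelineError",
    "SamplingRateMismatchError",
    "LengthMismatchError",
    "RhythmLabel",
    "SignalRecord",
    "EventTimeline",
    "PeriodOfInterest",
    "POI_PRE_SECONDS",
    "POI_POST_SECONDS",
    "POI_DURATION",
]

POI_PRE_SECONDS = 30.0  #: anterior extent of the period of interest (s)
POI_POST_SECONDS = 10.0  #: posterior extent, the regular-analysis window (s)
POI_DURATION = POI_PRE_SECONDS + POI_POST_SECONDS


class CprShockError(ValueError):
    """Base class for schema and invariant violations."""


class MalformedTimelineError(CprShockError):
    """Event timeline violates its invariants (overlap, order, rate)."""


class SamplingRateMismatchError(CprShockError):
    """Sampling rate of a file or record disagrees with its metadata."""


class LengthMismatchError(CprShockError):
    """Channel or segment lengths disagree."""


class RhythmLabel(str, Enum):
    """AHA rhythm classes used for the shock advisory decision.

    VF (coarse ventricular fibrillation, amplitude > 200 µV) is the only
    shockable class; NSR, ONR and ASYS form the non-shockable category.
    """

    VF = "VF"
    NSR = "NSR"
    ONR = "ONR"
    ASYS = "ASYS"

    @property
    def category(self) -> str:
        """Shock advisory category: ``"Sh"`` for VF, ``"NSh"`` otherwise."""
        return "Sh" if self is RhythmLabel.VF else "NSh"

    @property
    def shockable(self) -> bool:
        return self is RhythmLabel.VF


def _as_interval(iv) -> tuple[float, float]:
    start, stop = float(iv[0]), float(iv[1])
    if not stop > start:
        raise MalformedTimelineError(f"empty or inverted interval [{start}, {stop})")
    return start, stop


@dataclass(frozen=True)
class SignalRecord:
    """A sampled defi-lead ECG record, optionally with thoracic impedance.

    Parameters
    ----------
    record_id : str
        Opaque identifier.
    fs : float
        Sampling rate in Hz (125 for this pipeline's defaults).
    ecg : ndarray
        ECG amplitude samples in µV.
    impedance : ndarray, optional
        Thoracic impedance in Ω on the same clock; illustrative only —
        the classifier never reads it.
    band : tuple of float
        Analog bandwidth (Hz) of the ECG channel.
    t0 : float
        Clock time (s) just before the first sample.
    """

    record_id: str
    ecg: np.ndarray
    fs: float = 125.0
    impedance: Optional[np.ndarray] = None
    band: tuple[float, float] = (1.0, 30.0)
    t0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise CprShockError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "ecg", np.asarray(self.ecg, dtype=float))
        if self.ecg.ndim != 1:
            raise CprShockError("ecg must be one-dimensional")
        if self.impedance is not None:
            imp = np.asarray(self.impedance, dtype=float)
            if imp.shape != self.ecg.shape:
                raise LengthMismatchError(
                    f"impedance length {imp.shape} != ecg length {self.ecg.shape}"
                )
            object.__setattr__(self, "impedance", imp)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self.ecg) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def slice_seconds(self, start: float, stop: float) -> np.ndarray:
        """ECG samples whose timestamps fall in the window ``(start, stop]``."""
        i0 = int(round((start - self.t0) * self.fs))
        i1 = int(round((stop - self.t0) * self.fs))
        if i0 < 0 or i1 > len(self.ecg) or i1 <= i0:
            raise CprShockError(
                f"window ({start}, {stop}] outside record "
                f"({self.t0}, {self.t_end}]"
            )
        return self.ecg[i0:i1]


@dataclass(frozen=True)
class EventTimeline:
    """Chest-compression episodes, analysis reference and rhythm segments.

    Attributes
    ----------
    cc_episodes : sequence of (start, stop)
        Half-open intervals (s) during which compressions are delivered;
        disjoint and sorted.
    aed_analysis_start : float
        Start (s) of the regular AED analysis; mapped to 0 on the relative
        clock of a period of interest.
    rhythm_segments : sequence of ((start, stop), RhythmLabel)
        Ground-truth rhythm over time.
    cc_rate : float
        Compression rate within an episode (min⁻¹); guideline range is
        100–120 min⁻¹.
    extent : (start, stop)
        Time span over which the timeline carries evidence. Hands-off
        episodes are clipped to this extent before qualification.
    """

    cc_episodes: tuple[tuple[float, float], ...]
    aed_analysis_start: float
    rhythm_segments: tuple[tuple[tuple[float, float], RhythmLabel], ...] = ()
    cc_rate: float = 110.0
    extent: Optional[tuple[float, float]] = None

    def __post_init__(self):
        eps = tuple(_as_interval(iv) for iv in self.cc_episodes)
        for (a0, a1), (b0, b1) in zip(eps, eps[1:]):
            if b0 < a1:
                raise MalformedTimelineError(
                    f"cc_episodes overlap or are unsorted: [{a0},{a1}) vs [{b0},{b1})"
                )
        t = float(self.aed_analysis_start)
        for s, e in eps:
            if s < t + POI_POST_SECONDS and e > t:
                raise MalformedTimelineError(
                    f"cc_episode [{s},{e}) intrudes into the regular-analysis "
                    f"window ({t}, {t + POI_POST_SECONDS}]"
                )
        if not (100.0 <= self.cc_rate <= 120.0):
            raise MalformedTimelineError(
                f"cc_rate {self.cc_rate} min^-1 outside the guideline range [100, 120]"
            )
        segs = tuple(((_as_interval(iv)), RhythmLabel(lab)) for iv, lab in self.rhythm_segments)
        object.__setattr__(self, "cc_episodes", eps)
        object.__setattr__(self, "aed_analysis_start", t)
        object.__setattr__(self, "rhythm_segments", segs)
        if self.extent is not None:
            object.__setattr__(self, "extent", _as_interval(self.extent))

    def shifted(self, offset: float) -> "EventTimeline":
        """Timeline translated by ``offset`` seconds (relative-clock views)."""
        return EventTimeline(
            cc_episodes=tuple((s + offset, e + offset) for s, e in self.cc_episodes),
            aed_analysis_start=self.aed_analysis_start + offset,
            rhythm_segments=tuple(
                ((s + offset, e + offset), lab) for (s, e), lab in self.rhythm_segments
            ),
            cc_rate=self.cc_rate,
            extent=None if self.extent is None else (
                self.extent[0] + offset, self.extent[1] + offset
            ),
        )

    def clipped(self, start: float, stop: float) -> "EventTimeline":
        """Timeline restricted to ``[start, stop)``; extent set accordingly."""
        def clip(iv):
            s, e = iv
            return (max(s, start), min(e, stop))

        eps = tuple(clip(iv) for iv in self.cc_episodes if iv[1] > start and iv[0] < stop)
        segs = tuple(
            (clip(iv), lab)
            for iv, lab in self.rhythm_segments
            if iv[1] > start and iv[0] < stop
        )
        return EventTimeline(
            cc_episodes=eps,
            aed_analysis_start=self.aed_analysis_start,
            rhythm_segments=segs,
            cc_rate=self.cc_rate,
            extent=(start, stop),
        )


@dataclass(frozen=True)
class PeriodOfInterest:
    """The 40 s segment ``(-30 s, +10 s]`` around a regular AED analysis.

    ``samples`` holds exactly ``40 * fs`` ECG samples on the relative
    clock where the regular analysis starts at 0; ``timeline`` is
    re-expressed on the same clock. ``label`` is the single ground-truth
    rhythm of the whole period (periods with a Sh/NSh transition are
    excluded upstream).
    """

    source: str
    samples: np.ndarray
    timeline: EventTimeline
    label: RhythmLabel
    fs: float = 125.0
    poi_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        expected = int(round(POI_DURATION * self.fs))
        if len(self.samples) != expected:
            raise LengthMismatchError(
                f"period of interest must hold {expected} samples at fs={self.fs}, "
                f"got {len(self.samples)}"
            )
        if abs(self.timeline.aed_analysis_start) > 1e-9:
            raise MalformedTimelineError(
                "period-of-interest timeline must be on the relative clock "
                "(aed_analysis_start == 0)"
            )
        if not self.poi_id:
            object.__setattr__(self, "poi_id", self.source)

    @property
    def n_samples(self) -> int:
        return len(self.samples)
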