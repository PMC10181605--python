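"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cprshock import EventTimeline, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 24-patient cohort reused by read-only tests."""
    return make_dataset(24, seed=42)


def make_timeline(episodes, extent, aed_start=None, cc_rate=110.0, segments=()):
    """Convenience constructor for hand-built timelines."""
    if aed_start is None:
        aed_start = extent[1] + 100.0  # analysis far outside the extent
    return EventTimeline(
        cc_episodes=tuple(episodes),
        aed_analysis_start=aed_start,
        rhythm_segments=tuple(segments),
        cc_rate=cc_rate,
        extent=extent,
    )


def shot_mask_oracle(timeline, span, duration, fs=125.0):
    """Per-sample brute-force sHOT: count CC-free samples that belong to
    hands-off runs whose full length exceeds 1 s, inside the window span.

    Works in integer sample units (all probe timelines are snapped to
    the sample grid), so boundary membership is exact. Sample index j of
    the extent covers ``(e0 + j, e0 + j + 1]`` grid units; a run of m
    free samples spans m/fs seconds and qualifies iff m/fs > 1.
    """
    toi = lambda x: int(round(x * fs))
    lo, hi = toi(span[0]), toi(span[1])
    e0, e1 = toi(timeline.extent[0]), toi(timeline.extent[1])
    n = e1 - e0
    cc = np.zeros(n, dtype=bool)
    for s, e in timeline.cc_episodes:
        s_i, e_i = max(toi(s), e0), min(toi(e), e1)
        if e_i > s_i:
            cc[s_i - e0 : e_i - e0] = True
    free = ~cc
    w_lo, w_hi = max(0, lo - e0), min(n, hi - e0)
    total_samples = 0
    i = 0
    while i < n:
        if not free[i]:
            i += 1
            continue
        j = i
        while j < n and free[j]:
            j += 1
        if (j - i) / fs > 1.0:  # full run length, strictly over 1 s
            total_samples += max(0, min(j, w_hi) - max(i, w_lo))
        i = j
    return min(total_samples / fs, duration)


def random_snapped_timeline(rng, fs=125.0, extent=(0.0, 40.0)):
    """Random alternating CC/gap timeline with edges on the sample grid."""
    def snap(x):
        return round(x * fs) / fs

    episodes = []
    t = extent[0] + rng.uniform(0.0, 3.0)
    while t < extent[1] - 1.0:
        dur = snap(rng.uniform(1.0, 12.0))
        start = snap(t)
        stop = min(snap(t + dur), extent[1])
        if stop > start:
            episodes.append((start, stop))
        t = stop + rng.uniform(0.2, 6.0)
    return make_timeline(episodes, extent=extent)
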