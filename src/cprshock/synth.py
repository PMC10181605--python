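"""Synthetic out-of-hospital cardiac-arrest (OHCA) interventions.

The proprietary defi-pad recordings this pipeline was designed around are
not redistributable, so this module emulates their statistical structure:
four rhythm classes with machine-checkable annotation criteria, additive
quasi-periodic chest-compression (CC) artefacts, a 30:2
compression-to-ventilation protocol with insufflation pauses, and a
CC-free regular-analysis window terminating every record. All amplitudes
are in µV, times in seconds, and every generator is deterministic under a
fixed seed.

Annotation criteria enforced on every generated trace
-----------------------------------------------------
VF    coarse ventricular fibrillation, peak-to-peak amplitude > 200 µV,
      no discernible QRS periodicity (drifting 3–8 Hz oscillator);
NSR   normal sinus rhythm, template P-QRS-T beats at 40–100 bpm;
ONR   other organised non-shockable rhythm (irregular-RR, wide-QRS
      bradycardia, or ectopic-beat morphologies);
ASYS  asystole, peak-to-peak deflection ≤ 100 µV over every 4 s
      sub-interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    POI_DURATION,
    POI_POST_SECONDS,
    POI_PRE_SECONDS,
    CprShockError,
    EventTimeline,
    PeriodOfInterest,
    RhythmLabel,
    SignalRecord,
)

__all__ = [
    "DEFAULT_CLASS_MIX",
    "Protocol",
    "Dataset",
    "bandlimit",
    "synth_rhythm",
    "synth_cc_artefact",
    "build_intervention",
    "extract_period_of_interest",
    "check_consistency",
    "make_dataset",
]

#: Real-life OHCA rhythm prevalence used as the default class mix.
DEFAULT_CLASS_MIX: Mapping[RhythmLabel, float] = {
    RhythmLabel.VF: 0.06,
    RhythmLabel.NSR: 0.03,
    RhythmLabel.ONR: 0.28,
    RhythmLabel.ASYS: 0.63,
}


def bandlimit(x: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 30.0)) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass to the defi-lead bandwidth."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _smooth_noise(rng, n, fs, cutoff_hz, sd=1.0):
    """Gaussian noise low-passed to ``cutoff_hz``, unit-variance-ish."""
    x = rng.standard_normal(n)
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y * (sd / s) if s > 0 else y


def _max_p2p_4s(x: np.ndarray, fs: float) -> float:
    """Largest peak-to-peak deflection over any 4 s sub-interval."""
    w = int(round(4 * fs))
    if len(x) <= w:
        return float(np.ptp(x))
    hop = max(1, int(round(0.25 * fs)))
    best = 0.0
    for i in range(0, len(x) - w + 1, hop):
        best = max(best, float(np.ptp(x[i : i + w])))
    best = max(best, float(np.ptp(x[len(x) - w :])))
    return best


def _gauss(t, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _beat_template(fs: float, width: float, r_amp: float, wide: bool,
                   with_p: bool = True) -> np.ndarray:
    """One P-QRS-T complex sampled at ``fs`` over ``width`` seconds."""
    t = np.arange(int(round(width * fs))) / fs
    c = 0.35 * width  # QRS centre
    qrs_sigma = 0.035 if wide else 0.012
    y = _gauss(t, c, qrs_sigma, r_amp)
    y += _gauss(t, c - 3.2 * qrs_sigma, qrs_sigma * 0.8, -0.18 * r_amp)  # Q
    y += _gauss(t, c + 3.2 * qrs_sigma, qrs_sigma * 0.8, -0.25 * r_amp)  # S
    if with_p:
        y += _gauss(t, c - 0.17, 0.025, 0.12 * r_amp)  # P
    y += _gauss(t, c + (0.30 if not wide else 0.36), 0.06, 0.28 * r_amp)  # T
    return y


def _place_beats(n, fs, beat_times, templates):
    y = np.zeros(n)
    for bt, tmpl in zip(beat_times, templates):
        i0 = int(round(bt * fs))
        i1 = min(n, i0 + len(tmpl))
        if i0 < n:
            y[i0:i1] += tmpl[: i1 - i0]
    return y


def _synth_vf(rng, n, fs):
    # Narrowband stochastic oscillator: complex-envelope noise carried at
    # a dominant frequency drifting in 3-8 Hz, ~1-2 Hz spectral width —
    # fibrillatory waves wax and wane with no repeating QRS pattern.
    f0 = rng.uniform(4.0, 6.5)
    freq = np.clip(f0 + _smooth_noise(rng, n, fs, 0.3, sd=0.9), 3.0, 8.0)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    bw = rng.uniform(0.5, 1.1)  # half-bandwidth of the complex envelope (Hz)
    env = ((0.5 + _smooth_noise(rng, n, fs, bw, sd=1.0))
           + 1j * _smooth_noise(rng, n, fs, bw, sd=1.0))
    y = np.real(env * np.exp(1j * phase))
    y = bandlimit(y, fs)
    target_p2p = rng.uniform(450.0, 1400.0)  # coarse VF, well above 200 µV
    return y * (target_p2p / np.ptp(y))


def _synth_nsr(rng, n, fs):
    rate = rng.uniform(50.0, 95.0)  # bpm, inside the 40-100 criterion
    rr = 60.0 / rate
    r_amp = rng.uniform(500.0, 1400.0)
    beats, t = [], rng.uniform(0, 0.3 * rr)
    dur = n / fs
    while t < dur:
        beats.append(t)
        t += rr * (1 + 0.02 * rng.standard_normal())
    tmpl = _beat_template(fs, min(0.75 * rr, 0.9), r_amp, wide=False)
    y = _place_beats(n, fs, beats, [tmpl] * len(beats))
    y += _smooth_noise(rng, n, fs, 25.0, sd=0.01 * r_amp)
    return bandlimit(y, fs)


def _synth_onr(rng, n, fs):
    morph = rng.choice(["irregular", "wide_brady", "ectopic"])
    dur = n / fs
    r_amp = rng.uniform(350.0, 1200.0)
    beats, templates = [], []
    if morph == "irregular":
        # atrial-fibrillation-like: no P wave, irregular RR
        rate = rng.uniform(60.0, 140.0)
        t = rng.uniform(0, 0.4)
        tmpl = _beat_template(fs, 0.55, r_amp, wide=False, with_p=False)
        while t < dur:
            beats.append(t)
            templates.append(tmpl)
            t += (60.0 / rate) * rng.uniform(0.6, 1.5)
    elif morph == "wide_brady":
        # idioventricular escape rhythm: wide QRS, < 40 bpm allowed
        rate = rng.uniform(25.0, 38.0)
        rr = 60.0 / rate
        t = rng.uniform(0, 0.5 * rr)
        tmpl = _beat_template(fs, 0.9, r_amp, wide=True, with_p=False)
        while t < dur:
            beats.append(t)
            templates.append(tmpl)
            t += rr * (1 + 0.04 * rng.standard_normal())
    else:
        # sinus beats with interspersed wide ectopic (PVC-like) beats
        rate = rng.uniform(55.0, 95.0)
        rr = 60.0 / rate
        t = rng.uniform(0, 0.3 * rr)
        narrow = _beat_template(fs, min(0.75 * rr, 0.9), r_amp, wide=False)
        wide = _beat_template(fs, 0.9, 1.2 * r_amp, wide=True, with_p=False)
        while t < dur:
            ect = rng.random() < 0.25
            beats.append(t)
            templates.append(wide if ect else narrow)
            t += rr * (0.8 if ect else 1.0) * (1 + 0.03 * rng.standard_normal())
    y = _place_beats(n, fs, beats, templates)
    y += _smooth_noise(rng, n, fs, 25.0, sd=0.012 * r_amp)
    return bandlimit(y, fs)


def _synth_asys(rng, n, fs):
    # low-amplitude wandering baseline; p2p <= 100 µV in every 4 s window
    y = _smooth_noise(rng, n, fs, 2.5, sd=1.0) + 0.4 * _smooth_noise(rng, n, fs, 12.0, sd=1.0)
    y = bandlimit(y, fs)
    target = rng.uniform(30.0, 85.0)
    m = _max_p2p_4s(y, fs)
    return y * (target / m) if m > 0 else y


_GENERATORS = {
    RhythmLabel.VF: _synth_vf,
    RhythmLabel.NSR: _synth_nsr,
    RhythmLabel.ONR: _synth_onr,
    RhythmLabel.ASYS: _synth_asys,
}


def synth_rhythm(label: RhythmLabel, duration: float, fs: float = 125.0,
                 seed=None) -> np.ndarray:
    """Generate a clean (artefact-free) rhythm trace of one class.

    Parameters
    ----------
    label : RhythmLabel
        Rhythm class; each class satisfies its annotation criterion
        (see module docstring).
    duration : float
        Trace duration in seconds, at least 5 s.
    fs : float
        Sampling rate in Hz.
    seed : int or Generator, optional
        Randomness source.

    Returns
    -------
    ndarray
        ECG amplitudes in µV, band-limited to 1–30 Hz.
    """
    label = RhythmLabel(label)
    if duration < 5:
        raise CprShockError(f"duration must be >= 5 s, got {duration}")
    if fs <= 0:
        raise CprShockError(f"fs must be positive, got {fs}")
    rng = _rng(seed)
    n = int(round(duration * fs))
    return _GENERATORS[label](rng, n, fs)


def synth_cc_artefact(timeline: EventTimeline, duration: float, fs: float = 125.0,
                      amplitude_scale: float = 1000.0, seed=None,
                      t0: float = 0.0) -> np.ndarray:
    """Quasi-periodic chest-compression artefact for a given timeline.

    The artefact is non-zero only inside ``cc_episodes``. Within an
    episode it is a harmonic series (2–4 harmonics) at the episode's
    compression rate with per-compression log-normal amplitude jitter and
    slow phase noise, tapered by a short cosine ramp at the episode
    edges. ``amplitude_scale`` sets the typical peak amplitude in µV.
    """
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = t0 + (np.arange(n) + 1) / fs  # sample timestamps (right edge)
    y = np.zeros(n)
    if amplitude_scale == 0:
        return y
    period = 60.0 / timeline.cc_rate
    n_harm = int(rng.integers(2, 5))
    coefs = np.array([1.0 / (h + 1) ** 1.2 for h in range(n_harm)])
    coefs[0] = 1.0  # fundamental dominates -> spectral peak at cc_rate
    psis = rng.uniform(0, 2 * np.pi, size=n_harm)
    for start, stop in timeline.cc_episodes:
        mask = (t > start) & (t <= stop)
        if not mask.any():
            continue
        tt = t[mask] - start
        phase_noise = _smooth_noise(rng, mask.sum(), fs, 0.5, sd=0.12)
        phase = 2 * np.pi * tt / period + phase_noise
        # per-compression amplitude jitter, indexed by compression number
        n_comp = int(np.ceil((stop - start) / period)) + 1
        amps = np.exp(rng.normal(0.0, 0.25, size=n_comp))
        comp_idx = np.clip((phase / (2 * np.pi)).astype(int), 0, n_comp - 1)
        wave = np.zeros(mask.sum())
        for h in range(n_harm):
            wave += coefs[h] * np.sin((h + 1) * phase + psis[h])
        raw = amps[comp_idx] * wave
        peak = np.abs(raw).max()
        if peak > 0:  # amplitude_scale is the episode's peak amplitude
            raw = raw / peak
        ramp = np.minimum(1.0, np.minimum(tt, (stop - start) - tt) / 0.15)
        ramp = np.clip(ramp, 0.0, 1.0)
        y[mask] = amplitude_scale * raw * ramp
    return y


@dataclass(frozen=True)
class Protocol:
    """CPR protocol parameters (default: 30:2 with 2–8 s insufflation pauses)."""

    cc_per_cycle: int = 30
    insufflation_pause: tuple[float, float] = (2.0, 8.0)
    cc_rate_range: tuple[float, float] = (100.0, 120.0)

    def __post_init__(self):
        lo, hi = self.insufflation_pause
        if not (0 < lo <= hi):
            raise CprShockError(
                f"insufflation pause range must be positive, got {self.insufflation_pause}"
            )
        if self.cc_per_cycle < 1:
            raise CprShockError("cc_per_cycle must be >= 1")


def _snap(x: float, fs: float) -> float:
    return round(x * fs) / fs


def build_intervention(protocol: Protocol | None = None, n_cycles: int = 2,
                       rhythm: RhythmLabel = RhythmLabel.ASYS, seed=None,
                       fs: float = 125.0, artefact_scale: Optional[float] = None,
                       record_id: str = "synthetic",
                       ) -> tuple[SignalRecord, EventTimeline]:
    """Simulate one CPR intervention ending in a regular AED analysis.

    The record holds ``n_cycles`` compression episodes (``cc_per_cycle``
    compressions each) separated by insufflation pauses, followed by a
    CC-free regular-analysis window of at least 10 s. The ECG is the
    clean rhythm trace plus the CC artefact, mixed additively; the
    impedance channel shows compression deflections and is flat during
    pauses.

    Returns
    -------
    (SignalRecord, EventTimeline)
        The record on the absolute clock starting at 0, and its timeline.
    """
    protocol = protocol or Protocol()
    if n_cycles < 1:
        raise CprShockError("n_cycles must be >= 1")
    rhythm = RhythmLabel(rhythm)
    rng = _rng(seed)
    cc_rate = rng.uniform(*protocol.cc_rate_range)
    period = 60.0 / cc_rate
    if artefact_scale is None:
        # spans strong, moderate and weak artefacts (0.2-3 mV peak)
        artefact_scale = float(np.exp(rng.uniform(np.log(200.0), np.log(3000.0))))

    t = _snap(rng.uniform(1.0, 3.0), fs)  # short CC-free lead-in
    episodes = []
    for _ in range(n_cycles):
        dur = _snap(protocol.cc_per_cycle * period, fs)
        episodes.append((t, t + dur))
        t = _snap(t + dur + rng.uniform(*protocol.insufflation_pause), fs)
    aed_start = _snap(episodes[-1][1] + rng.uniform(0.3, 1.2), fs)
    total = aed_start + POI_POST_SECONDS
    n = int(round(total * fs))

    timeline = EventTimeline(
        cc_episodes=tuple(episodes),
        aed_analysis_start=aed_start,
        rhythm_segments=(((0.0, total), rhythm),),
        cc_rate=cc_rate,
        extent=(0.0, total),
    )

    ecg = synth_rhythm(rhythm, total, fs, seed=rng)
    ecg = ecg + synth_cc_artefact(timeline, total, fs, amplitude_scale=artefact_scale,
                                  seed=rng)

    # impedance: constant baseline, ~1.5 Ohm compression deflections
    tvec = (np.arange(n) + 1) / fs
    imp = np.full(n, 60.0)
    for start, stop in episodes:
        mask = (tvec > start) & (tvec <= stop)
        imp[mask] += 1.5 * np.abs(np.sin(np.pi * (tvec[mask] - start) / period))

    rec = SignalRecord(record_id=record_id, ecg=ecg, fs=fs, impedance=imp, t0=0.0)
    return rec, timeline


def extract_period_of_interest(record: SignalRecord, timeline: EventTimeline,
                               poi_id: str = "") -> PeriodOfInterest:
    """Cut the 40 s period of interest ``(-30 s, +10 s]`` around the analysis.

    The record must cover 30 s before and 10 s after the regular-analysis
    start; the timeline is shifted so that the analysis starts at 0 and
    clipped to the period.
    """
    start = timeline.aed_analysis_start
    eps = 0.5 / record.fs
    if record.t0 > start - POI_PRE_SECONDS + eps:
        raise CprShockError(
            f"record starts at {record.t0} s; needs coverage from "
            f"{start - POI_PRE_SECONDS} s (30 s before analysis)"
        )
    if record.t_end < start + POI_POST_SECONDS - eps:
        raise CprShockError("record ends before the 10 s regular-analysis window")
    samples = record.slice_seconds(start - POI_PRE_SECONDS, start + POI_POST_SECONDS)
    rel = timeline.shifted(-start).clipped(-POI_PRE_SECONDS, POI_POST_SECONDS)
    label = _dominant_label(rel)
    return PeriodOfInterest(
        source=record.record_id, samples=samples, timeline=rel, label=label,
        fs=record.fs, poi_id=poi_id or record.record_id,
    )


def _dominant_label(timeline: EventTimeline) -> RhythmLabel:
    """Ground-truth label = rhythm during the regular-analysis window (0, 10]."""
    best, best_olap = None, 0.0
    for (s, e), lab in timeline.rhythm_segments:
        olap = max(0.0, min(e, POI_POST_SECONDS) - max(s, 0.0))
        if olap > best_olap:
            best, best_olap = lab, olap
    if best is None:
        raise CprShockError("timeline has no rhythm segment covering (0, 10]")
    return best


def check_consistency(poi: PeriodOfInterest, tol: float = 1e-6) -> bool:
    """True iff the Sh/NSh category is constant across the whole period.

    Transitions between distinct non-shockable classes remain consistent;
    a Sh→NSh (e.g. ROSC) or NSh→Sh (refibrillation) transition makes the
    period inconsistent. The rhythm segments must cover the full 40 s.
    """
    segs = sorted(poi.timeline.rhythm_segments, key=lambda s: s[0][0])
    if not segs:
        raise CprShockError("period has no rhythm segments")
    cursor = -POI_PRE_SECONDS
    for (s, e), _ in segs:
        if s > cursor + tol:
            raise CprShockError(
                f"gap in rhythm-segment coverage at {cursor:.3f}..{s:.3f} s"
            )
        cursor = max(cursor, e)
    if cursor < POI_POST_SECONDS - tol:
        raise CprShockError(f"rhythm segments end at {cursor:.3f} s, before +10 s")
    want = poi.label.category
    return all(lab.category == want for _, lab in segs)


@dataclass
class Dataset:
    """A generated cohort: periods of interest plus a patient-wise manifest.

    ``manifest`` columns: patient_id, poi_id, split ("learning"/"test"),
    label.
    """

    pois: dict[str, PeriodOfInterest]
    manifest: pd.DataFrame

    def split(self, name: str) -> list[PeriodOfInterest]:
        ids = self.manifest.loc[self.manifest["split"] == name, "poi_id"]
        return [self.pois[i] for i in ids]


def make_dataset(n_patients: int, class_mix: Optional[Mapping] = None,
                 seed=None, fs: float = 125.0, n_cycles: int = 2,
                 test_fraction: float = 0.5) -> Dataset:
    """Simulate a cohort of single-period interventions, split patient-wise.

    Each patient contributes one period of interest with a rhythm drawn
    from ``class_mix`` (default: the real-life OHCA prevalence of about
    6% VF, 3% NSR, 28% ONR and 63% ASYS). Patients are partitioned into
    two disjoint uniform parts for independent learning and testing; no
    patient contributes to both.
    """
    if n_patients < 2:
        raise CprShockError("need at least 2 patients to form two splits")
    mix = dict(class_mix) if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    mix = {RhythmLabel(k): float(v) for k, v in mix.items()}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise CprShockError(f"class mix must sum to 1, got {total}")
    rng = _rng(seed)
    labels_pool = list(mix.keys())
    probs = np.array([mix[k] for k in labels_pool])

    order = rng.permutation(n_patients)
    n_test = int(round(test_fraction * n_patients))
    test_set = set(order[:n_test].tolist())

    pois: dict[str, PeriodOfInterest] = {}
    rows = []
    for p in range(n_patients):
        label = labels_pool[rng.choice(len(labels_pool), p=probs)]
        pid = f"pt{p:05d}"
        poi_id = f"{pid}-poi0"
        rec, tl = build_intervention(n_cycles=n_cycles, rhythm=label, seed=rng,
                                     fs=fs, record_id=poi_id)
        poi = extract_period_of_interest(rec, tl, poi_id=poi_id)
        if not check_consistency(poi):
            raise CprShockError(f"generated period {poi_id} is inconsistent")
        pois[poi_id] = poi
        rows.append({
            "patient_id": pid,
            "poi_id": poi_id,
            "split": "test" if p in test_set else "learning",
            "label": label.value,
        })
    manifest = pd.DataFrame(rows)
    return Dataset(pois=pois, manifest=manifest)
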