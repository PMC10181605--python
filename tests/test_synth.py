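"""Generator compliance with the rhythm annotation criteria and CPR protocol."""

import numpy as np
import pytest
from scipy import signal as sps

from cprshock import (
    CprShockError,
    Protocol,
    RhythmLabel,
    build_intervention,
    check_consistency,
    extract_period_of_interest,
    make_dataset,
    synth_cc_artefact,
    synth_rhythm,
)
from cprshock.types import EventTimeline, PeriodOfInterest

from conftest import make_timeline

FS = 125.0


def max_p2p_4s(x, fs=FS):
    w = int(4 * fs)
    return max(float(np.ptp(x[i : i + w]))
               for i in range(0, len(x) - w + 1, int(fs // 4)))


def detected_rate_bpm(x, fs=FS, duration=40.0):
    peaks, _ = sps.find_peaks(x, height=0.5 * x.max(), distance=int(0.35 * fs))
    return len(peaks) / duration * 60.0


@pytest.mark.parametrize("seed", [1, 2, 3, 17, 99])
class TestRhythmCriteria:
    def test_asys_low_amplitude_everywhere(self, seed):
        x = synth_rhythm(RhythmLabel.ASYS, 40, FS, seed=seed)
        assert max_p2p_4s(x) <= 100.0

    def test_vf_coarse_amplitude(self, seed):
        x = synth_rhythm(RhythmLabel.VF, 40, FS, seed=seed)
        assert np.ptp(x) > 200.0

    def test_nsr_rate_within_criterion(self, seed):
        x = synth_rhythm(RhythmLabel.NSR, 40, FS, seed=seed)
        assert 40.0 <= detected_rate_bpm(x) <= 100.0

    def test_onr_is_organized_but_not_asystole(self, seed):
        x = synth_rhythm(RhythmLabel.ONR, 40, FS, seed=seed)
        assert np.ptp(x) > 100.0  # organized rhythms are not flat


def test_rhythms_are_bandlimited():
    for lab in RhythmLabel:
        x = synth_rhythm(lab, 40, FS, seed=5)
        f, pxx = sps.welch(x, fs=FS, nperseg=1024)
        inband = pxx[(f >= 0.5) & (f <= 31)].sum()
        outband = pxx[f > 35].sum()
        assert outband < 0.01 * inband


def test_rhythm_rejects_bad_inputs():
    with pytest.raises((ValueError, KeyError)):
        synth_rhythm("QRS", 40, FS, seed=0)
    with pytest.raises(CprShockError):
        synth_rhythm(RhythmLabel.VF, 2, FS, seed=0)
    with pytest.raises(CprShockError):
        synth_rhythm(RhythmLabel.VF, 40, -1, seed=0)


class TestCCArtefact:
    def test_no_episodes_gives_silence(self):
        tl = make_timeline([], extent=(0, 30))
        assert not synth_cc_artefact(tl, 30, FS, seed=0).any()

    def test_zero_gain_gives_silence(self):
        tl = make_timeline([(5, 25)], extent=(0, 30))
        assert not synth_cc_artefact(tl, 30, FS, amplitude_scale=0, seed=0).any()

    def test_zero_outside_episodes(self):
        tl = make_timeline([(5, 15), (20, 26)], extent=(0, 30))
        y = synth_cc_artefact(tl, 30, FS, seed=1)
        t = (np.arange(len(y)) + 1) / FS
        outside = ~(((t > 5) & (t <= 15)) | ((t > 20) & (t <= 26)))
        assert not y[outside].any()
        assert np.abs(y[~outside]).max() > 0

    @pytest.mark.parametrize("rate", [100.0, 110.0, 120.0])
    def test_dominant_frequency_at_compression_rate(self, rate):
        tl = make_timeline([(0.0, 60.0)], extent=(0, 60), cc_rate=rate)
        y = synth_cc_artefact(tl, 60, FS, seed=2)
        f, pxx = sps.welch(y, fs=FS, nperseg=4096)
        fpeak = f[np.argmax(pxx)]
        assert 100 / 60 - 0.25 <= fpeak <= 120 / 60 + 0.25


class TestIntervention:
    def test_thirty_compressions_per_episode(self):
        rec, tl = build_intervention(n_cycles=3, rhythm=RhythmLabel.ASYS, seed=4)
        period = 60.0 / tl.cc_rate
        for start, stop in tl.cc_episodes:
            assert (stop - start) / period == pytest.approx(30, abs=0.05)

    def test_analysis_window_is_compression_free(self):
        for seed in range(5):
            rec, tl = build_intervention(rhythm=RhythmLabel.ONR, seed=seed)
            a = tl.aed_analysis_start
            for s, e in tl.cc_episodes:
                assert e <= a or s >= a + 10

    def test_additive_mixing_zero_artefact(self):
        # same seed, same rhythm draw; artefact only differs inside episodes
        r0, tl0 = build_intervention(rhythm=RhythmLabel.ASYS, seed=7,
                                     artefact_scale=0.0)
        r1, tl1 = build_intervention(rhythm=RhythmLabel.ASYS, seed=7,
                                     artefact_scale=500.0)
        assert tl0.cc_episodes == tl1.cc_episodes
        t = (np.arange(len(r0.ecg)) + 1) / FS
        inside = np.zeros(len(t), dtype=bool)
        for s, e in tl0.cc_episodes:
            inside |= (t > s) & (t <= e)
        np.testing.assert_array_equal(r0.ecg[~inside], r1.ecg[~inside])
        assert not np.array_equal(r0.ecg[inside], r1.ecg[inside])
        # with zero artefact the record is the pure rhythm trace
        assert max(np.ptp(r0.ecg[i : i + int(4 * FS)])
                   for i in range(0, len(r0.ecg) - int(4 * FS), 100)) <= 100.0

    def test_impedance_flat_in_pauses(self):
        rec, tl = build_intervention(rhythm=RhythmLabel.ASYS, seed=3)
        t = (np.arange(len(rec.ecg)) + 1) / FS
        inside = np.zeros(len(t), dtype=bool)
        for s, e in tl.cc_episodes:
            inside |= (t > s) & (t <= e)
        assert np.ptp(rec.impedance[~inside]) < 1e-9
        assert np.ptp(rec.impedance[inside]) > 1.0

    def test_bad_protocol_rejected(self):
        with pytest.raises(CprShockError):
            Protocol(insufflation_pause=(0.0, 0.0))
        with pytest.raises(CprShockError):
            build_intervention(n_cycles=0, seed=0)


class TestPeriodOfInterest:
    def test_extraction_window_and_length(self):
        rec, tl = build_intervention(n_cycles=2, rhythm=RhythmLabel.VF, seed=9)
        poi = extract_period_of_interest(rec, tl)
        assert poi.n_samples == 5000
        a = tl.aed_analysis_start
        i0 = int(round((a - 30 - rec.t0) * FS))
        np.testing.assert_array_equal(poi.samples, rec.ecg[i0 : i0 + 5000])
        assert poi.timeline.aed_analysis_start == 0.0

    def test_insufficient_anterior_signal_rejected(self):
        tl = EventTimeline(cc_episodes=(), aed_analysis_start=20.0,
                           rhythm_segments=(((0.0, 30.0), RhythmLabel.ASYS),),
                           extent=(0.0, 30.0))
        from cprshock import SignalRecord
        rec = SignalRecord("r", np.zeros(int(30 * FS)), fs=FS)
        with pytest.raises(CprShockError):
            extract_period_of_interest(rec, tl)


class TestConsistency:
    def _poi(self, segments):
        tl = EventTimeline(cc_episodes=(), aed_analysis_start=0.0,
                           rhythm_segments=segments, extent=(-30.0, 10.0))
        label = segments[-1][1]
        return PeriodOfInterest(source="x", samples=np.zeros(5000),
                                timeline=tl, label=label)

    def test_single_class_consistent(self):
        poi = self._poi((((-30.0, 10.0), RhythmLabel.ASYS),))
        assert check_consistency(poi)

    def test_nsh_to_nsh_transition_consistent(self):
        poi = self._poi((((-30.0, -10.0), RhythmLabel.ONR),
                         ((-10.0, 10.0), RhythmLabel.ASYS)))
        assert check_consistency(poi)

    def test_refibrillation_inconsistent(self):
        poi = self._poi((((-30.0, -5.0), RhythmLabel.ASYS),
                         ((-5.0, 10.0), RhythmLabel.VF)))
        assert not check_consistency(poi)

    def test_gap_in_coverage_rejected(self):
        poi = self._poi((((-30.0, -10.0), RhythmLabel.ONR),
                         ((-5.0, 10.0), RhythmLabel.ASYS)))
        with pytest.raises(CprShockError):
            check_consistency(poi)


class TestMakeDataset:
    def test_deterministic_under_seed(self):
        d1 = make_dataset(12, seed=5)
        d2 = make_dataset(12, seed=5)
        assert d1.manifest.equals(d2.manifest)
        pid = d1.manifest.poi_id.iloc[0]
        np.testing.assert_array_equal(d1.pois[pid].samples, d2.pois[pid].samples)

    def test_splits_disjoint_patientwise(self, small_dataset):
        m = small_dataset.manifest
        learn = set(m.loc[m.split == "learning", "patient_id"])
        test = set(m.loc[m.split == "test", "patient_id"])
        assert learn and test and not learn & test

    def test_degenerate_mix_all_asystole(self):
        ds = make_dataset(6, class_mix={RhythmLabel.ASYS: 1.0}, seed=0)
        assert set(ds.manifest.label) == {"ASYS"}

    def test_class_mix_near_default(self):
        ds = make_dataset(150, seed=8)
        frac_asys = (ds.manifest.label == "ASYS").mean()
        assert 0.5 < frac_asys < 0.78  # 63% +/- sampling error

    def test_every_period_consistent(self, small_dataset):
        assert all(check_consistency(p) for p in small_dataset.pois.values())

    def test_invalid_inputs_rejected(self):
        with pytest.raises(CprShockError):
            make_dataset(1, seed=0)
        with pytest.raises(CprShockError):
            make_dataset(4, class_mix={RhythmLabel.VF: 0.4}, seed=0)
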