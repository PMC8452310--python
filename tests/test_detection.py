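"""Detector contracts: criterion boundaries, recall, equivariances."""

import numpy as np
import pytest

import slowswitch as sw
from slowswitch.data import AlignmentError
from slowswitch.synthetic import one_over_f_noise
from conftest import SR, flat_recording, nrem_hypnogram


def _detect_template(neg_amp, p2p, neg_dur, pos_dur, stage="N2"):
    """Inject one template on a flat channel and run the full detector."""
    rec = flat_recording(120.0)
    tau = (neg_dur + pos_dur) / 2.0
    sw.inject_slow_wave(rec.signal[0], 60.0, tau, p2p, SR,
                        neg_duration=neg_dur, pos_duration=pos_dur,
                        neg_fraction=abs(neg_amp) / p2p)
    hyp = nrem_hypnogram(rec.n_samples, stage=stage)
    delta = sw.bandpass_delta(rec.signal, SR)
    return sw.detect_slow_waves(delta, hyp, SR, rec.channel_labels)


class TestCriteria:
    def test_compliant_template_detected(self):
        waves = _detect_template(-50, 90, 0.4, 0.5)
        assert len(waves) == 1
        w = waves[0]
        assert w.neg_peak_amp < -40 and w.pos_peak_amp - w.neg_peak_amp > 75
        # peaks are read from the delta-filtered trace, which shifts the
        # asymmetric template's extrema by a few milliseconds
        assert w.tau == pytest.approx(0.45, abs=0.02)
        assert w.f_tau == pytest.approx(1 / (2 * w.tau))

    def test_shallow_negative_peak_rejected(self):
        assert _detect_template(-35, 90, 0.4, 0.5) == []

    def test_small_peak_to_peak_rejected(self):
        assert _detect_template(-45, 70, 0.4, 0.5) == []

    def test_short_negative_deflection_rejected(self):
        assert _detect_template(-50, 90, 0.1, 0.5) == []

    def test_long_negative_deflection_rejected(self):
        assert _detect_template(-50, 90, 1.7, 0.5) == []

    def test_long_positive_deflection_rejected(self):
        assert _detect_template(-50, 90, 0.4, 1.2) == []

    def test_wave_outside_nrem_rejected(self):
        assert _detect_template(-50, 90, 0.4, 0.5, stage="R") == []

    def test_returned_waves_satisfy_invariants(self, detected_small):
        for w in detected_small["waves"]:
            assert w.neg_peak_amp < -40
            assert w.pos_peak_amp - w.neg_peak_amp > 75
            assert 0.125 <= w.neg_duration <= 1.5
            assert w.pos_duration <= 1.0
            assert w.tau > 0
            assert w.f_tau == pytest.approx(1 / (2 * w.tau))
            assert w.frequency == pytest.approx(1 / w.T)
            assert w.cycle in (1, 2, 3)

    def test_unaligned_hypnogram_raises(self):
        rec = flat_recording(120.0)
        hyp = nrem_hypnogram(int(60 * SR))
        with pytest.raises(AlignmentError):
            sw.detect_slow_waves(rec.signal, hyp, SR, rec.channel_labels)


class TestRecallAndSpecificity:
    def test_recall_of_injected_waves(self, detected_small):
        """On the clean high-SNR fixture the detector recovers >= 90% of
        the injected waves on every channel."""
        truth, waves = detected_small["truth"], detected_small["waves"]
        for ch in detected_small["rec"].channel_labels:
            injected = [e for e in truth.slow_wave_events if e.channel == ch]
            negs = np.array([w.neg_peak_time for w in waves if w.channel == ch])
            hits = sum(np.any(np.abs(negs - e.neg_peak_time) < 0.25)
                       for e in injected)
            assert hits / len(injected) >= 0.9

    def test_no_detections_on_background_only(self):
        cfg = sw.SyntheticConfig(n_channels=2, n_cycles=1, cycle_minutes=5,
                                 sw_rate_cycle1=0.0, spindle_probability=0.0,
                                 seed=9)
        rec, hyp, _ = sw.generate_recording(cfg)
        delta = sw.bandpass_delta(rec.signal, SR)
        assert sw.detect_slow_waves(delta, hyp, SR, rec.channel_labels) == []

    def test_translation_equivariance(self):
        rec = flat_recording(180.0)
        for t0 in (50.0, 95.0):
            sw.inject_slow_wave(rec.signal[0], t0, 0.4, 100.0, SR)
        hyp = nrem_hypnogram(rec.n_samples)
        shift = int(12.5 * SR)
        shifted = np.roll(rec.signal, shift, axis=1)
        w0 = sw.detect_slow_waves(sw.bandpass_delta(rec.signal, SR), hyp, SR)
        w1 = sw.detect_slow_waves(sw.bandpass_delta(shifted, SR), hyp, SR)
        assert len(w0) == len(w1) == 2
        for a, b in zip(w0, w1):
            assert b.neg_peak_time - a.neg_peak_time == pytest.approx(
                shift / SR, abs=1e-6)
            assert b.tau == pytest.approx(a.tau, abs=1e-6)


class TestSpindles:
    @staticmethod
    def _noise_recording(duration=300.0, seed=5):
        rng = np.random.default_rng(seed)
        rec = flat_recording(duration)
        rec.signal[0] = one_over_f_noise(rec.n_samples, 1.0, 10.0, rng)
        return rec

    def test_injected_burst_detected_with_duration(self):
        rec = self._noise_recording()
        sw.inject_spindle(rec.signal[0], 100.0, 1.0, SR)
        hyp = nrem_hypnogram(rec.n_samples)
        sigma = sw.bandpass_sigma(rec.signal, SR)
        spindles = sw.detect_spindles(sigma, hyp, SR, rec.channel_labels)
        near = [s for s in spindles if abs(s.onset - 100.0) < 0.5]
        assert len(near) == 1
        assert near[0].duration == pytest.approx(1.0, abs=0.35)

    def test_too_short_burst_rejected(self):
        rec = self._noise_recording()
        sw.inject_spindle(rec.signal[0], 100.0, 0.25, SR, amplitude=12.0)
        hyp = nrem_hypnogram(rec.n_samples)
        sigma = sw.bandpass_sigma(rec.signal, SR)
        spindles = sw.detect_spindles(sigma, hyp, SR, rec.channel_labels)
        assert [s for s in spindles if abs(s.onset - 100.0) < 0.5] == []

    def test_too_long_burst_rejected(self):
        rec = self._noise_recording()
        sw.inject_spindle(rec.signal[0], 100.0, 3.8, SR)
        hyp = nrem_hypnogram(rec.n_samples)
        sigma = sw.bandpass_sigma(rec.signal, SR)
        spindles = sw.detect_spindles(sigma, hyp, SR, rec.channel_labels)
        assert [s for s in spindles if abs(s.onset - 100.0) < 1.0] == []

    def test_scale_covariance(self):
        """Multiplying the signal by a constant leaves detections unchanged
        (the percentile threshold scales with the signal)."""
        rec = self._noise_recording(seed=6)
        for t0 in (60.0, 150.0, 240.0):
            sw.inject_spindle(rec.signal[0], t0, 1.2, SR)
        hyp = nrem_hypnogram(rec.n_samples)
        s1 = sw.detect_spindles(sw.bandpass_sigma(rec.signal, SR), hyp, SR)
        s2 = sw.detect_spindles(sw.bandpass_sigma(rec.signal * 3.7, SR), hyp, SR)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            assert abs(a.onset - b.onset) <= 1 / SR
            assert abs(a.offset - b.offset) <= 1 / SR

    def test_empty_nrem_raises(self):
        rec = self._noise_recording(duration=60.0)
        hyp = nrem_hypnogram(rec.n_samples, stage="W")
        with pytest.raises(ValueError):
            sw.detect_spindles(sw.bandpass_sigma(rec.signal, SR), hyp, SR)


class TestCooccurrenceAndDensity:
    @staticmethod
    def _wave_with_phase_map():
        rec = flat_recording(120.0)
        sw.inject_slow_wave(rec.signal[0], 60.0, 0.4, 100.0, SR)
        hyp = nrem_hypnogram(rec.n_samples)
        phase_band = sw.bandpass_delta(rec.signal, SR, 0.16, 4.0)
        waves = sw.detect_slow_waves(sw.bandpass_delta(rec.signal, SR), hyp,
                                     SR, rec.channel_labels)
        sw.attach_phase_maps(phase_band, waves, SR, rec.channel_labels)
        assert len(waves) == 1 and waves[0].phase_ok
        return waves

    def _spindle_at_phase(self, wave, phi):
        t = float(wave.phase_map.time_at_phase(phi))
        return sw.Spindle(channel=wave.channel, onset=t, offset=t + 1.0,
                          peak_envelope=20.0)

    def test_onset_inside_interval_tags_wave(self):
        waves = self._wave_with_phase_map()
        spindle = self._spindle_at_phase(waves[0], -np.pi / 2)
        sw.tag_cooccurrence(waves, [spindle])
        assert waves[0].has_spindle

    def test_onset_outside_interval_does_not_tag(self):
        waves = self._wave_with_phase_map()
        spindle = self._spindle_at_phase(waves[0], -5 * np.pi / 4)
        sw.tag_cooccurrence(waves, [spindle])
        assert not waves[0].has_spindle

    def test_no_spindles_all_false(self):
        waves = self._wave_with_phase_map()
        sw.tag_cooccurrence(waves, [])
        assert not waves[0].has_spindle

    def test_missing_phase_map_raises(self):
        waves = self._wave_with_phase_map()
        waves[0].phase_map = None
        with pytest.raises(ValueError):
            sw.tag_cooccurrence(waves, [])

    def test_density_arithmetic(self):
        waves = self._wave_with_phase_map() * 120  # 120 identical waves
        hyp60 = nrem_hypnogram(int(60 * 60 * SR))   # 60 NREM minutes
        assert sw.slow_wave_density(waves, hyp60)["Fp1"] == pytest.approx(2.0)
        hyp120 = nrem_hypnogram(int(120 * 60 * SR))
        assert sw.slow_wave_density(waves, hyp120)["Fp1"] == pytest.approx(1.0)

    def test_density_requires_nrem_time(self):
        hyp = nrem_hypnogram(int(30 * SR), stage="W")
        with pytest.raises(ValueError):
            sw.slow_wave_density([], hyp)
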