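"""PLI contracts: sign-sum oracle, symmetrization, null, GCI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slowswitch as sw
from slowswitch.connectivity import (_directed_matrix, _symmetrize_matrix,
                                     null_threshold)
from conftest import SR, flat_recording, nrem_hypnogram


class TestEventPli:
    def test_zero_lag_gives_zero(self):
        phi = np.linspace(-3, 3, 40)
        assert sw.event_pli(phi, phi[None, :]) == pytest.approx(0.0)

    def test_constant_lag_gives_unity(self):
        phi = np.linspace(-3, 3, 40)
        assert sw.event_pli(phi, (phi - np.pi / 4)[None, :])[0] == 1.0
        assert sw.event_pli(phi, (phi + np.pi / 4)[None, :])[0] == -1.0

    def test_mixed_signs_average(self):
        phi = np.zeros(4)
        others = -np.array([[np.pi / 4, np.pi / 4, -np.pi / 4, -np.pi / 4]])
        assert sw.event_pli(phi, others)[0] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(2, 10), st.integers(1, 4))
    def test_brute_force_oracle_and_bounds(self, seed, n_events, n_other):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-np.pi, np.pi, n_events)
        others = rng.uniform(-np.pi, np.pi, (n_other, n_events))
        got = sw.event_pli(phi, others)
        for m in range(n_other):
            expected = sum(np.sign(np.sin(phi[k] - others[m, k]))
                           for k in range(n_events)) / n_events
            assert got[m] == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= got[m] <= 1.0

    @given(st.integers(0, 10_000), st.floats(-10, 10))
    @settings(deadline=None, max_examples=30)
    def test_common_phase_offset_invariance(self, seed, offset):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(-np.pi, np.pi, 20)
        others = rng.uniform(-np.pi, np.pi, (3, 20))
        a = sw.event_pli(phi, others)
        b = sw.event_pli(phi + offset, others + offset)
        assert np.allclose(a, b, atol=1e-9)

    def test_antisymmetry_under_channel_swap(self):
        rng = np.random.default_rng(0)
        phi_a = rng.uniform(-np.pi, np.pi, 30)
        phi_b = rng.uniform(-np.pi, np.pi, 30)
        ab = sw.event_pli(phi_a, phi_b[None, :])[0]
        ba = sw.event_pli(phi_b, phi_a[None, :])[0]
        assert ab == pytest.approx(-ba, abs=1e-12)


class TestSymmetrize:
    @pytest.mark.parametrize("a,b,expected", [(0.6, 0.4, 0.5), (1.0, 1.0, 1.0),
                                              (0.7, -0.7, 0.0)])
    def test_arithmetic_mean(self, a, b, expected):
        assert sw.symmetrize_pli(a, b) == pytest.approx(expected)

    def test_matrix_symmetrization_keeps_propagation(self):
        """A fixed lead of channel 0 appears with the same sign in both
        detection roles, so the symmetrized value stays at 1."""
        rng = np.random.default_rng(1)
        n, N = 3, 50
        angles = np.zeros((n, 4 * N))
        base = rng.uniform(-np.pi, np.pi, 4 * N)
        angles[0] = base + 0.3          # channel 0 leads by 0.3 rad
        angles[1] = base
        angles[2] = base
        ev = {c: np.arange(c * N, (c + 1) * N) for c in range(3)}
        D, avail = _directed_matrix(angles, ev)
        P = _symmetrize_matrix(D, avail)
        assert P[0, 1] == pytest.approx(1.0)
        assert abs(P[0, 1]) == abs(P[1, 0])
        assert P[1, 2] == pytest.approx(0.0)  # zero lag cancels
        assert np.allclose(np.diag(P), 0.0)

    def test_single_direction_fallback(self):
        rng = np.random.default_rng(2)
        angles = rng.uniform(-np.pi, np.pi, (3, 100))
        ev = {0: np.arange(50)}  # only channel 0 has enough events
        D, avail = _directed_matrix(angles, ev)
        P = _symmetrize_matrix(D, avail)
        assert P[0, 1] == pytest.approx(D[0, 1])
        assert P[1, 0] == pytest.approx(P[0, 1])


class TestPhasePoints:
    @staticmethod
    def _template_wave():
        rec = flat_recording(120.0)
        sw.inject_slow_wave(rec.signal[0], 60.0, 0.45, 100.0, SR)
        hyp = nrem_hypnogram(rec.n_samples)
        waves = sw.detect_slow_waves(sw.bandpass_delta(rec.signal, SR), hyp,
                                     SR, rec.channel_labels)
        phase_band = sw.bandpass_delta(rec.signal, SR, 0.16, 4.0)
        sw.attach_phase_maps(phase_band, waves, SR, rec.channel_labels)
        return waves[0]

    def test_exact_phase_constants(self):
        pts = sw.sample_phase_points(self._template_wave())
        assert list(pts) == ["a", "b", "c", "d", "e", "f"]
        expected = [-np.pi, -3 * np.pi / 4, -np.pi / 2, -np.pi / 4, 0.0,
                    np.pi / 4]
        assert [p for p, _t in pts.values()] == pytest.approx(expected)

    def test_times_monotone_and_zero_phase_at_pos_peak(self):
        w = self._template_wave()
        pts = sw.sample_phase_points(w)
        times = [t for _p, t in pts.values() if t is not None]
        assert np.all(np.diff(times) > 0)
        assert abs(pts["e"][1] - w.pos_peak_time) <= 1.0 / SR

    def test_transition_times_evenly_spaced_for_symmetric_wave(self):
        """For the near-sinusoidal template, phase is ~linear in time, so
        the five transition phases are ~evenly spaced in time too."""
        pts = sw.sample_phase_points(self._template_wave())
        times = np.array([pts[k][1] for k in "abcde"])
        gaps = np.diff(times)
        assert np.all(np.abs(gaps - gaps.mean()) < 0.25 * gaps.mean())

    def test_phase_out_of_span_returns_none(self):
        w = self._template_wave()
        w.phase_map.phases = np.clip(w.phase_map.phases, None, np.pi / 8)
        pts = sw.sample_phase_points(w)
        assert pts["f"][1] is None
        assert pts["e"][1] is not None


class TestNullAndGci:
    def test_threshold_requires_seed_and_bounds(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-np.pi, np.pi, (3, 200))
        ev = {0: np.arange(60)}
        with pytest.raises(ValueError):
            null_threshold(angles, ev, n_perm=100, seed=None)
        thr = null_threshold(angles, ev, n_perm=200, p=0.01, seed=1)
        assert 0 < thr <= 1.0

    def test_independent_phases_give_empty_mask(self):
        rng = np.random.default_rng(3)
        C, N = 4, 80
        angles = rng.uniform(-np.pi, np.pi, (C, C * N))
        ev = {c: np.arange(c * N, (c + 1) * N) for c in range(C)}
        D, avail = _directed_matrix(angles, ev)
        P = _symmetrize_matrix(D, avail)
        thr = null_threshold(angles, ev, n_perm=400, p=0.01, seed=7)
        mask = np.abs(P) > thr
        np.fill_diagonal(mask, False)
        assert sw.global_connectivity_index(P, mask) == (
            np.abs(P[np.triu_indices(C, 1)])[mask[np.triu_indices(C, 1)]].sum())
        assert mask.sum() <= 2  # at most one spurious pair at p = 0.01

    def test_planted_constant_lag_exceeds_threshold(self):
        rng = np.random.default_rng(4)
        C, N = 4, 200
        angles = rng.uniform(-np.pi, np.pi, (C, C * N))
        # channel 1 follows channel 0 with a fixed 0.3 rad delay plus jitter
        angles[1] = angles[0] - 0.3 + rng.normal(0, 0.1, angles.shape[1])
        ev = {c: np.arange(c * N, (c + 1) * N) for c in range(C)}
        D, avail = _directed_matrix(angles, ev)
        P = _symmetrize_matrix(D, avail)
        thr = null_threshold(angles, ev, n_perm=400, p=0.01, seed=8)
        assert abs(P[0, 1]) > thr

    def test_gci_arithmetic_and_monotonicity(self):
        P = np.zeros((4, 4))
        P[0, 1] = P[1, 0] = 0.5
        P[2, 3] = P[3, 2] = -0.3
        mask = np.zeros((4, 4), dtype=bool)
        assert sw.global_connectivity_index(P, mask) == 0.0
        mask[0, 1] = mask[1, 0] = True
        gci_one = sw.global_connectivity_index(P, mask)
        mask[2, 3] = mask[3, 2] = True
        gci_two = sw.global_connectivity_index(P, mask)
        assert gci_one == pytest.approx(0.5)
        assert gci_two == pytest.approx(0.8)
        assert gci_two >= gci_one


class TestEndToEndConnectivity:
    def test_planted_channel_lag_detected_on_synthetic_night(self, detected_small):
        """The generator's constant propagation lag makes every
        reference-channel pair significant; zero-lag pairs stay out."""
        d = detected_small
        res = sw.connectivity_analysis(d["phase_band"], d["waves"],
                                       SR, d["rec"].channel_labels,
                                       n_perm=300, seed=10)
        n_ch = len(d["rec"].channel_labels)
        ref = 0
        for lab in ("a", "c", "e"):
            mask = res.significant_mask[lab]
            assert mask[ref, 1:].sum() >= 4      # lagged pairs found
            off = mask.copy()
            off[ref, :] = off[:, ref] = False
            assert off.sum() <= 2                # zero-lag pairs rare
            assert res.gci[lab] > 0
            P = res.pli_symmetric[lab]
            assert np.allclose(P, P.T)
            assert np.abs(P).max() <= 1.0

    def test_min_events_drops_channel(self, detected_small):
        d = detected_small
        few = [w for w in d["waves"] if w.channel != "Fp1"
               or w.neg_peak_time < 120]
        res = sw.connectivity_analysis(d["phase_band"], few, SR,
                                       d["rec"].channel_labels,
                                       n_perm=120, min_events=20, seed=11)
        n_fp1 = res.n_events["Fp1"]
        if n_fp1 < 20:
            assert np.allclose(res.pli_directed["e"][0], 0.0)
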