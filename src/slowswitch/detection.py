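"""Slow-wave and spindle detection on artifact-free N2/N3 epochs.

Slow waves are segmented between successive negative-going zero crossings
of the delta-filtered trace.  A candidate wave is kept when it satisfies,
inclusively, the four amplitude/duration criteria: negative peak below
-40 uV, peak-to-peak amplitude above 75 uV, negative-deflection duration
between 125 and 1500 ms, positive-deflection duration at most 1000 ms.

Spindles are runs where the smoothed Hilbert envelope of the sigma-filtered
trace exceeds the channel-wise 75th percentile (computed over artifact-free
N2/N3 samples) for 0.5-3 s; sub-threshold gaps shorter than 100 ms are
merged before the duration filter.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert
from scipy.fft import next_fast_len

from .data import (CLUSTERS, EPOCH_SECONDS, Hypnogram, Recording, SlowWave,
                   Spindle)

logger = logging.getLogger(__name__)


def _interp_crossing(x: np.ndarray, i: int) -> float:
    """Sub-sample index of the zero crossing between samples i-1 and i."""
    a, b = x[i - 1], x[i]
    if a == b:
        return float(i)
    return (i - 1) + a / (a - b)


def _parabolic_peak(x: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample (index, value) refinement of an extremum at sample i."""
    if i <= 0 or i >= len(x) - 1:
        return float(i), float(x[i])
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom == 0:
        return float(i), float(x[i])
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    value = x[i] - 0.25 * (x[i - 1] - x[i + 1]) * delta
    return i + float(delta), float(value)


def detect_slow_waves(filtered: np.ndarray, hypnogram: Hypnogram, sr: float,
                      channel_labels: tuple[str, ...] | None = None,
                      neg_amp_max: float = -40.0, p2p_min: float = 75.0,
                      neg_dur_bounds: tuple[float, float] = (0.125, 1.5),
                      pos_dur_max: float = 1.0) -> list[SlowWave]:
    """Detect slow waves on the delta-filtered signal.

    Parameters
    ----------
    filtered : ndarray, (n_channels, n_samples) or (n_samples,)
        Output of :func:`slowswitch.filters.bandpass_delta`, uV.
    hypnogram : Hypnogram
        Aligned staging; only artifact-free N2/N3 epochs are searched.
    sr : float
        Sampling rate in Hz.
    channel_labels : tuple of str, optional
        Labels for the rows of `filtered` (defaults to ``ch0, ch1, ...``).

    Returns
    -------
    list of SlowWave
        Waves satisfying all four criteria, with sub-sample peak times
        (parabolic refinement) and the transition delay
        ``tau = pos_peak_time - neg_peak_time``.
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    n_samples = filtered.shape[1]
    hypnogram.check_alignment(n_samples, sr)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(filtered.shape[0]))
    eligible = hypnogram.eligible_epochs()
    spe = int(round(EPOCH_SECONDS * sr))
    waves: list[SlowWave] = []
    for ch, label in enumerate(channel_labels):
        x = filtered[ch]
        down = np.flatnonzero((x[:-1] >= 0) & (x[1:] < 0)) + 1
        up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0)) + 1
        for d0, d1 in zip(down[:-1], down[1:]):
            mids = up[(up > d0) & (up < d1)]
            if len(mids) == 0:
                continue
            u = mids[0]
            # whole wave must sit inside eligible epochs
            if not eligible[d0 // spe: (d1 - 1) // spe + 1].all():
                continue
            t0 = _interp_crossing(x, d0) / sr
            tu = _interp_crossing(x, u) / sr
            t1 = _interp_crossing(x, d1) / sr
            neg_dur = tu - t0
            pos_dur = t1 - tu
            if not (neg_dur_bounds[0] <= neg_dur <= neg_dur_bounds[1]):
                continue
            if pos_dur > pos_dur_max:
                continue
            i_neg = d0 + int(np.argmin(x[d0:u]))
            i_pos = u + int(np.argmax(x[u:d1]))
            neg_idx, neg_amp = _parabolic_peak(x, i_neg)
            pos_idx, pos_amp = _parabolic_peak(x, i_pos)
            if neg_amp >= neg_amp_max:
                continue
            if pos_amp - neg_amp <= p2p_min:
                continue
            tau = (pos_idx - neg_idx) / sr
            if tau <= 0:
                continue
            T = t1 - t0
            waves.append(SlowWave(
                channel=label, start_time=t0, end_time=t1,
                neg_peak_time=neg_idx / sr, pos_peak_time=pos_idx / sr,
                neg_peak_amp=neg_amp, pos_peak_amp=pos_amp,
                neg_duration=neg_dur, pos_duration=pos_dur,
                T=T, frequency=1.0 / T, tau=tau, f_tau=1.0 / (2.0 * tau),
                cycle=int(hypnogram.cycle_index[min(i_neg // spe,
                                                    hypnogram.n_epochs - 1)]),
            ))
    logger.info("detected %d slow waves on %d channels", len(waves),
                filtered.shape[0])
    return waves


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def detect_spindles(filtered_sigma: np.ndarray, hypnogram: Hypnogram, sr: float,
                    channel_labels: tuple[str, ...] | None = None,
                    percentile: float = 75.0, smooth_ms: float = 200.0,
                    dur_bounds: tuple[float, float] = (0.5, 3.0),
                    merge_gap_ms: float = 100.0) -> list[Spindle]:
    """Detect spindles via the smoothed Hilbert envelope of the sigma band.

    The envelope threshold is the per-channel `percentile` computed over
    artifact-free N2/N3 samples only; events are supra-threshold runs of
    0.5-3 s after merging gaps shorter than `merge_gap_ms`.
    """
    filtered_sigma = np.atleast_2d(np.asarray(filtered_sigma, dtype=float))
    n_samples = filtered_sigma.shape[1]
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(filtered_sigma.shape[0]))
    eligible = hypnogram.sample_mask(n_samples, sr)
    if not eligible.any():
        raise ValueError("no artifact-free N2/N3 samples to detect spindles in")
    nfft = next_fast_len(n_samples)
    smooth = max(1, int(round(smooth_ms / 1000.0 * sr)))
    merge = int(round(merge_gap_ms / 1000.0 * sr))
    spindles: list[Spindle] = []
    for ch, label in enumerate(channel_labels):
        env = np.abs(hilbert(filtered_sigma[ch], N=nfft)[:n_samples])
        env = uniform_filter1d(env, size=smooth)
        thr = np.percentile(env[eligible], percentile)
        above = (env > thr) & eligible
        runs = _runs_of(above)
        # merge events separated by short gaps
        merged: list[list[int]] = []
        for a, b in runs:
            if merged and a - merged[-1][1] < merge:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            dur = (b - a) / sr
            if dur_bounds[0] <= dur <= dur_bounds[1]:
                spindles.append(Spindle(channel=label, onset=a / sr,
                                        offset=b / sr,
                                        peak_envelope=float(env[a:b].max())))
    logger.info("detected %d spindles on %d channels", len(spindles),
                filtered_sigma.shape[0])
    return spindles


def tag_cooccurrence(waves: list[SlowWave], spindles: list[Spindle],
                     phase_interval: tuple[float, float] = (-np.pi, np.pi / 2),
                     skip_missing: bool = False) -> list[SlowWave]:
    """Flag waves whose phase map places a same-channel spindle onset in
    ``phase_interval`` (default [-pi, pi/2]).

    Requires phase maps (see :func:`slowswitch.transition.attach_phase_maps`);
    waves lacking one raise ``ValueError`` unless ``skip_missing`` is set
    (they then keep ``has_spindle = False``, as used by the pipeline for
    edge waves whose phase could not be computed).
    """
    by_channel: dict[str, list[float]] = {}
    for sp in spindles:
        by_channel.setdefault(sp.channel, []).append(sp.onset)
    onsets = {ch: np.sort(np.asarray(v)) for ch, v in by_channel.items()}
    lo, hi = phase_interval
    for w in waves:
        if w.phase_map is None:
            if skip_missing:
                w.has_spindle = False
                continue
            raise ValueError("phase map missing; run attach_phase_maps first")
        w.has_spindle = False
        t_on = onsets.get(w.channel)
        if t_on is None or len(t_on) == 0:
            continue
        sel = t_on[(t_on >= w.start_time) & (t_on <= w.end_time)]
        for t in sel:
            phase = w.phase_map.phase_at(t)
            if lo <= phase <= hi:
                w.has_spindle = True
                break
    return waves


def slow_wave_density(waves: list[SlowWave], hypnogram: Hypnogram) -> dict[str, float]:
    """Events per artifact-free NREM minute, per channel."""
    minutes = hypnogram.eligible_minutes()
    if minutes <= 0:
        raise ValueError("no artifact-free NREM time")
    counts: dict[str, int] = {}
    for w in waves:
        counts[w.channel] = counts.get(w.channel, 0) + 1
    return {ch: n / minutes for ch, n in counts.items()}


def cluster_density(waves: list[SlowWave], hypnogram: Hypnogram,
                    clusters: dict[str, tuple[str, ...]] = CLUSTERS
                    ) -> dict[str, float]:
    """Mean per-derivation density within each cluster of channels."""
    per_channel = slow_wave_density(waves, hypnogram)
    out = {}
    for name, channels in clusters.items():
        vals = [per_channel.get(ch, 0.0) for ch in channels]
        out[name] = float(np.mean(vals)) if vals else 0.0
    return out
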