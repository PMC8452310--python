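"""Per-wave internal phase and the transition-frequency statistic.

Each slow wave is mapped to an internal Hilbert phase spanning
[-3*pi/2, pi/2], anchored at 0 on the depolarization maximum (positive
peak) so that -pi falls on the hyperpolarization maximum (negative peak).
The transition delay ``tau`` is the time from the negative to the positive
peak and the transition frequency is ``f_tau = 1 / (2 tau)`` - the
frequency of the oscillation whose half period equals the depolarization
transition.

Phase is computed from the analytic signal of the delta-filtered trace;
the characteristics band defaults to 0.16-4 Hz (wider at the low end than
the 0.3-4 Hz detection band so that long waves keep a monotone phase).
The Hilbert transform is evaluated on a window extending one wave length
beyond the wave on each side and then cropped, suppressing edge
transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .data import SlowWave

logger = logging.getLogger(__name__)

PHASE_RANGE = (-1.5 * np.pi, 0.5 * np.pi)
_RANGE_TOL = 0.35       # rad of tolerated overshoot before a wave is flagged
_MONOTONE_TOL = 0.2     # rad of tolerated backward phase step


class PhaseMapError(ValueError):
    """Wave too close to the signal edge for a clean analytic phase."""


@dataclass
class PhaseMap:
    """Monotone time->phase map of one slow wave.

    ``phases`` is the unwrapped analytic phase over the wave samples,
    offset so the phase is exactly 0 at ``zero_time`` (the depolarization
    maximum) and clipped to [-3*pi/2, pi/2].  ``monotone`` is False when the
    unwrapped phase regressed or overshot the admissible range beyond
    tolerance; such waves are excluded from connectivity.
    """

    times: np.ndarray
    phases: np.ndarray
    zero_time: float
    monotone: bool = True

    def phase_at(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, self.phases)

    def time_at_phase(self, phi: float | np.ndarray) -> float | np.ndarray:
        """Invert the map (requires a non-decreasing phase course)."""
        return np.interp(phi, self.phases, self.times)

    @property
    def covers(self) -> tuple[float, float]:
        return float(self.phases[0]), float(self.phases[-1])


def compute_phase_map(filtered: np.ndarray, wave: SlowWave, sr: float) -> PhaseMap:
    """Hilbert phase of the band-limited signal over one wave.

    Parameters
    ----------
    filtered : 1-D ndarray
        The wave's channel filtered in the characteristics band
        (0.16-4 Hz by default upstream).
    wave : SlowWave
        Wave with peak and boundary times on this channel.
    sr : float
        Sampling rate in Hz.

    Raises
    ------
    PhaseMapError
        When the padding window (one wave length each side) does not fit
        inside the signal.
    """
    i0 = int(round(wave.start_time * sr))
    i1 = int(round(wave.end_time * sr))
    if i1 <= i0:
        raise PhaseMapError("degenerate wave interval")
    pad = i1 - i0
    a, b = i0 - pad, i1 + pad
    if a < 0 or b > len(filtered):
        raise PhaseMapError("wave too close to the signal edge")
    seg = filtered[a:b]
    analytic = hilbert(seg, N=next_fast_len(len(seg)))[: len(seg)]
    phase = np.unwrap(np.angle(analytic))[i0 - a: i1 - a + 1]
    times = np.arange(i0, i1 + 1) / sr
    # anchor: zero phase at the depolarization maximum
    phase = phase - np.interp(wave.pos_peak_time, times, phase)
    monotone = not np.any(np.diff(phase) < -_MONOTONE_TOL)
    lo, hi = PHASE_RANGE
    if phase[0] < lo - _RANGE_TOL or phase[-1] > hi + _RANGE_TOL:
        monotone = False
    phase = np.clip(phase, lo, hi)
    return PhaseMap(times=times, phases=phase, zero_time=wave.pos_peak_time,
                    monotone=monotone)


def attach_phase_maps(filtered: np.ndarray, waves: list[SlowWave], sr: float,
                      channel_labels: tuple[str, ...] | None = None
                      ) -> list[SlowWave]:
    """Compute and attach a phase map to every wave; flag unusable ones.

    `filtered` is the full (n_channels, n_samples) array in the
    characteristics band.  Waves at the signal edge or with a non-monotone
    phase keep ``phase_ok = False`` and are counted in the log.
    """
    filtered = np.atleast_2d(filtered)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(filtered.shape[0]))
    index = {lab: i for i, lab in enumerate(channel_labels)}
    n_bad = 0
    for w in waves:
        try:
            pm = compute_phase_map(filtered[index[w.channel]], w, sr)
        except PhaseMapError:
            w.phase_map = None
            w.phase_ok = False
            n_bad += 1
            continue
        w.phase_map = pm
        w.phase_ok = pm.monotone
        if not pm.monotone:
            n_bad += 1
    if n_bad:
        logger.info("flagged %d/%d waves with unusable phase maps", n_bad,
                    len(waves))
    return waves


def transition_delay(wave: SlowWave) -> float:
    """Delay tau from the maximum negative to the maximum positive point."""
    tau = wave.pos_peak_time - wave.neg_peak_time
    if tau <= 0:
        raise ValueError("positive peak precedes negative peak: "
                         "inconsistent detection")
    return tau


def transition_frequency(tau: float) -> float:
    """Transition frequency f_tau = 1 / (2 tau) in Hz."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 1.0 / (2.0 * tau)


def wave_frequency(wave: SlowWave) -> float:
    """Wave frequency as the inverse of the total duration T."""
    if wave.T <= 0:
        raise ValueError("total duration must be positive")
    return 1.0 / wave.T
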