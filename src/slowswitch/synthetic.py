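"""Synthetic polysomnography with ground-truth slow waves and spindles.

The generator emulates the statistical structure the downstream analysis
assumes: 1/f background EEG on a 10-20 montage, embedded biphasic slow
waves whose negative-to-positive transition delay tau is drawn from a
two-mode (slow/fast switcher) distribution, optional spindles
phase-coupled to the waves, a constant inter-channel propagation lag that
creates detectable phase-locked connectivity, and per-cycle event rates
decaying exponentially across sleep cycles.

Waveform template
-----------------
A slow wave is a half-sine negative lobe followed by a half-sine positive
lobe.  Peaks sit at the lobe centers, so with lobe durations ``d_neg`` and
``d_pos`` the transition delay is ``tau = (d_neg + d_pos) / 2``; by default
both lobes last ``tau`` so amplitude, tau and lobe durations can be set
independently of one another.

Seeding
-------
One master integer seed; ``numpy.random.SeedSequence(seed).spawn(2)``
yields child 0 for the event plan (counts, times, tau, classes, spindles)
and child 1 for the background noise.  Identical configs therefore give
bit-identical recordings, and the event plan can be re-drawn without
synthesizing the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .data import (CHANNELS_1020, EPOCH_SECONDS, Hypnogram, Recording)


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


# tau draws are truncated so every injected wave respects the detector's
# duration criteria (neg lobe >= 125 ms, pos lobe <= 1000 ms) with margin.
_TAU_BOUNDS = (0.15, 0.95)
_MIN_EVENT_GAP = 3.0        # s between wave midpoints, avoids overlap
_SPINDLE_FREQ = 13.0        # Hz carrier of injected spindles
_SPINDLE_AMP = 25.0         # uV peak of the Hann-windowed burst
_SPINDLE_DUR = (0.5, 1.5)   # s, uniform
_SPINDLE_PHASE = -np.pi / 4  # slow-wave phase at spindle onset


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic polysomnography generator.

    The tau modes default to transition frequencies of ~0.9 Hz (slow
    switchers) and ~1.8 Hz (fast switchers), i.e. on either side of the
    ~1.2 Hz boundary where the two populations cross; the decay rates
    default to the values reported for young adults (fast switchers
    dissipating more steeply than slow ones).
    """

    n_channels: int = 19
    sampling_rate: float = 256.0
    n_cycles: int = 3
    cycle_minutes: float = 20.0
    sw_rate_cycle1: float = 3.0          # events/min per switcher class in cycle 1
    decay_rate_slow: float = 1.3         # per-cycle exponential rate, slow switchers
    decay_rate_fast: float = 1.6         # per-cycle exponential rate, fast switchers
    tau_mode_slow: float = 0.556         # s  -> f_tau ~ 0.9 Hz
    tau_mode_fast: float = 0.278         # s  -> f_tau ~ 1.8 Hz
    tau_sd_slow: float = 0.12            # s  -> ~0.2 Hz spread in f_tau
    tau_sd_fast: float = 0.05            # s  -> ~0.32 Hz spread in f_tau
    sw_amplitude: float = 120.0          # uV peak-to-peak
    spindle_probability: float = 0.5
    channel_lag: float = 0.03            # s propagation lag of non-reference channels
    noise_exponent: float = 1.0          # 1/f^a slope of the background
    noise_rms: float = 10.0              # uV RMS of the background
    reference_channel: int = 0           # channel carrying the un-lagged events
    rem_fraction: float = 0.2            # tail fraction of each cycle scored R
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_channels <= len(CHANNELS_1020)):
            raise ConfigurationError(f"n_channels must be in [1, {len(CHANNELS_1020)}]")
        if self.sampling_rate < 128:
            raise ConfigurationError("sampling_rate must be >= 128 Hz")
        if self.n_cycles < 1 or self.cycle_minutes <= 0:
            raise ConfigurationError("need n_cycles >= 1 and positive cycle_minutes")
        for name in ("sw_rate_cycle1", "decay_rate_slow", "decay_rate_fast",
                     "spindle_probability", "noise_rms", "sw_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.tau_mode_slow <= 0 or self.tau_mode_fast <= 0:
            raise ConfigurationError("tau modes must be positive")
        if self.tau_mode_fast >= self.tau_mode_slow:
            raise ConfigurationError("fast switchers must have the shorter tau mode")
        if not 0 <= self.spindle_probability <= 1:
            raise ConfigurationError("spindle_probability must be in [0, 1]")
        if not 0 <= self.reference_channel < self.n_channels:
            raise ConfigurationError("reference_channel out of range")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return CHANNELS_1020[: self.n_channels]

    @property
    def n_samples(self) -> int:
        return int(round(self.n_cycles * self.cycle_minutes * 60.0 * self.sampling_rate))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SlowWaveEvent:
    """Ground truth for one injected slow wave on one channel."""

    channel: str
    neg_peak_time: float
    pos_peak_time: float
    tau: float
    switcher: str            # "slow" | "fast"
    cycle: int
    t_center: float          # negative-to-positive zero crossing


@dataclass
class SpindleEvent:
    channel: str
    onset: float
    offset: float


@dataclass
class GroundTruth:
    """Injected events and the cycle structure they were drawn from."""

    slow_wave_events: list[SlowWaveEvent] = field(default_factory=list)
    spindle_events: list[SpindleEvent] = field(default_factory=list)
    cycle_boundaries: list[int] = field(default_factory=list)  # first epoch of each cycle

    def events_on(self, channel: str) -> list[SlowWaveEvent]:
        return [e for e in self.slow_wave_events if e.channel == channel]


def build_hypnogram(config: SyntheticConfig) -> Hypnogram:
    """Deterministic block hypnogram: N2 then N3, one REM block per cycle."""
    epc = int(round(config.cycle_minutes * 2))  # 30-s epochs per cycle
    if epc < 2:
        raise ConfigurationError("cycle_minutes too short for a cycle structure")
    n_rem = max(1, int(round(config.rem_fraction * epc)))
    n_nrem = epc - n_rem
    stages: list[str] = []
    cycles: list[int] = []
    for c in range(1, config.n_cycles + 1):
        block = ["N2"] * (n_nrem // 2) + ["N3"] * (n_nrem - n_nrem // 2) + ["R"] * n_rem
        stages.extend(block)
        cycles.extend([c] * epc)
    n = len(stages)
    return Hypnogram(np.array(stages, dtype=object), np.array(cycles),
                     np.zeros(n, dtype=bool))


def _eligible_runs(hypnogram: Hypnogram, cycle: int) -> list[tuple[float, float]]:
    """Contiguous artifact-free N2/N3 spans of one cycle, in seconds."""
    ok = hypnogram.eligible_epochs() & (hypnogram.cycle_index == cycle)
    runs: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start * EPOCH_SECONDS, i * EPOCH_SECONDS))
            start = None
    if start is not None:
        runs.append((start * EPOCH_SECONDS, len(ok) * EPOCH_SECONDS))
    return runs


def _draw_tau(rng: np.random.Generator, mode: float, sd: float) -> float:
    for _ in range(1000):
        tau = rng.normal(mode, sd)
        if _TAU_BOUNDS[0] <= tau <= _TAU_BOUNDS[1]:
            return float(tau)
    raise ConfigurationError("tau distribution incompatible with detector bounds")


def plan_events(config: SyntheticConfig,
                hypnogram: Optional[Hypnogram] = None,
                rng: Optional[np.random.Generator] = None) -> GroundTruth:
    """Draw the ground-truth event plan without synthesizing any signal.

    Per cycle ``c`` (1-based) and switcher class, the number of injected
    waves is Poisson with mean ``sw_rate_cycle1 * exp(-r_class * (c - 1))``
    events per artifact-free NREM minute, so expected counts decay
    exponentially across cycles with the class-specific rate.
    """
    if hypnogram is None:
        hypnogram = build_hypnogram(config)
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(config.seed).spawn(2)[0]))
    truth = GroundTruth()
    epc = int(round(config.cycle_minutes * 2))
    truth.cycle_boundaries = [c * epc for c in range(config.n_cycles)]
    labels = config.channel_labels
    lags = [0.0 if i == config.reference_channel else config.channel_lag
            for i in range(config.n_channels)]
    placed: list[float] = []  # accepted t_center values, all cycles

    for cycle in range(1, config.n_cycles + 1):
        runs = _eligible_runs(hypnogram, cycle)
        nrem_min = sum(b - a for a, b in runs) / 60.0
        if nrem_min <= 0:
            continue
        lengths = np.array([b - a for a, b in runs])
        for klass, rate in (("slow", config.decay_rate_slow),
                            ("fast", config.decay_rate_fast)):
            mean_rate = config.sw_rate_cycle1 * np.exp(-rate * (cycle - 1))
            n_events = rng.poisson(mean_rate * nrem_min) if mean_rate > 0 else 0
            for _ in range(n_events):
                mode, sd = ((config.tau_mode_slow, config.tau_sd_slow)
                            if klass == "slow"
                            else (config.tau_mode_fast, config.tau_sd_fast))
                tau = _draw_tau(rng, mode, sd)
                margin_pre = tau + 0.25
                margin_post = tau + config.channel_lag + _SPINDLE_DUR[1] + 0.25
                t_center = None
                for _try in range(200):
                    ri = rng.choice(len(runs), p=lengths / lengths.sum())
                    a, b = runs[ri]
                    if b - a <= margin_pre + margin_post:
                        continue
                    t = rng.uniform(a + margin_pre, b - margin_post)
                    if all(abs(t - q) >= _MIN_EVENT_GAP for q in placed):
                        t_center = t
                        break
                if t_center is None:
                    continue  # cycle saturated; drop the event
                placed.append(t_center)
                with_spindle = rng.random() < config.spindle_probability
                sp_dur = rng.uniform(*_SPINDLE_DUR) if with_spindle else 0.0
                for ch, lag in zip(labels, lags):
                    neg_t = t_center - tau / 2.0 + lag
                    pos_t = t_center + tau / 2.0 + lag
                    truth.slow_wave_events.append(
                        SlowWaveEvent(ch, neg_t, pos_t, tau, klass, cycle,
                                      t_center + lag))
                    if with_spindle:
                        # onset at wave phase -pi/4: an eighth of tau before
                        # the positive peak (linear phase over the transition)
                        onset = pos_t - tau / 8.0
                        truth.spindle_events.append(
                            SpindleEvent(ch, onset, onset + sp_dur))
    truth.slow_wave_events.sort(key=lambda e: (e.neg_peak_time, e.channel))
    truth.spindle_events.sort(key=lambda e: (e.onset, e.channel))
    return truth


def inject_slow_wave(signal: np.ndarray, t_center: float, tau: float,
                     amplitude: float, sr: float, *,
                     neg_duration: float | None = None,
                     pos_duration: float | None = None,
                     neg_fraction: float = 0.5) -> np.ndarray:
    """Add a biphasic slow-wave template to a single-channel signal in place.

    Parameters
    ----------
    signal : 1-D ndarray
        Channel samples (modified in place and returned).
    t_center : float
        Time (s) of the negative-to-positive zero crossing.
    tau : float
        Target delay between the negative and positive peaks; with default
        lobe durations both lobes last ``tau`` so the realized peak-to-peak
        delay equals ``tau`` exactly (up to the sample grid).
    amplitude : float
        Peak-to-peak amplitude in uV; split ``neg_fraction`` /
        ``1 - neg_fraction`` between the lobes.
    neg_duration, pos_duration : float, optional
        Lobe durations in seconds (default ``tau`` each).  Peaks sit at the
        lobe centers, so the realized delay is ``(d_neg + d_pos) / 2``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    d_neg = tau if neg_duration is None else float(neg_duration)
    d_pos = tau if pos_duration is None else float(pos_duration)
    if d_neg <= 0 or d_pos <= 0:
        raise ValueError("lobe durations must be positive")
    i0 = int(round((t_center - d_neg) * sr))
    i1 = int(round((t_center + d_pos) * sr))
    if i0 < 0 or i1 >= len(signal):
        raise ValueError("slow wave does not fit inside the signal")
    if amplitude == 0:
        return signal
    t = np.arange(i0, i1 + 1) / sr - t_center
    wave = np.zeros_like(t)
    neg = t < 0
    wave[neg] = -neg_fraction * amplitude * np.sin(np.pi * (t[neg] + d_neg) / d_neg)
    wave[~neg] = (1.0 - neg_fraction) * amplitude * np.sin(np.pi * t[~neg] / d_pos)
    signal[i0:i1 + 1] += wave
    return signal


def inject_spindle(signal: np.ndarray, onset: float, duration: float, sr: float,
                   freq: float = _SPINDLE_FREQ,
                   amplitude: float = _SPINDLE_AMP) -> np.ndarray:
    """Add a Hann-windowed sinusoidal burst to a single-channel signal in place."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    i0 = int(round(onset * sr))
    n = int(round(duration * sr))
    if i0 < 0 or i0 + n >= len(signal):
        raise ValueError("spindle does not fit inside the signal")
    t = np.arange(n) / sr
    burst = amplitude * np.hanning(n) * np.sin(2 * np.pi * freq * t)
    signal[i0:i0 + n] += burst
    return signal


def one_over_f_noise(n_samples: int, exponent: float, rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, scaled to `rms` uV."""
    white = rng.standard_normal(n_samples)
    if exponent == 0 or rms == 0:
        return white * (rms / max(white.std(), 1e-12))
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shape, n=n_samples)
    return x * (rms / max(x.std(), 1e-12))


def generate_recording(config: SyntheticConfig
                       ) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Synthesize a seeded multichannel recording with its ground truth.

    Returns the recording (channels x samples, uV), the block hypnogram and
    the injected-event inventory.  Identical configs (including the seed)
    give bit-identical output.
    """
    children = np.random.SeedSequence(config.seed).spawn(2)
    plan_rng = np.random.Generator(np.random.PCG64(children[0]))
    noise_rng = np.random.Generator(np.random.PCG64(children[1]))

    hypnogram = build_hypnogram(config)
    truth = plan_events(config, hypnogram, plan_rng)

    n = config.n_samples
    sr = config.sampling_rate
    signal = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        signal[ch] = one_over_f_noise(n, config.noise_exponent, config.noise_rms,
                                      noise_rng)
    label_to_idx = {lab: i for i, lab in enumerate(config.channel_labels)}
    for ev in truth.slow_wave_events:
        inject_slow_wave(signal[label_to_idx[ev.channel]], ev.t_center, ev.tau,
                         config.sw_amplitude, sr)
    for sp in truth.spindle_events:
        inject_spindle(signal[label_to_idx[sp.channel]], sp.onset,
                       sp.offset - sp.onset, sr)
    rec = Recording(signal, sr, config.channel_labels)
    return rec, hypnogram, truth
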