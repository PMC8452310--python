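"""Shared fixtures: small seeded synthetic recordings and builders."""

from __future__ import annotations

import math

import numpy as np
import pytest

import slowswitch as sw

SR = 256.0


def flat_recording(duration_s: float, n_channels: int = 1,
                   labels: tuple[str, ...] | None = None) -> sw.Recording:
    """All-zero recording, handy for injecting single templates."""
    n = int(round(duration_s * SR))
    if labels is None:
        labels = sw.CHANNELS_1020[:n_channels]
    return sw.Recording(np.zeros((n_channels, n)), SR, labels)


def nrem_hypnogram(n_samples: int, sr: float = SR, stage: str = "N2",
                   cycle: int = 1) -> sw.Hypnogram:
    """Single-stage artifact-free hypnogram covering `n_samples`."""
    n_ep = math.ceil(n_samples / int(30 * sr))
    return sw.Hypnogram(np.array([stage] * n_ep, dtype=object),
                        np.full(n_ep, cycle), np.zeros(n_ep, dtype=bool))


@pytest.fixture(scope="session")
def synth_small():
    """6-channel, 3-cycle synthetic night (8 min/cycle) at default rates."""
    cfg = sw.SyntheticConfig(n_channels=6, n_cycles=3, cycle_minutes=8, seed=7)
    rec, hyp, truth = sw.generate_recording(cfg)
    return cfg, rec, hyp, truth


@pytest.fixture(scope="session")
def detected_small(synth_small):
    """Detection + phase maps on the small synthetic night."""
    cfg, rec, hyp, truth = synth_small
    sr = rec.sampling_rate
    delta = sw.bandpass_delta(rec.signal, sr)
    waves = sw.detect_slow_waves(delta, hyp, sr, rec.channel_labels)
    phase_band = sw.bandpass_delta(rec.signal, sr, 0.16, 4.0)
    sw.attach_phase_maps(phase_band, waves, sr, rec.channel_labels)
    return dict(cfg=cfg, rec=rec, hyp=hyp, truth=truth, delta=delta,
                phase_band=phase_band, waves=waves)
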