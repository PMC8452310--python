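"""Core containers for multichannel sleep EEG analysis.

A :class:`Recording` holds the scalp EEG matrix in microvolts, a
:class:`Hypnogram` the 30-s epoch staging with sleep-cycle indices and an
artifact mask, and :class:`SlowWave` / :class:`Spindle` one detected event
each.  All times are seconds from recording onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: 19-channel subset of the international 10-20 montage, in the order the
#: synthetic generator lays them out.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Derivation clusters used for pooled, region-wise analyses.
CLUSTERS: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "Fz", "F4"),
    "central": ("C3", "Cz", "C4"),
    "parietal": ("P3", "Pz", "P4"),
}

EPOCH_SECONDS = 30.0
NREM_STAGES = frozenset({"N2", "N3"})
VALID_STAGES = frozenset({"W", "N1", "N2", "N3", "R"})


class AlignmentError(ValueError):
    """Hypnogram and recording do not describe the same time axis."""


@dataclass
class Recording:
    """Multichannel EEG signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    sampling_rate : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique 10-20 channel names, one per signal row.
    reference : str
        Free-text description of the recording reference.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    reference: str = "linked earlobes"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class Hypnogram:
    """Per-epoch sleep staging with cycle indices and artifact flags.

    ``stages`` holds one label per 30-s epoch in {W, N1, N2, N3, R};
    ``cycle_index`` the 1-based sleep-cycle number (0 = outside any cycle);
    ``artifact_mask`` is True for epochs rejected as artifactual.
    """

    stages: np.ndarray
    cycle_index: np.ndarray
    artifact_mask: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        self.cycle_index = np.asarray(self.cycle_index, dtype=int)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        n = len(self.stages)
        if len(self.cycle_index) != n or len(self.artifact_mask) != n:
            raise ValueError("stages, cycle_index and artifact_mask must have equal length")
        bad = set(self.stages) - VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def eligible_epochs(self, stages: frozenset[str] = NREM_STAGES) -> np.ndarray:
        """Boolean mask of artifact-free epochs in the requested stages."""
        in_stage = np.isin(self.stages.astype(str), sorted(stages))
        return in_stage & ~self.artifact_mask

    def eligible_minutes(self, stages: frozenset[str] = NREM_STAGES) -> float:
        return self.eligible_epochs(stages).sum() * EPOCH_SECONDS / 60.0

    def check_alignment(self, n_samples: int, sr: float) -> None:
        """Raise :class:`AlignmentError` unless the epoch grid covers the signal."""
        spe = int(round(EPOCH_SECONDS * sr))
        lo = (self.n_epochs - 1) * spe
        hi = self.n_epochs * spe
        if not (lo < n_samples <= hi):
            raise AlignmentError(
                f"{self.n_epochs} epochs cover ({lo}, {hi}] samples, signal has {n_samples}"
            )

    def epoch_of(self, time: float, sr: float) -> int:
        return int(time * sr) // int(round(EPOCH_SECONDS * sr))

    def sample_mask(self, n_samples: int, sr: float,
                    stages: frozenset[str] = NREM_STAGES) -> np.ndarray:
        """Per-sample eligibility mask (artifact-free epochs of `stages`)."""
        self.check_alignment(n_samples, sr)
        spe = int(round(EPOCH_SECONDS * sr))
        return np.repeat(self.eligible_epochs(stages), spe)[:n_samples]

    def cycles(self) -> list[int]:
        """Sorted list of cycle numbers present (excluding 0)."""
        return sorted(c for c in np.unique(self.cycle_index) if c > 0)


@dataclass
class SlowWave:
    """One detected slow wave on a single derivation.

    The wave spans ``start_time`` (negative-going zero crossing) to
    ``end_time`` (next negative-going crossing).  ``tau`` is the delay from
    the maximum negative point to the maximum positive point; the transition
    frequency is ``f_tau = 1 / (2 tau)``.  ``T`` is the total duration and
    ``frequency = 1 / T``.
    """

    channel: str
    start_time: float
    end_time: float
    neg_peak_time: float
    pos_peak_time: float
    neg_peak_amp: float
    pos_peak_amp: float
    neg_duration: float
    pos_duration: float
    T: float
    frequency: float
    tau: float
    f_tau: float
    cycle: int = 0
    phase_map: Optional["PhaseMap"] = None  # noqa: F821 - set by transition module
    phase_ok: bool = False
    has_spindle: bool = False
    switcher: str = "unlabeled"

    def to_row(self) -> dict:
        return {
            "channel": self.channel,
            "start_time": self.start_time,
            "end_time": self.end_time,
            "neg_peak_time": self.neg_peak_time,
            "pos_peak_time": self.pos_peak_time,
            "neg_peak_amp": self.neg_peak_amp,
            "pos_peak_amp": self.pos_peak_amp,
            "neg_duration": self.neg_duration,
            "pos_duration": self.pos_duration,
            "duration_s": self.T,
            "frequency_hz": self.frequency,
            "tau_s": self.tau,
            "f_tau_hz": self.f_tau,
            "cycle": self.cycle,
            "phase_ok": self.phase_ok,
            "has_spindle": self.has_spindle,
            "switcher": self.switcher,
        }


@dataclass
class Spindle:
    """One detected sleep spindle (10-16 Hz burst, 0.5-3 s)."""

    channel: str
    onset: float
    offset: float
    peak_envelope: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def to_row(self) -> dict:
        return {
            "channel": self.channel,
            "onset": self.onset,
            "offset": self.offset,
            "duration_s": self.duration,
            "peak_envelope": self.peak_envelope,
        }
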