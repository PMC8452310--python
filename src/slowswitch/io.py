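"""File formats: EDF recordings, plain-text hypnograms, event tables.

Recordings are written as 16-bit EDF (European Data Format) with microvolt
physical units at 0.1 uV resolution; the writer emits the format directly
(ASCII header blocks + little-endian int16 data records) and reading goes
through :mod:`mne`.  Hypnograms travel as CSV with columns
``epoch,stage,cycle,artifact`` (one row per 30-s epoch) or as a bare text
file with one stage label per line.  Ground truth and fitted models are
JSON; event inventories are tidy CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Hypnogram, Recording, SlowWave, Spindle
from .synthetic import GroundTruth, SlowWaveEvent, SpindleEvent

_PHYS_MIN, _PHYS_MAX = -3276.8, 3276.7   # uV, 0.1 uV / digit at 16 bit
_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: Recording) -> Path:
    """Write a recording as 16-bit EDF with microvolt physical units.

    The sampling rate must be an integer (one data record per second).
    The final partial record, if any, is zero-padded.  Header date/time
    fields are fixed so identical recordings give byte-identical files.
    """
    path = Path(path)
    sr = recording.sampling_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sr))
    n_sig = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / spr))
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2001 X X X", 80),
        _ascii("01.01.01", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_sig + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii("1", 8),
        _ascii(n_sig, 4),
    ])
    fields = [
        (16, [lab for lab in recording.channel_labels]),
        (80, ["AgAgCl electrode"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"{_PHYS_MIN}"] * n_sig),
        (8, [f"{_PHYS_MAX}"] * n_sig),
        (8, [f"{_DIG_MIN}"] * n_sig),
        (8, [f"{_DIG_MAX}"] * n_sig),
        (80, [""] * n_sig),
        (8, [f"{spr}"] * n_sig),
        (32, [""] * n_sig),
    ]
    for width, values in fields:
        header += b"".join(_ascii(v, width) for v in values)
    scale = (_DIG_MAX - _DIG_MIN) / (_PHYS_MAX - _PHYS_MIN)
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : recording.n_samples] = np.clip(recording.signal,
                                               _PHYS_MIN, _PHYS_MAX)
    digital = np.rint((padded - _PHYS_MIN) * scale + _DIG_MIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr: (r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF recording via MNE; signal returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # V -> uV
    return Recording(signal=signal, sampling_rate=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names))


def write_hypnogram(path: str | Path, hypnogram: Hypnogram) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "epoch": np.arange(hypnogram.n_epochs),
        "stage": hypnogram.stages.astype(str),
        "cycle": hypnogram.cycle_index,
        "artifact": hypnogram.artifact_mask.astype(int),
    })
    df.to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram from CSV (epoch,stage,cycle,artifact) or from a
    plain list of stage labels (one per line; no cycles, no artifacts)."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if "," in first:
        df = pd.read_csv(path)
        return Hypnogram(df["stage"].to_numpy(dtype=object),
                         df["cycle"].to_numpy(dtype=int),
                         df["artifact"].to_numpy(dtype=bool))
    stages = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    n = len(stages)
    return Hypnogram(np.array(stages, dtype=object), np.zeros(n, dtype=int),
                     np.zeros(n, dtype=bool))


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    payload = {
        "slow_wave_events": [asdict(e) for e in truth.slow_wave_events],
        "spindle_events": [asdict(e) for e in truth.spindle_events],
        "cycle_boundaries": list(truth.cycle_boundaries),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        slow_wave_events=[SlowWaveEvent(**e) for e in payload["slow_wave_events"]],
        spindle_events=[SpindleEvent(**e) for e in payload["spindle_events"]],
        cycle_boundaries=list(payload["cycle_boundaries"]),
    )


def waves_to_frame(waves: list[SlowWave]) -> pd.DataFrame:
    if not waves:
        return pd.DataFrame(columns=list(SlowWave(
            "x", 0, 1, 0.2, 0.5, -50, 40, 0.4, 0.5, 1.0, 1.0, 0.3,
            1 / 0.6).to_row()))
    return pd.DataFrame([w.to_row() for w in waves])


def spindles_to_frame(spindles: list[Spindle]) -> pd.DataFrame:
    if not spindles:
        return pd.DataFrame(columns=["channel", "onset", "offset",
                                     "duration_s", "peak_envelope"])
    return pd.DataFrame([s.to_row() for s in spindles])


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    """Deterministic CSV output (fixed float format, no index)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
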