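"""Event-locked phase-lag-index (PLI) connectivity along the depolarization
transition.

For every slow wave k detected on derivation n* we read, at six wave
phases, the instantaneous Hilbert phase of the detection channel and the
simultaneous phase of every other derivation m.  The directed PLI

    pli(n*, m) = (1 / N*) * sum_k sign(sin(phi_n*k - phi_mk))

is the mean sign of the phase difference over the N* waves detected on n*;
it is 0 for zero-lag (volume-conducted) synchrony and +/-1 for a constant
non-vanishing delay.  Symmetrizing over the detection role,
PLI(n, m) = (pli(n*, m) + pli(n, m*)) / 2, emphasizes cortico-cortical
propagation, for which both directed values share the same sign.

Significance is assessed with a phase-resampling max-statistics null: in
each permutation the non-detection channels' phase vectors are permuted
independently across events, and the maximum |PLI| over all electrode
pairs is recorded; the (1 - p) quantile of that distribution thresholds
the observed |PLI| matrix with family-wise error control.  The global
connectivity index (GCI) is the sum of |PLI| over significant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .data import SlowWave

logger = logging.getLogger(__name__)

#: The six wave phases: five evenly spaced along the transition from the
#: hyperpolarization maximum (-pi) to the depolarization maximum (0), and a
#: sixth after the depolarization maximum.
PHASE_POINTS: tuple[float, ...] = (-np.pi, -3 * np.pi / 4, -np.pi / 2,
                                   -np.pi / 4, 0.0, np.pi / 4)
PHASE_LABELS: tuple[str, ...] = ("a", "b", "c", "d", "e", "f")


@dataclass
class PhaseConnectivity:
    """Per-phase PLI matrices, max-statistics thresholds, masks and GCI."""

    channels: tuple[str, ...]
    phase_points: dict[str, float]
    n_events: dict[str, int]
    pli_directed: dict[str, np.ndarray] = field(default_factory=dict)
    pli_symmetric: dict[str, np.ndarray] = field(default_factory=dict)
    null_threshold: dict[str, float] = field(default_factory=dict)
    significant_mask: dict[str, np.ndarray] = field(default_factory=dict)
    gci: dict[str, float] = field(default_factory=dict)


def phase_matrix(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous Hilbert phase of every channel of a band-limited array."""
    filtered = np.atleast_2d(filtered)
    n = filtered.shape[1]
    analytic = hilbert(filtered, N=next_fast_len(n), axis=1)[:, :n]
    return np.angle(analytic)


def sample_phase_points(wave: SlowWave,
                        phases: tuple[float, ...] = PHASE_POINTS,
                        labels: tuple[str, ...] = PHASE_LABELS
                        ) -> dict[str, tuple[float, float | None]]:
    """Times at which one wave passes the six phases.

    Returns ``{label: (phase, time)}``; the time is None for phases outside
    the wave's phase-map span (e.g. a wave whose map stops short of +pi/4
    is excluded from phase f only).
    """
    if wave.phase_map is None:
        raise ValueError("wave has no phase map")
    pm = wave.phase_map
    lo, hi = pm.covers
    out: dict[str, tuple[float, float | None]] = {}
    for lab, phi in zip(labels, phases):
        if lo - 1e-9 <= phi <= hi + 1e-9:
            out[lab] = (phi, float(pm.time_at_phase(phi)))
        else:
            out[lab] = (phi, None)
    return out


def event_pli(phi_det: np.ndarray, phi_others: np.ndarray) -> np.ndarray:
    """Directed pli(n*, m) for one detection channel.

    Parameters
    ----------
    phi_det : ndarray, (n_events,)
        Phase of the detection channel at the sampled wave phase.
    phi_others : ndarray, (n_channels, n_events)
        Simultaneous phases of the other derivations.

    Returns
    -------
    ndarray, (n_channels,)
        Mean sign of sin(phi_det - phi_m) per channel, in [-1, 1].
    """
    phi_det = np.asarray(phi_det, dtype=float)
    phi_others = np.atleast_2d(np.asarray(phi_others, dtype=float))
    if phi_others.shape[1] != len(phi_det):
        raise ValueError("event counts differ between detection and other channels")
    return np.sign(np.sin(phi_det[None, :] - phi_others)).mean(axis=1)


def symmetrize_pli(pli_ab: float | np.ndarray,
                   pli_ba: float | np.ndarray) -> float | np.ndarray:
    """PLI(n, m) = (pli(n*, m) + pli(n, m*)) / 2."""
    return 0.5 * (np.asarray(pli_ab) + np.asarray(pli_ba))


def _directed_matrix(angles: np.ndarray,
                     event_indices: dict[int, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Directed PLI matrix D[n, m] = pli(n*, m) and availability mask.

    ``event_indices`` maps detection-channel index -> sample indices of its
    waves at one phase point; channels absent from the map give NaN rows.
    """
    n_ch = angles.shape[0]
    D = np.full((n_ch, n_ch), np.nan)
    avail = np.zeros(n_ch, dtype=bool)
    for n, idx in event_indices.items():
        if len(idx) == 0:
            continue
        phases = angles[:, idx]          # (n_ch, N*)
        D[n] = np.sign(np.sin(phases[n][None, :] - phases)).mean(axis=1)
        D[n, n] = 0.0
        avail[n] = True
    return D, avail


def _symmetrize_matrix(D: np.ndarray, avail: np.ndarray) -> np.ndarray:
    """Average the two detection roles of each pair.

    For the pair (n, m), pli(n*, m) is ``D[n, m]`` while pli(n, m*) - the
    same n-minus-m phase difference read from the waves detected on m - is
    ``-D[m, n]``: swapping the detection role flips the sign of the
    difference, so true propagation contributes with the same sign to both
    terms and zero-lag (symmetric) structure cancels.  When only one
    detection direction has enough events, that direction is used alone.
    The returned matrix mirrors the n < m orientation onto the lower
    triangle, so it is symmetric; the entry magnitude is orientation-free.
    """
    n_ch = D.shape[0]
    A = np.broadcast_to(avail[:, None], (n_ch, n_ch))
    num = np.where(A, D, 0.0) - np.where(A.T, D.T, 0.0)
    den = A.astype(float) + A.T.astype(float)
    with np.errstate(invalid="ignore"):
        P = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    il = np.tril_indices(n_ch, k=-1)
    P[il] = P.T[il]
    np.fill_diagonal(P, 0.0)
    return P


def null_threshold(angles: np.ndarray, event_indices: dict[int, np.ndarray],
                   n_perm: int = 1000, p: float = 0.01,
                   seed: int | np.random.SeedSequence | None = None,
                   chunk: int = 250) -> float:
    """Max-statistics threshold at one phase point.

    In each resample, for every detection channel, the phases of the
    non-detection channels are redrawn uniformly on (-pi, pi] per event and
    per channel - the no-phase-locking null, under which the sign of
    sin(phase difference) is a fair coin regardless of the event-locked
    (nearly constant) detection phase.  The maximum |PLI| over all
    electrode pairs is recorded per resample and the (1 - p) empirical
    quantile (linear interpolation) is returned.

    Note that permuting the other channels' phases across events, a more
    conventional pairing-destruction null, is *not* valid here: the
    detection channel's phase is pinned to the sampled wave phase by
    construction, so the PLI is almost invariant to such permutations.
    """
    if seed is None:
        raise ValueError("a seed is required for a reproducible null")
    if n_perm < 100:
        logger.warning("n_perm=%d is low for p=%g; threshold will be coarse",
                       n_perm, p)
    rng = np.random.default_rng(seed)
    n_ch = angles.shape[0]
    others_by_det = {n: np.delete(np.arange(n_ch), n) for n in event_indices}
    max_stats = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        D_perm = np.full((m, n_ch, n_ch), np.nan)
        avail = np.zeros(n_ch, dtype=bool)
        for n, idx in event_indices.items():
            if len(idx) == 0:
                continue
            avail[n] = True
            own = angles[n, idx]                         # (N,)
            M, N = len(others_by_det[n]), len(idx)
            surrogate = rng.uniform(-np.pi, np.pi, size=(m, M, N))
            rows = np.sign(np.sin(own[None, None, :] - surrogate)).mean(axis=2)
            D_perm[:, n, others_by_det[n]] = rows
            D_perm[:, n, n] = 0.0
        for j in range(m):
            P = _symmetrize_matrix(D_perm[j], avail)
            iu = np.triu_indices(n_ch, k=1)
            max_stats[done + j] = np.abs(P[iu]).max() if n_ch > 1 else 0.0
        done += m
    return float(np.quantile(max_stats, 1.0 - p))


def global_connectivity_index(pli_symmetric: np.ndarray,
                              mask: np.ndarray) -> float:
    """Sum of |PLI| over significant upper-triangle pairs (0 if none)."""
    iu = np.triu_indices(pli_symmetric.shape[0], k=1)
    sel = mask[iu]
    return float(np.abs(pli_symmetric[iu][sel]).sum())


def connectivity_analysis(filtered: np.ndarray, waves: list[SlowWave],
                          sr: float, channel_labels: tuple[str, ...],
                          n_perm: int = 1000, p: float = 0.01,
                          min_events: int = 20,
                          seed: int | np.random.SeedSequence | None = 0,
                          phase_points: tuple[float, ...] = PHASE_POINTS,
                          phase_labels: tuple[str, ...] = PHASE_LABELS
                          ) -> PhaseConnectivity:
    """Full event-locked connectivity analysis at the six wave phases.

    Parameters
    ----------
    filtered : ndarray, (n_channels, n_samples)
        Signals filtered in the phase characteristics band (0.16-4 Hz).
    waves : list of SlowWave
        Waves with valid phase maps (``phase_ok``); others are skipped.
        Waves are grouped by detection channel, and channels with fewer
        than `min_events` usable waves are excluded (logged).
    """
    filtered = np.atleast_2d(filtered)
    n_ch, n_samples = filtered.shape
    angles = phase_matrix(filtered)
    index = {lab: i for i, lab in enumerate(channel_labels)}
    # per phase label, per detection channel: sample indices
    per_phase: dict[str, dict[int, list[int]]] = {lab: {} for lab in phase_labels}
    usable = [w for w in waves if w.phase_ok and w.phase_map is not None]
    counts: dict[str, int] = {}
    for w in usable:
        ch = index[w.channel]
        counts[w.channel] = counts.get(w.channel, 0) + 1
        pts = sample_phase_points(w, phase_points, phase_labels)
        for lab, (_phi, t) in pts.items():
            if t is None:
                continue
            si = int(round(t * sr))
            if 0 <= si < n_samples:
                per_phase[lab].setdefault(ch, []).append(si)
    kept = {ch for ch, c in counts.items() if c >= min_events}
    dropped = sorted(set(counts) - kept)
    if dropped:
        logger.info("channels below %d events dropped from directed PLI: %s",
                    min_events, dropped)
    result = PhaseConnectivity(
        channels=tuple(channel_labels),
        phase_points=dict(zip(phase_labels, phase_points)),
        n_events={ch: counts.get(ch, 0) for ch in channel_labels},
    )
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(phase_labels))
    for lab, child in zip(phase_labels, children):
        ev = {index[ch]: np.asarray(idx)
              for ch, idx in ((c, per_phase[lab].get(index[c], [])) for c in kept)
              if len(idx) >= min_events}
        if not ev:
            z = np.zeros((n_ch, n_ch))
            result.pli_directed[lab] = z
            result.pli_symmetric[lab] = z.copy()
            result.null_threshold[lab] = np.inf
            result.significant_mask[lab] = np.zeros((n_ch, n_ch), dtype=bool)
            result.gci[lab] = 0.0
            continue
        D, avail = _directed_matrix(angles, ev)
        P = _symmetrize_matrix(D, avail)
        thr = null_threshold(angles, ev, n_perm=n_perm, p=p, seed=child)
        mask = np.abs(P) > thr
        np.fill_diagonal(mask, False)
        result.pli_directed[lab] = np.nan_to_num(D, nan=0.0)
        result.pli_symmetric[lab] = P
        result.null_threshold[lab] = thr
        result.significant_mask[lab] = mask
        result.gci[lab] = global_connectivity_index(P, mask)
    return result
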