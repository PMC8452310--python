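"""Band-pass filters for slow-wave and spindle analysis.

Two realizations are used, matching the two detection stages:

* :func:`bandpass_delta` - a zero-phase spectral-gain filter for the delta
  band.  The amplitude response is built from half-cosine transition ramps
  solved so that the gain is exactly -3 dB at the passband edges and
  -23 dB at the stopband anchor frequencies; the symmetric (real, positive)
  transfer function applied in the frequency domain introduces no phase
  distortion, which matters because peak times feed the transition-delay
  statistic.
* :func:`bandpass_sigma` - a linear-phase FIR (windowed sinc) for the
  sigma band, applied with group-delay compensation; cutoffs are calibrated
  numerically so the -3 dB points sit on the requested band edges.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal as sps


def _ramp_params(f_pass: float, f_stop: float, edge_db: float, stop_db: float,
                 rising: bool) -> tuple[float, float]:
    """Solve the half-cosine ramp g(f)=sin^2(pi/2 * (f-a)/w) (or the mirrored
    falling version) so that |g(f_pass)| = -edge_db and |g(f_stop)| = -stop_db.

    Returns (a, w): ramp start and width, with gain 0 at `a` (rising) or
    gain 1 at `a` (falling).
    """
    g_edge = 10.0 ** (-edge_db / 20.0)
    g_stop = 10.0 ** (-stop_db / 20.0)
    if rising:
        u_edge = (2.0 / np.pi) * np.arcsin(np.sqrt(g_edge))
        u_stop = (2.0 / np.pi) * np.arcsin(np.sqrt(g_stop))
    else:
        u_edge = (2.0 / np.pi) * np.arccos(np.sqrt(g_edge))
        u_stop = (2.0 / np.pi) * np.arccos(np.sqrt(g_stop))
    w = (f_pass - f_stop) / (u_edge - u_stop)
    a = f_pass - u_edge * w
    return a, w


def band_gain(freqs: np.ndarray, low: float, high: float,
              stop_low: float, stop_high: float,
              edge_db: float = 3.0, stop_db: float = 23.0) -> np.ndarray:
    """Amplitude gain curve of the delta-band filter on a frequency grid."""
    a_lo, w_lo = _ramp_params(low, stop_low, edge_db, stop_db, rising=True)
    a_hi, w_hi = _ramp_params(high, stop_high, edge_db, stop_db, rising=False)
    g = np.ones_like(freqs, dtype=float)
    # rising ramp
    lo_ramp = (freqs >= a_lo) & (freqs < a_lo + w_lo)
    g[freqs < a_lo] = 0.0
    u = (freqs[lo_ramp] - a_lo) / w_lo
    g[lo_ramp] = np.sin(0.5 * np.pi * u) ** 2
    # falling ramp
    hi_ramp = (freqs >= a_hi) & (freqs < a_hi + w_hi)
    v = (freqs[hi_ramp] - a_hi) / w_hi
    g[hi_ramp] = np.minimum(g[hi_ramp], np.cos(0.5 * np.pi * v) ** 2)
    g[freqs >= a_hi + w_hi] = 0.0
    g[freqs <= 0] = 0.0
    return g


def _default_stops(low: float, high: float) -> tuple[float, float]:
    stop_low = low - 0.2 if low - 0.2 > 0.02 else low / 2.0
    return stop_low, high + 0.2


def bandpass_delta(x: np.ndarray, sr: float, low: float = 0.3, high: float = 4.0,
                   stop_low: float | None = None, stop_high: float | None = None,
                   edge_db: float = 3.0, stop_db: float = 23.0) -> np.ndarray:
    """Zero-phase delta band-pass: -3 dB at (low, high), -23 dB at the stops.

    Parameters
    ----------
    x : ndarray, (..., n_samples)
        Signal(s); filtering runs along the last axis.
    sr : float
        Sampling rate in Hz.
    low, high : float
        -3 dB band edges (defaults 0.3-4.0 Hz).
    stop_low, stop_high : float, optional
        Frequencies at which attenuation reaches ``stop_db`` (defaults
        0.1 Hz below / 0.2 Hz above the band, i.e. 0.1 and 4.2 Hz for the
        canonical band).

    Returns
    -------
    ndarray
        Filtered signal, same shape as the input.
    """
    if stop_low is None or stop_high is None:
        d_lo, d_hi = _default_stops(low, high)
        stop_low = d_lo if stop_low is None else stop_low
        stop_high = d_hi if stop_high is None else stop_high
    nyq = sr / 2.0
    if not (0 < stop_low < low < high < stop_high):
        raise ValueError("need 0 < stop_low < low < high < stop_high")
    if stop_high >= nyq:
        raise ValueError(f"upper stop {stop_high} Hz is at/above Nyquist ({nyq} Hz)")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sr)
    g = band_gain(freqs, low, high, stop_low, stop_high, edge_db, stop_db)
    X = np.fft.rfft(x, axis=-1)
    return np.fft.irfft(X * g, n=n, axis=-1)


@lru_cache(maxsize=8)
def design_sigma_fir(sr: float, low: float = 10.0, high: float = 16.0,
                     numtaps: int | None = None) -> np.ndarray:
    """Linear-phase FIR for the sigma band with -3 dB points at (low, high).

    A Hamming-windowed sinc puts -6 dB at its nominal cutoffs, so the
    cutoffs are nudged outward iteratively until the measured -3 dB
    frequencies land on the requested edges (within the freqz grid).
    """
    if numtaps is None:
        numtaps = int(4 * sr) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    lo, hi = float(low), float(high)
    target = 1.0 / np.sqrt(2.0)
    h = None
    for _ in range(4):
        h = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=sr)
        w, resp = sps.freqz(h, worN=32768, fs=sr)
        mag = np.abs(resp)
        mid = np.searchsorted(w, 0.5 * (low + high))
        # lower -3 dB crossing (gain rising through target below band center)
        below = np.flatnonzero(mag[:mid] < target)
        i = below[-1]
        f3_lo = np.interp(target, [mag[i], mag[i + 1]], [w[i], w[i + 1]])
        above = np.flatnonzero(mag[mid:] < target) + mid
        j = above[0]
        f3_hi = np.interp(target, [mag[j], mag[j - 1]], [w[j], w[j - 1]])
        err_lo, err_hi = f3_lo - low, f3_hi - high
        if abs(err_lo) < 5e-3 and abs(err_hi) < 5e-3:
            break
        lo -= err_lo
        hi -= err_hi
    return h


def bandpass_sigma(x: np.ndarray, sr: float, low: float = 10.0,
                   high: float = 16.0, numtaps: int | None = None) -> np.ndarray:
    """Sigma (10-16 Hz) band-pass with a delay-compensated linear-phase FIR."""
    if high >= sr / 2.0:
        raise ValueError("upper band edge at/above Nyquist")
    h = design_sigma_fir(sr, low, high, numtaps)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return sps.fftconvolve(x, h, mode="same")
    return np.stack([sps.fftconvolve(row, h, mode="same") for row in x])
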