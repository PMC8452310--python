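"""Across-cycle dynamics of slow and fast switchers.

Each switcher class is summarized by the percentage of its waves falling in
each sleep cycle (percentages sum to 100 over the night), and the decline
over the first cycles is fitted with one of two exponential forms:

* ``decay``:      y(t) = a * exp(-r * t)
* ``reduction``:  y(t) = a - b * exp(r * t),  a, b >= 0

with t the 1-based cycle index.  The rate r >= 0 is shared notation for
both forms; the amplitude parameters are profiled out by linear least
squares so the fit reduces to a 1-D search over r, which recovers
noise-free model-generated rates to machine-level precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize_scalar

from .data import SlowWave

_R_MAX = 20.0


@dataclass
class DecayFit:
    """Exponential fit of per-cycle percentages for one switcher class."""

    model_form: str            # "decay" | "reduction"
    r: float                   # per-cycle rate, >= 0
    r_squared: float
    amplitude: float           # a
    offset: float              # b (0 for the decay form)
    cycle_percentages: np.ndarray

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model_form == "decay":
            return self.amplitude * np.exp(-self.r * t)
        return self.amplitude - self.offset * np.exp(self.r * t)

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "r": self.r,
            "r_squared": self.r_squared,
            "amplitude": self.amplitude,
            "offset": self.offset,
            "cycle_percentages": list(map(float, self.cycle_percentages)),
        }


def cycle_percentages(waves: list[SlowWave],
                      cycles: list[int] | None = None) -> pd.DataFrame:
    """Percentage of each switcher class falling in each sleep cycle.

    For class c and cycle j the percentage is
    100 * count(c, j) / count(c, all cycles), so each class sums to 100
    over the night.  Waves must be labeled and cycle-indexed; a class with
    zero waves raises ``ValueError``.
    """
    labeled = [w for w in waves if w.switcher in ("slow", "fast") and w.cycle > 0]
    if cycles is None:
        cycles = sorted({w.cycle for w in labeled})
    if not cycles:
        raise ValueError("no cycle-indexed labeled waves")
    rows = []
    for klass in ("slow", "fast"):
        klass_waves = [w for w in labeled if w.switcher == klass]
        total = len(klass_waves)
        if total == 0:
            raise ValueError(f"no waves labeled '{klass}'")
        for j in cycles:
            count = sum(w.cycle == j for w in klass_waves)
            rows.append({"switcher": klass, "cycle": j, "count": count,
                         "percentage": 100.0 * count / total})
    return pd.DataFrame(rows)


def _profiled_ss(y: np.ndarray, t: np.ndarray, r: float, form: str
                 ) -> tuple[float, float, float]:
    """Residual sum of squares with amplitudes profiled out at fixed r."""
    if form == "decay":
        basis = np.exp(-r * t)
        a = float(y @ basis / (basis @ basis))
        a = max(a, 0.0)
        resid = y - a * basis
        return float(resid @ resid), a, 0.0
    # reduction: y = a - b e^{rt} with 0 <= a, b <= 4 max|y|.  The upper
    # bound keeps the family genuinely exponential: unbounded amplitudes
    # admit a degenerate r -> 0 limit in which a - b e^{rt} collapses to an
    # arbitrary straight line (a, b -> inf), making the fitted rate
    # meaningless.
    A = np.column_stack([np.ones_like(t), -np.exp(r * t)])
    cap = 4.0 * float(np.max(np.abs(y))) if np.any(y) else 1.0
    sol = lsq_linear(A, y, bounds=([0.0, 0.0], [cap, cap]))
    return float(sol.cost * 2.0), float(sol.x[0]), float(sol.x[1])


def _fit_form(y: np.ndarray, t: np.ndarray, form: str) -> DecayFit:
    res = minimize_scalar(lambda r: _profiled_ss(y, t, r, form)[0],
                          bounds=(0.0, _R_MAX), method="bounded",
                          options={"xatol": 1e-12})
    r = float(res.x)
    ss, a, b = _profiled_ss(y, t, r, form)
    # the bounded search cannot return exactly 0; snap when flat data fit better
    ss0, a0, b0 = _profiled_ss(y, t, 0.0, form)
    if ss0 <= ss + 1e-12:
        r, ss, a, b = 0.0, ss0, a0, b0
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 1.0 if ss <= 1e-12 else 0.0
    else:
        r2 = 1.0 - ss / ss_tot
    return DecayFit(model_form=form, r=r, r_squared=r2, amplitude=a, offset=b,
                    cycle_percentages=y.copy())


def fit_decay(percentages: np.ndarray, form: str | None = None,
              max_cycles: int = 3) -> DecayFit:
    """Fit the across-cycle exponential to per-cycle percentages.

    Parameters
    ----------
    percentages : array
        Percentage per cycle, cycle 1 first.  Only the first
        `max_cycles` values enter the fit (later cycles are sparse in real
        cohorts).
    form : {"decay", "reduction", None}
        Exponential form; with None both are fitted and the better
        (higher R-squared) fit is returned, ties going to the decay form.
    """
    y = np.asarray(percentages, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("percentages must be finite")
    if len(y) < 3:
        raise ValueError("need at least 3 cycles to fit")
    y = y[:max_cycles]
    t = np.arange(1, len(y) + 1, dtype=float)
    if form is not None:
        if form not in ("decay", "reduction"):
            raise ValueError("form must be 'decay', 'reduction' or None")
        return _fit_form(y, t, form)
    fits = [_fit_form(y, t, "decay"), _fit_form(y, t, "reduction")]
    return max(fits, key=lambda f: (f.r_squared, f.model_form == "decay"))


def fit_cycle_dynamics(waves: list[SlowWave], form: str | None = None,
                       max_cycles: int = 3,
                       cycles: list[int] | None = None) -> dict[str, DecayFit]:
    """Per-class decay fits from labeled, cycle-indexed waves."""
    table = cycle_percentages(waves, cycles=cycles)
    out: dict[str, DecayFit] = {}
    for klass in ("slow", "fast"):
        sub = table[table.switcher == klass].sort_values("cycle")
        out[klass] = fit_decay(sub.percentage.to_numpy(), form=form,
                               max_cycles=max_cycles)
    return out
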