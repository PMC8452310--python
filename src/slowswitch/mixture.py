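"""Two-Gaussian mixture of transition frequencies: slow vs fast switchers.

The per-subject distribution of transition frequencies f_tau is modelled as

    p(f) = p_slow N(f; mu_slow, sd_slow^2) + p_fast N(f; mu_fast, sd_fast^2),
    p_slow + p_fast = 1,

fitted by expectation-maximization.  The number of components is selected
by the Akaike Information Criterion (AIC = 2 * n_params - 2 * logL), and the
crossing frequency f* - the root of
p_slow g_slow(f) = p_fast g_fast(f) between the two means - separates the
classes: a wave is a *slow switcher* iff f_tau < f*, a *fast switcher*
otherwise (ties go to fast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .data import SlowWave

#: EM settings: k-means++ initialisation with restarts, tight convergence,
#: and a variance floor (in Hz^2) preventing degenerate spike components
#: that would otherwise let over-parameterized fits win the AIC comparison.
EM_DEFAULTS = dict(n_init=10, tol=1e-6, max_iter=500, reg_covar=1e-3,
                   init_params="k-means++")


@dataclass
class MixtureModel:
    """Fitted Gaussian mixture over transition frequencies (Hz).

    Components are sorted by mean, so for the two-component model index 0
    is the slow-switcher and index 1 the fast-switcher population.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n: int
    f_star: float | None = None
    aic_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def p_slow(self) -> float:
        return float(self.weights[0])

    @property
    def p_fast(self) -> float:
        return float(self.weights[-1])

    def pdf(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        out = np.zeros_like(f)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out += w * np.exp(-0.5 * ((f - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return out

    def component_density(self, idx: int, f: np.ndarray) -> np.ndarray:
        """Weighted density w_i * N(f; mu_i, sd_i^2)."""
        f = np.asarray(f, dtype=float)
        w, m, s = self.weights[idx], self.means[idx], self.sds[idx]
        return w * np.exp(-0.5 * ((f - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means_hz": self.means.tolist(),
            "sds_hz": self.sds.tolist(),
            "f_star_hz": self.f_star,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "aic_by_k": {str(k): v for k, v in sorted(self.aic_by_k.items())},
        }


def _validate(values: np.ndarray, min_n: int) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < min_n:
        raise ValueError(f"need at least {min_n} transition frequencies, "
                         f"got {len(values)}")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("transition frequencies must be finite and positive")
    return values


def fit_mixture(f_tau_values: np.ndarray, k: int = 2, min_n: int = 50,
                random_state: int = 0, **em_kwargs) -> MixtureModel:
    """Maximum-likelihood Gaussian mixture of the f_tau sample via EM.

    Components are sorted by mean and, for ``k == 2``, the crossing
    frequency f* is attached.  Raises on too-small samples, non-finite
    input, or EM non-convergence.
    """
    values = _validate(f_tau_values, min_n)
    opts = {**EM_DEFAULTS, **em_kwargs}
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         random_state=random_state, **opts)
    X = values[:, None]
    gm.fit(X)
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in {opts['max_iter']} iterations "
            f"(k={k}, n={len(values)}, lower bound {gm.lower_bound_:.6g})")
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_[order]
    weights = weights / weights.sum()
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(k)[order])
    model = MixtureModel(weights=weights, means=means, sds=sds,
                         log_likelihood=float(gm.score(X) * len(values)),
                         n=len(values))
    model.aic_by_k = {k: float(gm.aic(X))}
    if k == 2:
        try:
            model.f_star = crossing_frequency(model)
        except ValueError:
            # near-identical components (e.g. on unimodal data) have no
            # admissible crossing; classification then needs an explicit f*
            model.f_star = None
    return model


def select_components(f_tau_values: np.ndarray, k_max: int = 5,
                      min_n: int = 50, random_state: int = 0,
                      **em_kwargs) -> int:
    """Number of mixture components minimizing the AIC over k = 1..k_max."""
    aic = aic_trace(f_tau_values, k_max=k_max, min_n=min_n,
                    random_state=random_state, **em_kwargs)
    return min(aic, key=aic.get)


def aic_trace(f_tau_values: np.ndarray, k_max: int = 5, min_n: int = 50,
              random_state: int = 0, **em_kwargs) -> dict[int, float]:
    """AIC for each candidate component count.

    A candidate order whose EM does not converge is scored +inf (an
    over-parameterized k occasionally stalls without affecting the argmin);
    if every candidate fails, the last error propagates.
    """
    values = _validate(f_tau_values, min_n)
    aic: dict[int, float] = {}
    last_error: Exception | None = None
    for k in range(1, k_max + 1):
        try:
            aic[k] = fit_mixture(values, k=k, min_n=min_n,
                                 random_state=random_state,
                                 **em_kwargs).aic_by_k[k]
        except RuntimeError as exc:
            aic[k] = float("inf")
            last_error = exc
    if not np.isfinite(list(aic.values())).any():
        raise last_error  # type: ignore[misc]
    return aic


def crossing_frequency(model: MixtureModel) -> float:
    """Frequency f* where the two weighted component densities intersect.

    Solves the quadratic obtained by equating the weighted Gaussian
    log-densities and keeps the root strictly between the two means.
    """
    if model.k != 2:
        raise ValueError("crossing frequency requires a two-component model")
    (w1, w2) = model.weights
    (m1, m2) = model.means
    (s1, s2) = model.sds
    if np.isclose(m1, m2) and np.isclose(s1, s2):
        raise ValueError("identical components have no crossing")
    # log(w1) - log(s1) - (f-m1)^2 / (2 s1^2) = log(w2) - log(s2) - (f-m2)^2 / (2 s2^2)
    a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    c = (m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2)
         + np.log((w1 * s2) / (w2 * s1)))
    if np.isclose(a, 0.0):
        if np.isclose(b, 0.0):
            raise ValueError("identical components have no crossing")
        roots = np.array([-c / b])
    else:
        disc = b ** 2 - 4 * a * c
        if disc < 0:
            raise ValueError("weighted densities do not intersect")
        roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
    inside = roots[(roots > m1) & (roots < m2)]
    if len(inside) == 0:
        raise ValueError("no crossing strictly between the component means "
                         "(pathological overlap)")
    return float(inside[0])


def classify_waves(waves: list[SlowWave], f_star: float) -> list[SlowWave]:
    """Label each wave: slow switcher iff f_tau < f*, fast otherwise."""
    for w in waves:
        if w.f_tau is None or not np.isfinite(w.f_tau):
            raise ValueError(f"wave at {w.neg_peak_time:.2f}s has no f_tau")
        w.switcher = "slow" if w.f_tau < f_star else "fast"
    return waves


def switcher_probability(waves: list[SlowWave]) -> float:
    """Fraction of labeled waves that are slow switchers."""
    labeled = [w for w in waves if w.switcher in ("slow", "fast")]
    if not labeled:
        raise ValueError("no labeled waves")
    return sum(w.switcher == "slow" for w in labeled) / len(labeled)
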