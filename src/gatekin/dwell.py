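"""Dwell-time distributions: log-binned histograms and exponential mixtures.

Dwell times of a Markov gating model are mixtures of exponentials,
``pdf(t) = sum_i a_i/t_i * exp(-t/t_i)`` with relative areas summing to 1.
Histograms use the log-time / square-root-count display in which each
exponential component appears as a peak at its mean lifetime.

Fitting maximises the dead-time-censored log-likelihood

    sum_j log[ pdf(t_j) / S(t_d) ],   S(t) = sum_i a_i exp(-t/t_i),

i.e. the mixture conditioned on dwells having survived the imposed
resolution t_d.  The single-exponential case has the closed-form MLE
``t_1 = mean(t) - t_d`` (memorylessness); multi-component fits use
multi-start quasi-Newton optimisation on unconstrained parameters
(log-lifetimes, softmax areas).  Model size is chosen by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

__all__ = [
    "DwellHistogram",
    "ExpMixture",
    "ShiftSummary",
    "FitError",
    "build_histogram",
    "fit_mixture",
    "select_components",
    "summarize_shift",
]

MAX_COMPONENTS = 5


class FitError(RuntimeError):
    """Raised when no restart of the mixture optimiser converges.

    The best attempt (if any) is attached as ``.best``.
    """

    def __init__(self, message: str, best: Optional["ExpMixture"] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class DwellHistogram:
    """Log-binned dwell histogram with square-root display ordinate."""

    edges_s: np.ndarray  # strictly increasing, len = n_bins + 1
    counts: np.ndarray
    bins_per_decade: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges_s, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "edges_s", edges)
        object.__setattr__(self, "counts", counts)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if counts.size != edges.size - 1 or np.any(counts < 0):
            raise ValueError("counts must be nonnegative, one per bin")

    @property
    def centers_s(self) -> np.ndarray:
        """Geometric bin centres (log-axis midpoints)."""
        return np.sqrt(self.edges_s[:-1] * self.edges_s[1:])

    @property
    def sqrt_counts(self) -> np.ndarray:
        return np.sqrt(self.counts)


@dataclass(frozen=True)
class ExpMixture:
    """Fitted exponential mixture: areas a_i and mean lifetimes t_i."""

    areas: np.ndarray
    lifetimes_s: np.ndarray
    dead_time_s: float
    log_likelihood: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        t = np.asarray(self.lifetimes_s, dtype=float)
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "lifetimes_s", t)
        if a.size != t.size or a.size < 1:
            raise ValueError("areas and lifetimes must be equal-length, >= 1")
        if np.any(a <= 0) or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("areas must be positive and sum to 1")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("lifetimes must be positive and strictly increasing")

    @property
    def k(self) -> int:
        return int(self.areas.size)

    @property
    def mean_lifetime_s(self) -> float:
        """Area-weighted mean lifetime of the (uncensored) mixture."""
        return float(np.sum(self.areas * self.lifetimes_s))

    def pdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.areas[:, None] / self.lifetimes_s[:, None]
            * np.exp(-t[None, :] / self.lifetimes_s[:, None]),
            axis=0,
        )

    def survival(self, t: float) -> float:
        return float(np.sum(self.areas * np.exp(-t / self.lifetimes_s)))

    def bic(self) -> float:
        p = 2 * self.k - 1
        return -2.0 * self.log_likelihood + p * np.log(max(self.n_obs, 1))


def build_histogram(
    durations: Sequence[float], bins_per_decade: int = 10
) -> DwellHistogram:
    """Tally dwell durations into log-spaced bins spanning [min, max]."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations")
    bad = np.flatnonzero(~(d > 0))
    if bad.size:
        raise ValueError(f"nonpositive duration at index {bad[0]}")
    lo, hi = np.log10(d.min()), np.log10(d.max())
    n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, lo + n_bins / bins_per_decade, n_bins + 1)
    # guard against extreme durations falling a rounding error past an edge
    edges[0] = min(edges[0], d.min())
    edges[-1] = max(edges[-1], d.max())
    counts, _ = np.histogram(d, bins=edges)
    assert counts.sum() == d.size
    return DwellHistogram(edges_s=edges, counts=counts, bins_per_decade=bins_per_decade)


def _censored_nll(theta: np.ndarray, t: np.ndarray, k: int, dead: float) -> float:
    """Negative censored log-likelihood on unconstrained parameters.

    theta = [k-1 area logits (first fixed at 0), k log-lifetimes].
    """
    logits = np.concatenate([[0.0], theta[: k - 1]])
    log_a = logits - logsumexp(logits)
    tau = np.exp(theta[k - 1:])
    # log pdf(t_j) = logsumexp_i [ log a_i - log tau_i - t_j/tau_i ]
    terms = log_a[None, :] - np.log(tau)[None, :] - t[:, None] / tau[None, :]
    ll = np.sum(logsumexp(terms, axis=1))
    if dead > 0:
        log_s = logsumexp(log_a - dead / tau)
        ll -= t.size * log_s
    return -ll


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    logits = np.concatenate([[0.0], theta[: k - 1]])
    return softmax(logits), np.exp(theta[k - 1:])


def fit_mixture(
    durations: Sequence[float],
    k: int,
    dead_time_s: float = 0.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> ExpMixture:
    """Maximum-likelihood exponential mixture fit with dead-time censoring.

    Components are returned sorted by increasing lifetime.  Deterministic
    given ``seed``: restarts perturb quantile-spaced lifetime initials with
    a seeded generator.
    """
    t = np.asarray(durations, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_COMPONENTS:
        raise ValueError(f"k={k} exceeds the identifiable limit ({MAX_COMPONENTS})")
    if np.any(t < dead_time_s - 1e-15):
        raise ValueError("durations below the dead time are not fittable")
    if t.size < 10 * k:
        raise ValueError(f"need at least {10 * k} durations for k={k}, got {t.size}")

    if k == 1:
        # closed form: censored exponential MLE is mean - dead time
        tau = float(np.mean(t) - dead_time_s)
        if tau <= 0:
            raise FitError("sample mean does not exceed the dead time")
        ll = float(-t.size * np.log(tau) - np.sum(t - dead_time_s) / tau)
        return ExpMixture(
            areas=np.array([1.0]),
            lifetimes_s=np.array([tau]),
            dead_time_s=dead_time_s,
            log_likelihood=ll,
            n_obs=t.size,
        )

    rng = np.random.default_rng(seed)
    # quantile-spaced lifetime initials, equal areas
    qs = np.quantile(t, (np.arange(k) + 0.5) / k)
    qs = np.maximum(qs, max(dead_time_s, t.min()) * 1e-3 + 1e-12)
    base_theta = np.concatenate([np.zeros(k - 1), np.log(qs)])

    best = None
    best_nll = np.inf
    any_success = False
    for r in range(n_restarts):
        theta0 = base_theta.copy()
        if r > 0:
            theta0[: k - 1] += rng.normal(0, 0.5, k - 1)
            theta0[k - 1:] += rng.normal(0, 0.5, k)
        res = minimize(
            _censored_nll,
            theta0,
            args=(t, k, dead_time_s),
            method="L-BFGS-B",
            options={"maxiter": 2000},
        )
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best = float(res.fun), res.x.copy()
        any_success = any_success or bool(res.success)

    if best is None:
        raise FitError("mixture fit diverged in every restart")
    areas, taus = _unpack(best, k)
    order = np.argsort(taus)
    mix = ExpMixture(
        areas=areas[order] / areas.sum(),
        lifetimes_s=taus[order],
        dead_time_s=dead_time_s,
        log_likelihood=-best_nll,
        n_obs=t.size,
    )
    if not any_success:
        raise FitError("no restart reported convergence", best=mix)
    return mix


def select_components(
    durations: Sequence[float],
    k_max: int = 3,
    dead_time_s: float = 0.0,
    seed: int = 0,
) -> ExpMixture:
    """Fit k = 1..k_max mixtures and return the BIC-optimal one.

    Ties (and fits that fail outright) resolve toward smaller k.
    """
    if k_max > MAX_COMPONENTS:
        raise ValueError(f"k_max exceeds the identifiable limit ({MAX_COMPONENTS})")
    t = np.asarray(durations, dtype=float)
    best: Optional[ExpMixture] = None
    for k in range(1, k_max + 1):
        if t.size < 10 * k:
            break
        try:
            mix = fit_mixture(t, k, dead_time_s=dead_time_s, seed=seed)
        except FitError:
            continue
        if best is None or mix.bic() < best.bic():
            best = mix
    if best is None:
        raise FitError("no component count could be fitted")
    return best


@dataclass(frozen=True)
class ShiftSummary:
    """Per-component changes between a control and a treated mixture.

    Components are matched by lifetime rank; each matched pair reports the
    treated/control lifetime ratio and the treated-minus-control area
    difference.  Surplus components on either side are listed unmatched.
    """

    lifetime_ratios: np.ndarray
    area_differences: np.ndarray
    control_lifetimes_s: np.ndarray
    treated_lifetimes_s: np.ndarray
    unmatched_control: np.ndarray = field(default_factory=lambda: np.array([]))
    unmatched_treated: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_matched(self) -> int:
        return int(self.lifetime_ratios.size)


def summarize_shift(control: ExpMixture, treated: ExpMixture) -> ShiftSummary:
    """Rank-matched component comparison between two fitted mixtures."""
    m = min(control.k, treated.k)
    return ShiftSummary(
        lifetime_ratios=treated.lifetimes_s[:m] / control.lifetimes_s[:m],
        area_differences=treated.areas[:m] - control.areas[:m],
        control_lifetimes_s=control.lifetimes_s[:m],
        treated_lifetimes_s=treated.lifetimes_s[:m],
        unmatched_control=control.lifetimes_s[m:],
        unmatched_treated=treated.lifetimes_s[m:],
    )
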