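"""Monte-Carlo ensembles of emptying trajectories and their summaries.

An :class:`Ensemble` is ``n`` independent realizations of the jump process
on a shared grid, member ``i`` drawn from the deterministic sub-stream
seeded by ``(seed, i)``. Summaries are pointwise in time: empirical
percentile envelopes (5th/95th by default, i.e. a two-sided 90% band), the
ensemble mean, and the marginal distribution at a fixed time. Percentiles
use linear interpolation between order statistics (numpy's default), a
convention fixed here so bands are bit-reproducible.

For even ``beta`` the transform depends on the path only through ``|W|``,
which yields a closed-form median for ``X(t)`` (used as a test oracle) and
makes the Monte-Carlo median of ``S(t)`` monotone in ``alpha`` pathwise —
the property the median-targeted calibration relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    CalibrationError,
    InvalidInputError,
    InvalidProtocolError,
    UnsupportedParameterError,
)
from .grid import TimeGrid
from .stochastic import (
    SGEMParams,
    member_seed_sequence,
    power_exponential_transform,
    running_minimum,
    simulate_wiener,
)

__all__ = [
    "Ensemble",
    "EnvelopeBands",
    "simulate_ensemble",
    "pointwise_percentiles",
    "ensemble_mean",
    "marginal_at",
    "analytic_median_x",
    "calibrate_alpha_for_median",
    "GAUSSIAN_MEDIAN_ABS",
]

#: Median of |Z| for Z standard normal: the 75th-percentile point of Phi.
GAUSSIAN_MEDIAN_ABS = 0.6744897501960817


@dataclass(frozen=True)
class Ensemble:
    """A matrix of residual-fraction trajectories, one row per member."""

    params: SGEMParams
    grid: TimeGrid
    values: np.ndarray  # shape (n, len(grid))
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.grid) or v.shape[0] < 1:
            raise InvalidInputError(
                f"ensemble values must be (n >= 1, {len(self.grid)}), got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EnvelopeBands:
    """Pointwise percentile curves; ``curves[i]`` belongs to ``probs[i]``."""

    grid: TimeGrid
    probs: tuple[float, ...]
    curves: np.ndarray  # shape (len(probs), len(grid))

    def curve(self, prob: float) -> np.ndarray:
        """The band for one requested percentile level."""
        for p, c in zip(self.probs, self.curves):
            if p == prob:
                return c
        raise KeyError(f"no band computed for percentile {prob}")

    def interp(self, prob: float, t: np.ndarray) -> np.ndarray:
        """Band value at arbitrary times, linear in t between grid points."""
        return np.interp(t, self.grid.times, self.curve(prob))


def simulate_ensemble(
    params: SGEMParams,
    n: int = 2000,
    t_end: float = 240.0,
    dt: float = 0.01,
    seed: int = 0,
) -> Ensemble:
    """Simulate ``n`` independent trajectories with per-member sub-seeds."""
    if n < 1:
        raise InvalidProtocolError(f"ensemble size must be >= 1, got {n}")
    grid = TimeGrid(t_end, dt)
    values = np.empty((n, len(grid)))
    for i in range(n):
        w = simulate_wiener(t_end, dt, member_seed_sequence(seed, i))
        s = running_minimum(power_exponential_transform(w, params))
        values[i] = s.values
    return Ensemble(params, grid, values, int(seed))


def pointwise_percentiles(
    e: Ensemble, probs: tuple[float, ...] = (5.0, 95.0)
) -> EnvelopeBands:
    """Empirical percentiles of the member values at every grid point.

    Linear interpolation between order statistics; levels must lie strictly
    inside (0, 100).
    """
    probs = tuple(float(p) for p in probs)
    if not probs or any(not (0.0 < p < 100.0) for p in probs):
        raise InvalidInputError(f"percentile levels must lie in (0, 100), got {probs}")
    curves = np.percentile(e.values, probs, axis=0, method="linear")
    return EnvelopeBands(e.grid, probs, np.atleast_2d(curves))


def ensemble_mean(e: Ensemble) -> np.ndarray:
    """Arithmetic mean of S across members at each grid point."""
    return e.values.mean(axis=0)


def marginal_at(e: Ensemble, t_star: float) -> np.ndarray:
    """One S value per member, read at the last grid point at or before t_star."""
    return e.values[:, e.grid.index_at_or_before(t_star)].copy()


def analytic_median_x(t: float, params: SGEMParams) -> float:
    """Exact median of ``X(t)`` for even beta.

    For even beta, ``W(t)^beta = |W(t)|^beta`` is increasing in ``|W(t)|``,
    whose median is ``m sqrt(t)`` with ``m = 0.6744898`` (the 75th-percentile
    point of the standard Gaussian). Hence

        median X(t) = exp(-alpha * t**(beta/2) * m**beta).
    """
    if params.beta % 2 != 0:
        raise UnsupportedParameterError(
            "analytic median is only available for even beta"
        )
    m = GAUSSIAN_MEDIAN_ABS
    return float(np.exp(-params.alpha * t ** (params.beta / 2) * m**params.beta))


def _running_max_pow(
    beta: int, t_star: float, n: int, dt: float, seed: int
) -> np.ndarray:
    """Per-member running maximum of W^beta up to t_star (even beta).

    These samples determine S(t_star) = exp(-alpha * M_i) for every alpha at
    once, so a calibration can rescan alpha without re-simulating paths.
    """
    out = np.empty(n)
    for i in range(n):
        w = simulate_wiener(t_star, dt, member_seed_sequence(seed, i))
        out[i] = np.max(w.values[1:] ** beta)
    return out


def calibrate_alpha_for_median(
    beta: int,
    t_star: float = 150.0,
    target_median: float = 0.5,
    n: int = 2000,
    t_end: float = 240.0,
    dt: float = 0.01,
    seed: int = 0,
    tol: float = 1e-3,
    alpha_bracket: tuple[float, float] = (1e-12, 1e2),
    max_iter: int = 200,
) -> float:
    """Find alpha so the Monte-Carlo median of S(t_star) hits a target.

    Bisection on log-alpha. Valid for even beta, where S is pathwise
    non-increasing in alpha, so the Monte-Carlo median (over a fixed seed
    set) is monotone and the bisection converges. The per-iteration median
    is evaluated on cached running maxima of ``W^beta`` from the same
    member sub-streams — identical to re-simulating with those seeds.

    Parameters
    ----------
    target_median
        Desired median of S(t_star), in (0, 1]. A target of 1 returns
        alpha = 0 (the only value that keeps S identically 1).
    tol
        Stop when the Monte-Carlo median is within ``tol`` of the target.
    """
    params_check = SGEMParams(alpha=0.0, beta=beta)
    if params_check.beta % 2 != 0:
        raise UnsupportedParameterError("calibration requires even beta")
    if not (0.0 < target_median <= 1.0):
        raise CalibrationError(f"target median must be in (0, 1], got {target_median}")
    if t_star <= 0 or t_star > t_end:
        raise CalibrationError(f"t_star={t_star} outside (0, t_end={t_end}]")
    if target_median == 1.0:
        return 0.0

    maxima = _running_max_pow(params_check.beta, t_star, n, dt, int(seed))
    med_max = np.median(maxima)

    def median_s(alpha: float) -> float:
        return float(np.median(np.exp(-alpha * maxima)))

    lo, hi = alpha_bracket
    if median_s(lo) < target_median or median_s(hi) > target_median:
        raise CalibrationError(
            f"target median {target_median} not bracketed by alpha in "
            f"[{lo}, {hi}] (median at bounds: {median_s(lo):.4g}, {median_s(hi):.4g})"
        )
    log_lo, log_hi = np.log(lo), np.log(hi)
    for _ in range(max_iter):
        log_mid = 0.5 * (log_lo + log_hi)
        alpha = float(np.exp(log_mid))
        med = median_s(alpha)
        if abs(med - target_median) <= tol:
            return alpha
        if med > target_median:  # emptying too slow: increase alpha
            log_lo = log_mid
        else:
            log_hi = log_mid
    # interval exhausted; return the closed-form solution on the cached set
    return float(-np.log(target_median) / med_max)
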