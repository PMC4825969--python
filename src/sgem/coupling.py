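"""Jejunal glucose delivery driven by the emptying spurts.

Each spurt instantaneously transfers a fraction ``u_j`` of the meal's
glucose ``M0`` to the jejunum, which drains with first-order rate ``kGJ``:

    dJ/dt = -kGJ * J + M0 * sum_j u_j delta(t - t_j).

Between impulses the equation is solved exactly — piecewise exponential
decay, no numerical ODE error and no impulse smearing. J is taken
right-continuous at spurt times: the value at ``t_j`` includes the jump.

Units of ``M0`` (mass) and ``kGJ`` (per minute) are the caller's; the module
only guarantees dimensional consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, RangeError
from .grid import TimeGrid
from .stochastic import SpurtSequence

__all__ = [
    "CouplingParams",
    "JejunumTrajectory",
    "jejunum_response",
    "delivered_mass",
    "outflow_integral",
]


@dataclass(frozen=True)
class CouplingParams:
    """Meal glucose content M0 (mass) and jejunal outflow rate kGJ (1/min)."""

    M0: float = 100.0
    kGJ: float = 0.05

    def __post_init__(self) -> None:
        if self.M0 < 0 or self.kGJ < 0:
            raise InvalidInputError("M0 and kGJ must be non-negative")


@dataclass(frozen=True)
class JejunumTrajectory:
    """Jejunal glucose amount J per grid point; J(0) = 0, J >= 0."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.grid):
            raise InvalidInputError("J trajectory length does not match its grid")
        object.__setattr__(self, "values", v)


def _check_spurts_in_range(spurts: SpurtSequence, grid: TimeGrid) -> None:
    if len(spurts) and (spurts.times[0] < 0 or spurts.times[-1] > grid.t_end + 0.5 * grid.dt):
        raise RangeError(
            f"spurt at t={spurts.times[-1]} outside grid range [0, {grid.t_end}]"
        )


def jejunum_response(
    spurts: SpurtSequence, cp: CouplingParams, grid: TimeGrid
) -> JejunumTrajectory:
    """Exact jejunal glucose trajectory on the grid.

    Walks the grid once, decaying the current amount in closed form over
    each sub-interval and adding ``M0 * u_j`` at every spurt time (spurt
    times need not coincide with grid points). Right-continuous: a spurt at
    a grid time is included in that grid point's value.
    """
    _check_spurts_in_range(spurts, grid)
    times = grid.times
    out = np.empty(len(times))
    out[0] = 0.0
    j = 0.0
    t_cur = 0.0
    ev = 0
    n_ev = len(spurts)
    # spurts exactly at t=0 cannot occur (times > 0 by invariant)
    for i, t_next in enumerate(times):
        if i == 0:
            continue
        while ev < n_ev and spurts.times[ev] <= t_next:
            te = spurts.times[ev]
            j *= np.exp(-cp.kGJ * (te - t_cur))
            j += cp.M0 * spurts.amounts[ev]
            t_cur = te
            ev += 1
        j *= np.exp(-cp.kGJ * (t_next - t_cur))
        t_cur = t_next
        out[i] = j
    return JejunumTrajectory(grid, out)


def delivered_mass(spurts: SpurtSequence, M0: float) -> float:
    """Total glucose mass delivered to the jejunum: ``M0 * sum(u_j)``."""
    return float(M0) * spurts.total


def outflow_integral(
    spurts: SpurtSequence, cp: CouplingParams, t_end: float
) -> float:
    """Closed-form ``integral_0^t_end J dt`` over the piecewise segments.

    With kGJ > 0 each segment contributes ``J0 (1 - exp(-kGJ h)) / kGJ``;
    with kGJ = 0 it contributes ``J0 h``. Together with the final amount
    this yields the mass balance
    ``M0 sum(u_j) = J(t_end) + kGJ * integral J dt`` exactly.
    """
    if len(spurts) and spurts.times[-1] > t_end:
        raise RangeError("spurt beyond t_end")
    k = cp.kGJ
    total = 0.0
    j = 0.0
    t_cur = 0.0
    boundaries = list(spurts.times) + [t_end]
    amounts = list(spurts.amounts) + [0.0]
    for tb, u in zip(boundaries, amounts):
        h = tb - t_cur
        if h > 0:
            total += j * (1.0 - np.exp(-k * h)) / k if k > 0 else j * h
            j *= np.exp(-k * h)
        j += cp.M0 * u
        t_cur = tb
    return float(total)
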