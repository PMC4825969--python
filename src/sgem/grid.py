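"""Uniform time grids and simulation protocols.

Every trajectory in the package lives on a :class:`TimeGrid`: a uniform
discretization ``t_i = i * dt`` for ``i = 0..N`` with ``N = round(t_end/dt)``.
The default protocol (240 minutes, 0.01-minute step, 2000 ensemble members)
matches the simulation design the model was originally studied under.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidProtocolError, RangeError

__all__ = ["TimeGrid", "SimulationProtocol"]


@dataclass(frozen=True)
class TimeGrid:
    """A uniform time grid on [0, t_end] in minutes.

    Parameters
    ----------
    t_end
        Horizon in minutes; must be positive.
    dt
        Step in minutes; must be positive and no larger than ``t_end``.
    """

    t_end: float
    dt: float

    def __post_init__(self) -> None:
        if not (self.t_end > 0):
            raise InvalidProtocolError(f"t_end must be positive, got {self.t_end}")
        if not (self.dt > 0):
            raise InvalidProtocolError(f"dt must be positive, got {self.dt}")
        if self.dt > self.t_end:
            raise InvalidProtocolError(
                f"dt={self.dt} exceeds horizon t_end={self.t_end}"
            )

    @property
    def n_steps(self) -> int:
        """Number of increments N; the grid has N + 1 points."""
        return int(round(self.t_end / self.dt))

    @property
    def times(self) -> np.ndarray:
        """Grid points ``0, dt, 2 dt, ..., N dt`` as a float array."""
        return np.arange(self.n_steps + 1) * self.dt

    def __len__(self) -> int:
        return self.n_steps + 1

    def index_at_or_before(self, t: float) -> int:
        """Index of the last grid point at or before time ``t``.

        Raises :class:`RangeError` if ``t`` lies outside ``[0, t_end]``
        (a half-step slack absorbs float rounding at the right endpoint).
        """
        if t < 0 or t > self.t_end + 0.5 * self.dt:
            raise RangeError(f"time {t} outside grid range [0, {self.t_end}]")
        return min(int(np.floor(t / self.dt + 1e-9)), self.n_steps)


@dataclass(frozen=True)
class SimulationProtocol:
    """Ensemble simulation settings: horizon, step, size, master seed."""

    t_end: float = 240.0
    dt: float = 0.01
    n_paths: int = 2000
    seed: int = 0
    grid: TimeGrid = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", TimeGrid(self.t_end, self.dt))
        if self.n_paths < 1:
            raise InvalidProtocolError(f"n_paths must be >= 1, got {self.n_paths}")
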