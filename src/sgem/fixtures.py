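"""Synthetic observed-profile generators.

Real scintigraphic studies observe each subject at a handful of time points
over a few hours. These generators emulate that design with the statistical
structure the stochastic model assumes: each synthetic subject is one
independent realization of the jump process, sampled at sparse observation
times, with optional additive Gaussian observation noise on the fraction
scale. The noise model is a fixture convention — the field reports no
observation-error model for scintigraphy — and the default design (19
subjects, 7 points over 240 min) mirrors the published study scale.

Deterministic-model fixtures (closed-form curve + noise) support the
parameter-recovery tests of the fitting routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compare import GEProfile
from .deterministic import DeterministicModelSpec, evaluate_model
from .errors import InvalidInputError, RangeError
from .grid import SimulationProtocol
from .stochastic import (
    SGEMParams,
    member_seed_sequence,
    power_exponential_transform,
    running_minimum,
    simulate_wiener,
)

__all__ = ["FixtureSpec", "generate_profiles", "generate_deterministic_profiles",
           "DEFAULT_OBS_TIMES"]

#: Sparse clinical-style sampling design: 7 points over 4 hours.
DEFAULT_OBS_TIMES = (10.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Design of a synthetic observed-profile dataset."""

    params: SGEMParams = field(default_factory=SGEMParams)
    n_subjects: int = 19
    obs_times: tuple[float, ...] = DEFAULT_OBS_TIMES
    noise_sd: float = 0.0
    clip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError(f"n_subjects must be >= 1, got {self.n_subjects}")
        ot = tuple(float(t) for t in self.obs_times)
        if not ot or ot[0] < 0 or any(b <= a for a, b in zip(ot, ot[1:])):
            raise InvalidInputError("obs_times must be non-negative and strictly increasing")
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        object.__setattr__(self, "obs_times", ot)


def generate_profiles(
    fs: FixtureSpec, protocol: SimulationProtocol
) -> list[GEProfile]:
    """One independent jump-process realization per subject, sampled sparsely.

    Subject ``i`` uses the deterministic sub-stream ``(seed, i)`` both for
    its trajectory and (a child stream) for its observation noise, so
    subjects are independent and the whole dataset reproduces under the
    seed. With ``clip`` set, noisy values are truncated at 0.
    """
    if fs.obs_times[-1] > protocol.t_end:
        raise RangeError(
            f"observation time {fs.obs_times[-1]} beyond horizon {protocol.t_end}"
        )
    obs = np.asarray(fs.obs_times)
    idx = [protocol.grid.index_at_or_before(t) for t in obs]
    profiles = []
    for i in range(fs.n_subjects):
        ss = member_seed_sequence(fs.seed, i)
        path_seed, noise_seed = ss.spawn(2)
        w = simulate_wiener(protocol.t_end, protocol.dt, path_seed)
        s = running_minimum(power_exponential_transform(w, fs.params))
        values = s.values[idx].astype(float)
        if fs.noise_sd > 0:
            values = values + np.random.default_rng(noise_seed).normal(
                0.0, fs.noise_sd, size=len(values)
            )
        if fs.clip:
            values = np.maximum(values, 0.0)
        profiles.append(GEProfile(f"S{i + 1:02d}", obs.copy(), values))
    return profiles


def generate_deterministic_profiles(
    spec: DeterministicModelSpec,
    obs_times=DEFAULT_OBS_TIMES,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject_id: str = "D01",
    clip: bool = False,
) -> GEProfile:
    """Closed-form curve sampled at obs_times, plus optional Gaussian noise.

    With ``clip`` set, noisy values are truncated at 0 (profiles require
    non-negative fractions, and additive noise near full emptying can dip
    below zero).
    """
    t = np.asarray(obs_times, dtype=float)
    y = np.asarray(evaluate_model(spec, t), dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(np.random.SeedSequence(int(seed))).normal(
            0.0, noise_sd, size=len(t)
        )
    if clip:
        y = np.maximum(y, 0.0)
    return GEProfile(subject_id, t, y)
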