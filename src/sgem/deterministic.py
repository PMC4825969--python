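"""Classical deterministic gastric-emptying curve models.

The literature describes the residual meal fraction y(t) with a small set of
closed forms plus one mechanistic ODE:

==========================  ====================================================
family                      form (fraction scale)
==========================  ====================================================
mono_exponential            y = C exp(-k t)                        (C default 1)
lag_exponential             y = min(1, exp(-k (t - t_lag)))
weibull                     y = exp(-(t / eta)**beta_shape)
double_weibull              y = [(100-H) exp(-(t/eta1)**beta1)
                                 + H exp(-(t/eta2)**beta2)] / 100
modified_power_exponential  y = 1 - (1 - exp(-k t))**beta_shape
stubbs_ode                  dy/dt = -k y**p (1 - (v/y)**n)      (y in ml)
==========================  ====================================================

Families historically printed in percent (lag, Weibull, double Weibull) are
normalized here so every closed form returns a fraction. The lag model
formally exceeds 100% before t_lag; the returned fraction is clamped at 1
there. The power-exponential form exp(-(k t)**beta) is the Weibull family
with eta = 1/k.

The mechanistic ODE (elastic stomach wall + Poiseuille outflow) tracks
volume in ml, not meal fraction; ``v`` is the resting stomach volume and
``y = v`` is its fixed point. Published exponents are read as p = 4/3 and
n = 1/2 (the source prints them garbled); both are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import InvalidInputError, UnsupportedParameterError
from .grid import TimeGrid

__all__ = [
    "FAMILIES",
    "DeterministicModelSpec",
    "ModelFit",
    "evaluate_model",
    "integrate_stubbs",
    "fit_model",
]

FAMILIES = (
    "mono_exponential",
    "lag_exponential",
    "weibull",
    "double_weibull",
    "modified_power_exponential",
    "stubbs_ode",
)

# family -> (fitted parameter names, lower bounds, upper bounds)
_FIT_SPACE: dict[str, tuple[tuple[str, ...], tuple[float, ...], tuple[float, ...]]] = {
    "mono_exponential": (("k",), (1e-8,), (10.0,)),
    "lag_exponential": (("k", "t_lag"), (1e-8, 0.0), (10.0, 500.0)),
    "weibull": (("eta", "beta_shape"), (1e-3, 0.05), (1e5, 20.0)),
    "double_weibull": (
        ("H", "eta1", "beta1", "eta2", "beta2"),
        (0.0, 1e-3, 0.05, 1e-3, 0.05),
        (100.0, 1e5, 20.0, 1e5, 20.0),
    ),
    "modified_power_exponential": (("k", "beta_shape"), (1e-8, 0.05), (10.0, 50.0)),
}

_STUBBS_DEFAULTS = {"k": 0.001, "p": 4.0 / 3.0, "n": 0.5, "v": 28.0, "y0": 280.0}


@dataclass(frozen=True)
class DeterministicModelSpec:
    """One model family plus its named parameter values."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UnsupportedParameterError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        p = dict(self.params)
        if self.family == "stubbs_ode":
            p = {**_STUBBS_DEFAULTS, **p}
            if p["y0"] >= 300.0:
                raise UnsupportedParameterError(
                    f"stomach-volume model is stated valid for y0 < 300 ml, got {p['y0']}"
                )
            if p["y0"] <= 0 or p["v"] <= 0:
                raise InvalidInputError("y0 and v must be positive volumes")
        for name in ("k", "eta", "eta1", "eta2", "beta_shape", "beta1", "beta2"):
            if name in p and p[name] <= 0:
                raise UnsupportedParameterError(f"{name} must be > 0, got {p[name]}")
        if "H" in p and not (0.0 <= p["H"] <= 100.0):
            raise UnsupportedParameterError(f"H must lie in [0, 100], got {p['H']}")
        object.__setattr__(self, "params", p)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


@dataclass(frozen=True)
class ModelFit:
    """Result of a least-squares fit: best spec, SSE, and convergence flag."""

    spec: DeterministicModelSpec
    sse: float
    n_obs: int
    converged: bool

    @property
    def aic(self) -> float:
        """Gaussian-residual AIC, reported as a convenience only."""
        k = len(_FIT_SPACE[self.spec.family][0])
        n = self.n_obs
        return n * np.log(max(self.sse, 1e-300) / n) + 2 * k


def _eval_family(family: str, p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    if family == "mono_exponential":
        return p.get("C", 1.0) * np.exp(-p["k"] * t)
    if family == "lag_exponential":
        return np.minimum(1.0, np.exp(-p["k"] * (t - p["t_lag"])))
    if family == "weibull":
        return np.exp(-((t / p["eta"]) ** p["beta_shape"]))
    if family == "double_weibull":
        return (
            (100.0 - p["H"]) * np.exp(-((t / p["eta1"]) ** p["beta1"]))
            + p["H"] * np.exp(-((t / p["eta2"]) ** p["beta2"]))
        ) / 100.0
    if family == "modified_power_exponential":
        return 1.0 - (1.0 - np.exp(-p["k"] * t)) ** p["beta_shape"]
    raise UnsupportedParameterError(f"no closed form for family {family!r}")


def evaluate_model(spec: DeterministicModelSpec, t) -> np.ndarray | float:
    """Closed-form residual fraction at time(s) ``t`` (minutes).

    Percent-scale families are divided by 100, so every family returns a
    fraction. The mechanistic ODE has no closed form; use
    :func:`integrate_stubbs` for it.
    """
    if spec.family == "stubbs_ode":
        raise UnsupportedParameterError(
            "stubbs_ode has no closed form; use integrate_stubbs()"
        )
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("evaluation times must be non-negative")
    out = _eval_family(spec.family, spec.params, arr)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def integrate_stubbs(
    spec: DeterministicModelSpec,
    grid: TimeGrid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the elastic-stomach outflow ODE on the grid; returns ml.

    dy/dt = -k y**p (1 - (v/y)**n). The resting volume ``y = v`` is a fixed
    point, so solutions starting above it decrease monotonically toward it
    and never cross. Solved with an adaptive RK45 at tight tolerances and
    read off at the grid points.
    """
    if spec.family != "stubbs_ode":
        raise UnsupportedParameterError("integrate_stubbs requires family 'stubbs_ode'")
    k, p, n, v, y0 = (spec.params[s] for s in ("k", "p", "n", "v", "y0"))

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        yy = np.maximum(y, 1e-12)
        return -k * yy**p * (1.0 - (v / yy) ** n)

    sol = solve_ivp(
        rhs,
        (0.0, grid.t_end),
        [y0],
        t_eval=grid.times,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise InvalidInputError(f"stomach-volume ODE integration failed: {sol.message}")
    y = sol.y[0]
    if np.any(y <= 0):
        raise InvalidInputError("integration produced non-positive volume")
    return y


def _random_start(
    rng: np.random.Generator,
    init: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    jitter = init * np.exp(rng.normal(0.0, 0.7, size=init.shape))
    return np.clip(jitter, lo, hi)


def fit_model(
    family: str,
    profile,
    init: Mapping[str, float] | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> ModelFit:
    """Nonlinear least squares of one closed-form family to one profile.

    Multi-start (default 10 starts: the supplied or default initial guess
    plus seeded log-normal jitters of it) with box constraints, to reduce
    the risk of a local minimum. ``profile`` is any object with ``times``
    and ``fractions`` arrays (see :class:`sgem.compare.GEProfile`).

    The mechanistic ODE family is not fittable here: it predicts stomach
    volume in ml, and residuals against fraction-of-meal observations would
    be dimensionally meaningless.
    """
    if family == "stubbs_ode":
        raise UnsupportedParameterError(
            "stubbs_ode predicts volume (ml), not meal fraction; "
            "fit_model covers the closed-form fraction-scale families"
        )
    if family not in _FIT_SPACE:
        raise UnsupportedParameterError(f"unknown family {family!r}")
    names, lo, hi = _FIT_SPACE[family]
    t = np.asarray(profile.times, dtype=float)
    y = np.asarray(profile.fractions, dtype=float)
    if len(t) < len(names):
        raise InvalidInputError(
            f"need at least {len(names)} observations to fit {family}, got {len(t)}"
        )

    defaults = {
        "k": 0.05, "t_lag": 5.0, "eta": 60.0, "beta_shape": 1.0,
        "H": 50.0, "eta1": 40.0, "beta1": 1.0, "eta2": 120.0, "beta2": 1.5,
    }
    start = np.array([(init or {}).get(nm, defaults[nm]) for nm in names])
    lo_a, hi_a = np.asarray(lo), np.asarray(hi)
    start = np.clip(start, lo_a, hi_a)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = dict(zip(names, theta))
        return _eval_family(family, p, t) - y

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF17)))
    best_theta, best_sse, converged = start, np.inf, False
    for s in range(max(1, n_starts)):
        x0 = start if s == 0 else _random_start(rng, start, lo_a, hi_a)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo_a, hi_a), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if sse < best_sse:
            best_theta, best_sse, converged = res.x, sse, bool(res.success)
    spec = DeterministicModelSpec(family, dict(zip(names, map(float, best_theta))))
    return ModelFit(spec=spec, sse=best_sse, n_obs=len(t), converged=converged)
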