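# Methods

## The stochastic emptying process

The model treats the fractional residual meal content of the stomach,
`S(t)`, as a monotone jump process driven by standard Brownian motion
`W(t)`:

    X(t) = exp(-alpha * W(t)^beta)
    S(t) = min(1, min_{0 < s <= t} X(s))

`S(0) = 1` (the whole meal is present at ingestion), `S` never increases,
and every strict decrease is an emptying spurt: an instantaneous expulsion
of chyme through the transiently opening pylorus. The spurt sequence
`{(t_j, u_j)}` — jump times and sizes — is recovered from `S` by scanning
for strict decreases; the sizes telescope exactly,
`sum_j u_j = 1 - S(t_end)`.

The model makes no claim about the microscopic physiology of antral
contractions; it is the simplest process that is (a) bounded in `(0, 1]`,
(b) non-increasing with piecewise-constant plateaus between random jumps,
and (c) rich enough that one parameter pair generates the between-subject
spread seen in real scintigraphic series. An exponential-like mean decline
emerges because large excursions of `X` below its past minimum are most
probable early on.

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `alpha` | exponent scale; larger ⇒ faster emptying | — | 1e-6 |
| `beta`  | integer power on `W`; larger ⇒ heavier weighting of large excursions | — | 6 |
| `t_end` | simulation horizon | min | 240 |
| `dt`    | grid step | min | 0.01 |
| `n_paths` | ensemble size | — | 2000 |

The defaults are the combination whose 90% envelope brackets published
scintigraphic profiles of healthy subjects, at the protocol those envelope
studies used. `beta` is restricted to positive integers: for non-integer
`beta` and negative `W`, `W^beta` is undefined over the reals, so such
values are rejected rather than silently patched.

### Discretization and conventions

- **Wiener path.** Increments are exact `N(0, dt)` draws, so the marginal
  law of `W` at grid points carries no discretization error. The running
  minimum, however, is taken over grid points only; with `dt = 0.01` min
  the unobserved intra-step minima are negligible at the horizons studied.
- **Open-interval minimum.** The defining minimum runs over `0 < s <= t`.
  Discretely, `S(t_k)` is the minimum of `X` over grid points `1..k`
  (including the current point) and `S(0) = 1`; since `X(s) -> 1` as
  `s -> 0+`, the infimum over `(0, t)` never exceeds 1, so defining
  `S(0) = 1` is exact. Whether the continuous-time endpoint `s = t` is
  included is immaterial on a grid and the inclusive convention is used.
- **Clamp at 1.** For odd `beta`, negative `W` gives `X > 1`; a residual
  fraction cannot exceed 1, so `S` is the prefix minimum capped at 1. For
  even `beta` the cap is inert.
- **Spurt time stamp.** A spurt is recorded at the first grid point where
  the lower value holds (the jump's right endpoint); `S` is treated as
  right-continuous.
- **Underflow.** Mathematically `S > 0` always. In double precision
  `exp(-alpha W^beta)` underflows to 0 once `alpha W^beta > ~745` (routine
  at `alpha = 1e-4, beta = 6`, occasional at `1e-6`); the value 0.0 is then
  carried honestly rather than clamped to a fake epsilon. Conservation
  identities are unaffected.
- **RNG.** All randomness flows from numpy `SeedSequence`/PCG64. Ensemble
  member `i` under master seed `s` uses the sub-stream seeded by `(s, i)`;
  fixture subjects additionally spawn a child stream for observation
  noise. Identical seeds give bit-identical output everywhere.

## Ensemble summaries

Envelopes are **pointwise in time**: at each grid point the empirical
percentiles (default 5th/95th — a two-sided 90% band) of the member values,
using linear interpolation between order statistics (numpy's default rule,
fixed here so bands are bit-reproducible). These are not simultaneous
path bands; the in-sample fraction of member values strictly outside the
band at any time point is at most `10% + 2/n` by construction.
`marginal_at` reads members at the last grid point at or below the query
time (≤ `dt` of snapping error).

**Calibration.** `calibrate_alpha_for_median` bisects on `log(alpha)` until
the Monte-Carlo median of `S(t*)` over a fixed seed set reaches a target.
For even `beta`, `S` is pathwise non-increasing in `alpha`
(`W^beta >= 0`), so the fixed-seed median is monotone in `alpha` and the
bisection is valid. Each iteration evaluates the median on cached running
maxima of `W^beta` from the same member sub-streams — algebraically
identical to re-simulating those members, because
`S(t*) = exp(-alpha * max_{s<=t*} W(s)^beta)`. The default bracket is
`alpha ∈ [1e-12, 1e2]`, comfortably containing every regime from
effectively-no-emptying to near-instant emptying; an unreachable target
raises rather than returning a boundary value.

**Closed-form oracle.** For even `beta`, `X(t)` is a decreasing function of
`|W(t)|`, whose median is `m * sqrt(t)` with `m = Phi^{-1}(0.75) ≈
0.6744898`. Hence `median X(t) = exp(-alpha t^{beta/2} m^beta)` — an exact
oracle the test suite checks the simulator against. Note the sampling
error of an empirical median at `n = 2000` is ≈ 0.034 at
`(alpha=1e-6, beta=6, t=150)`, so single-seed Monte-Carlo medians scatter
around the closed form on that scale.

## Meal coupling

The jejunal glucose compartment `dJ/dt = -kGJ J + M0 Σ u_j δ(t - t_j)` is
solved exactly: between impulses `J` decays as `J0 exp(-kGJ h)`, and at
each spurt `M0 u_j` is added (right-continuous convention — the value at
`t_j` includes the jump). No ODE solver touches the deltas, so there is no
impulse smearing; the mass balance
`M0 Σ u_j = J(t_end) + kGJ ∫ J dt` (integral in closed form per segment)
holds to accumulated rounding (~1e-12 relative over 24k grid points).
Units of `M0` (mass) and `kGJ` (1/min) are the caller's; only dimensional
consistency is enforced. The downstream plasma glucose/insulin dynamics
are deliberately out of scope — the package stops at the jejunal forcing
function.

## Deterministic catalogue

Families historically written in percent (lag-exponential, Weibull,
double-Weibull) are normalized to fractions so every family returns values
on one scale. Specifics:

- the lag-exponential form exceeds 100% before `t_lag`; the returned
  fraction is clamped at 1 there (a lag phase, not super-filling);
- `C e^{-kt}` is the mono-exponential with an optional amplitude `C`, and
  `e^{-(kt)^beta}` is the Weibull family with `eta = 1/k` — both
  equivalences are asserted in tests rather than duplicated as families;
- the elastic-stomach ODE `dy/dt = -k y^p (1 - (v/y)^n)` uses `p = 4/3`,
  `n = 1/2`, `v = 28` ml by default. The published exponents are printed
  garbled in the source literature ("p=43, n=12"); the 4/3 and 1/2 reading
  is an interpretation, and all three values are overridable. `y = v` is a
  fixed point; integration uses adaptive RK45 at `rtol 1e-10 / atol 1e-12`.
  The model is stated valid for `y(0) < 300` ml and larger initial volumes
  are rejected.

**Fitting** is bounded nonlinear least squares (trust-region reflective)
with multi-start: the supplied or default initial guess plus nine seeded
log-normal jitters of it. Bounds enforce positivity and `H ∈ [0, 100]`.
The ODE family is excluded from fitting: it predicts volume in ml, so
residuals against fraction-of-meal profiles would be dimensionally
meaningless. A Gaussian-residual AIC is reported per fit as a convenience,
not as a model-selection study.

## Coverage and ranking

An observation is outside a band iff strictly below the lower or strictly
above the upper curve at its time (curves linearly interpolated between
grid points; a point exactly on a curve is inside). Observed fractions
above 1 are compared as-is, not clipped. `rank_parameter_grid` simulates
one ensemble per `(alpha, beta)` candidate, builds the two-sided band at
the nominal level, and sorts by `|fraction_outside - (1 - nominal)|`, ties
broken by `(alpha, beta)` for determinism.

## Synthetic fixtures

Each synthetic subject is an independent process realization sampled at
sparse clinical-style times (default 7 points over 240 min, 19 subjects)
plus additive Gaussian noise on the fraction scale (default design value
0.03 where noise is wanted; truncation at 0 optional). This emulates the
sampling design of gamma-scintigraphy series, **not** its physics: real
scintigraphic error is count-based and heteroscedastic, meals are
inhomogeneous (liquids empty faster than solids), and real subjects may
violate the single-(alpha, beta) assumption. Passing tests therefore
demonstrate internal consistency and recoverability under the model's own
assumptions, not clinical validity. Near full emptying, additive noise
around values ≈ 0 inflates the outside-band fraction above the nominal
10% even for the generating parameters; ranking remains consistent because
all candidates are scored on the same data.

## Problem sizes

The test and acceptance runs use the full published protocol (240 min,
`dt = 0.01`, 2000-member ensembles) for single-ensemble checks, and
500-member ensembles across the 3×2 parameter grid × 10 replicates for the
ranking-recovery experiment — sizes chosen to keep the complete suite in
the minutes range on a single CPU while leaving every statistical check
comfortably powered.

## Known limitations

- The running minimum is grid-based; no exact continuous-time simulation
  of the minimum is attempted (and no SDE formulation exists for this
  process by design).
- Pointwise envelopes understate simultaneous (whole-path) coverage.
- `S` can underflow to exactly 0 in double precision (see above).
- No formal parameter estimation (mixed-effects or SDE-likelihood) is
  provided; the grid ranking reproduces an informal envelope-consistency
  calibration only.
- The published 9.73%-outside figure for historical scintigraphy data
  depends on a privately digitized point set and cannot be recomputed
  here; the coverage machinery accepts any user-supplied CSV of profiles.
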