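"""Envelope-coverage analysis: do observed profiles fit inside the band?

Synthetic 19-subject scintigraphy-style data are generated from known
parameters, then a grid of candidate (alpha, beta) combinations is ranked
by how close each envelope's outside-fraction comes to the nominal 10%.
The generating combination should rank first.
"""

from sgem import (
    FixtureSpec,
    SGEMParams,
    SimulationProtocol,
    coverage_fraction,
    generate_profiles,
    pointwise_percentiles,
    rank_parameter_grid,
    simulate_ensemble,
)

truth = SGEMParams(alpha=1e-6, beta=6)
proto = SimulationProtocol(t_end=240.0, dt=0.01, n_paths=500, seed=11)
profiles = generate_profiles(
    FixtureSpec(params=truth, n_subjects=19, noise_sd=0.03, clip=True, seed=11), proto
)
print(f"{len(profiles)} synthetic subjects x {len(profiles[0])} observations")

ens = simulate_ensemble(truth, proto.n_paths, proto.t_end, proto.dt, proto.seed)
report = coverage_fraction(profiles, pointwise_percentiles(ens, (5.0, 95.0)))
print(f"true-parameter envelope: {report.n_outside}/{report.n_points} outside "
      f"(nominal 10% for noise-free in-sample data; observation noise near "
      f"the emptied floor inflates it)\n")

ranked = rank_parameter_grid(profiles, [1e-7, 1e-6, 1e-5], [4, 6], proto)
print("rank  alpha    beta  outside%")
for r, (params, rep) in enumerate(ranked, 1):
    print(f"{r:4d}  {params.alpha:7.0e}  {params.beta:4d}  {100 * rep.fraction_outside:7.1f}")
# The combination whose band leaves closest to 10% of points outside is the
# informal calibration choice.
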