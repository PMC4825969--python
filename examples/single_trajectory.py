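"""Simulate one stochastic emptying trajectory and inspect its spurts.

The residual meal fraction S(t) is the running minimum of
X(t) = exp(-alpha W(t)^beta): it stays at 1 until the Brownian excursion
first pushes X below its past minimum, then drops in discrete spurts.
"""

import numpy as np

from sgem import SGEMParams, simulate_sgem

params = SGEMParams(alpha=1e-6, beta=6)
w, x, s, spurts = simulate_sgem(params, t_end=240.0, dt=0.01, seed=1)

print(f"model: alpha={params.alpha:g}, beta={params.beta}")
for t in (30, 60, 120, 180, 240):
    print(f"  S({t:3d} min) = {s.at(t):.4f}")
print(f"{len(spurts)} spurts; largest = {spurts.amounts.max():.4f} "
      f"at t = {spurts.times[np.argmax(spurts.amounts)]:.2f} min")
print(f"total emptied = {spurts.total:.6f} = 1 - S(240) = {1 - s.values[-1]:.6f}")

# S(t) is the fraction of the meal still in the stomach: the spurt sizes
# telescope exactly to the total emptied fraction.
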