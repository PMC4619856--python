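"""Closed-form shrinkage rules versus direct 1D minimization.

The auxiliary update of the split PWLS problem reduces to independent
scalar problems  min_y Phi(|y|) + (gamma/2)(y - v)^2.  Both supported
potentials admit exact solutions; this script checks them against a
bounded scalar minimizer.
"""

import numpy as np
from scipy.optimize import minimize_scalar

from ctpwls import prox_edge_preserving, prox_l1

rng = np.random.default_rng(0)
s, gamma = 0.01, 50.0

print(f"edge-preserving potential, s={s}, gamma={gamma}")
print(f"{'v':>8} {'closed form':>12} {'numeric':>12}")
for v in (-0.5, -0.05, 0.0, 0.02, 0.4):
    y = prox_edge_preserving(v, s, gamma)
    ref = minimize_scalar(
        lambda t: abs(t) / s - np.log1p(abs(t) / s) + 0.5 * gamma * (t - v) ** 2,
        bounds=(-2, 2), method="bounded", options={"xatol": 1e-12},
    ).x
    print(f"{v:8.3f} {y:12.6f} {ref:12.6f}")

print(f"\nl1 potential (soft threshold at 1/gamma = {1 / gamma}):")
v = np.array([-0.5, -0.01, 0.0, 0.02, 0.4])
print("v      :", v)
print("prox(v):", prox_l1(v, gamma))
print("values inside the threshold collapse to zero; the rest shrink by 1/gamma")
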