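"""How heterogeneity extends criticality: the eight-case comparison.

Sweeps mean connectivity K for all eight combinations of homogeneous (Ho) /
heterogeneous (He) structure (S: Poisson vs exponential out-degrees),
temporality (T: synchronous vs out-degree update periods), and function
(F: fixed bias 0.5 vs triangular per-node biases), at a reduced scale, and
prints the mean complexity curves.  Functionally heterogeneous cases keep
complexity elevated far beyond the homogeneous critical point K=2 -- the
criticality region is broadened.  The crossover K is the smallest grid
connectivity from which the fully heterogeneous case (3He) tops all others.
"""

import numpy as np

from hetrbn.experiments import crossover_k, eight_case_comparison

k_grid = np.arange(1.0, 9.01, 1.0)
curves = eight_case_comparison(
    n_nodes=60, k_grid=k_grid, n_networks=25, n_steps=200, seed=3
)

header = "case           " + " ".join(f"K={k:<4g}" for k in k_grid)
print(header)
for curve in curves:
    row = " ".join(f"{v:.3f}" for v in curve.y_mean)
    print(f"{curve.label:14s} {row}")

k_star = crossover_k(curves, "3He")
print()
print(f"3He crossover (dominates all other cases from): K = {k_star}")
print("Cases with heterogeneous function (HeF) stay complex at large K,")
print("while fully homogeneous complexity decays after its peak near K = 2.")
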