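"""Ordered, critical, and chaotic dynamics of classical random Boolean networks.

Builds small classical RBNs (N=50 nodes, every node regulated by exactly K
others, rule bias p=0.5) at K = 1, 2, 5, runs 200 synchronous steps, and
prints the entropy-based network complexity C = mean over nodes of 4*I*(1-I).
For p = 0.5 the order-chaos transition sits at Kc = 1/(2*p*(1-p)) = 2, so
complexity should peak at K = 2: ordered dynamics (K=1) freeze (low I, low C)
and chaotic dynamics (K=5) look random (I near 1, again low C).
"""

import numpy as np

from hetrbn import (
    BiasDistributionSpec,
    DegreeDistributionSpec,
    critical_connectivity,
)
from hetrbn.experiments import ensemble_complexity

print(f"critical connectivity at p=0.5: Kc = {critical_connectivity(0.5):g}")
print()
print("K   mean C (100 nets)   regime")
for k, regime in [(1, "ordered"), (2, "critical"), (5, "chaotic")]:
    values = ensemble_complexity(
        50,
        DegreeDistributionSpec("regular", k),
        BiasDistributionSpec("point", 0.5),
        "synchronous",
        n_steps=200,
        n_networks=100,
        seed=1,
        stream=k,
    )
    print(f"{k}   {values.mean():.4f} +- {values.std()/np.sqrt(len(values)):.4f}"
          f"      {regime}")
print()
print("The ensemble mean complexity is largest at the critical connectivity;")
print("both the frozen (K=1) and the quasi-random (K=5) regimes score lower.")
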