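"""Antifragility of ordered and critical networks under state perturbations.

Every O steps, X randomly chosen node states are flipped while the network
runs for T steps.  Fragility A = -(C_perturbed - C_unperturbed) * X/(N*O)
compares the same network with and without the perturbations: A < 0 means
the network GAINS complexity from noise (antifragile), A > 0 that it loses
complexity (fragile).  Ordered networks (K=1) profit most: perturbations
unfreeze their dynamics.  Chaotic networks (K=5) only get noisier.
"""

from hetrbn import BiasDistributionSpec, DegreeDistributionSpec, PerturbationProtocol
from hetrbn.experiments import CaseLabel, case_specs, fragility_point

x_values = [1, 5, 10, 20, 40]
print("mean fragility A (N=100, T=200, O=1, 60 nets/point); negative = antifragile")
print("K    " + "  ".join(f"X={x:<4d}" for x in x_values))
for ki, k in enumerate([1, 2, 5]):
    structural, functional, scheme = case_specs(CaseLabel("Ho", "Ho", "Ho"), float(k))
    row = []
    for i, x in enumerate(x_values):
        protocol = PerturbationProtocol(n_flips=x, period=1, n_steps=200)
        mean, se = fragility_point(
            100, structural, functional, scheme, protocol, 60, 5,
            stream=9, point=ki * 10 + i,
        )
        row.append(f"{mean:+.3f}")
    print(f"K={k}  " + "  ".join(row))
print()
print("Ordered (K=1) and critical (K=2) networks show negative fragility over")
print("a wide X range; the chaotic K=5 networks never profit from perturbation.")
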