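# hetrbn

Random Boolean networks (RBNs) with **structural, temporal, and functional
heterogeneity**: a simulation and measurement toolkit for studying how
heterogeneity broadens the parameter region of critical-like dynamics, and
how networks respond to externally imposed state perturbations
(robustness, fragility, antifragility).

RBNs are a classical abstraction of gene regulatory networks: `N` binary
nodes, each updated by a randomly generated Boolean rule of its regulators.
They are useful whenever specific regulatory topologies are unknown but
the qualitative dynamics (ordered / critical / chaotic) matter. This package
is aimed at researchers in complex systems and computational/systems biology
who want reproducible, seed-controlled ensemble experiments on these models.

## Model

A network is built from three independently chosen ingredients:

* **Structure** — each node's out-degree is drawn from a distribution with
  mean connectivity `K`: Poisson (homogeneous case, HoS) or exponential
  (heterogeneous case, HeS); `regular` gives the classical fixed in-degree
  wiring. Targets are uniform; self-connections are allowed.
* **Function** — node `a`'s lookup table has `2^k_in` entries, each 1 with
  probability `p_a` (the bias). Homogeneous function (HoF) fixes
  `p_a = 0.5`; heterogeneous function (HeF) draws `p_a` from a distribution
  (triangular, Gaussian, uniform) with mean 0.5.
* **Temporality** — synchronous updating (HoT), or heterogeneous periods
  (HeT) where node `a` updates only when `t` is a multiple of its out-degree
  (`out_degree` scheme) or of one shared period (`ceil` scheme).

For bias `p` the order–chaos transition of the classical model sits at the
critical connectivity `Kc = [2p(1−p)]⁻¹` (so `Kc = 2` at `p = 0.5`).

**Complexity.** For each node the normalized Shannon entropy `I ∈ [0,1]` of
its binary time series is computed, and the node complexity is
`C = 4·I·(1−I)` — zero for frozen (`I=0`) and fully random (`I=1`) series,
maximal between order and chaos. The network complexity is the average of
node complexities; high `C` operationalizes criticality.

**Antifragility.** A perturbation protocol `(X, O, T)` flips `X` random node
states whenever `t` is a multiple of `O` during a run of length `T`. With
`Δx = X/(N·O)` the perturbation degree and `Δℂ = C − C₀` the complexity
gain of the perturbed run over the unperturbed run of the same network from
the same initial state, the fragility is `A = −Δℂ·Δx`: negative `A` means
the network *gains* complexity from noise (antifragile).

## Worked example

`examples/classical_regimes.py` builds classical RBN ensembles
(N=50, fixed in-degree K, p=0.5, 200 synchronous steps) and prints:

```
critical connectivity at p=0.5: Kc = 2

K   mean C (100 nets)   regime
1   0.1370 +- 0.0033      ordered
2   0.2289 +- 0.0075      critical
5   0.1180 +- 0.0032      chaotic
```

Mean complexity peaks at the predicted critical connectivity `K = Kc = 2`;
frozen (K=1) and quasi-random (K=5) ensembles both score lower. The other
examples demonstrate the eight-case heterogeneity sweep and crossover
(`heterogeneity_sweep.py`), fragility/antifragility curves
(`antifragility.py`), and functional-distribution variations with the
area-under-curve comparison (`functional_variations.py`).

A thin CLI mirrors the library for shell use:

```bash
hetrbn generate --n-nodes 9 --structural-kind regular --structural-mean-k 2 \
    --seed 1 --out model.json
hetrbn run --model model.json --steps 200 --out traj.csv --png traj.png
hetrbn sweep --case 3He --n-nodes 100 --n-networks 100 --steps 500 \
    --seed 1 --out curve.csv
```

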