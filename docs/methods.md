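# Methods

This note documents the model conventions, estimator definitions, parameter
defaults, and numerical choices behind `hetrbn`, including the places where
the construction is genuinely underdetermined and a convention had to be
fixed. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

A random Boolean network is a directed graph of `N` binary nodes. Node `a`
has an ordered list of distinct in-neighbors (regulators) and a lookup table
of `2^k_in` bits; at an update, the regulators' states (read from the
previous step) are encoded into a table index with the **first listed
in-neighbor as the most significant bit**, and the node takes the indexed
bit. Table entries are i.i.d. Bernoulli(`p_a`), where `p_a` is the node's
bias. The model is quenched: wiring, tables, and biases are fixed for the
lifetime of a network.

### Structural generation

* `regular` (classical case): every node receives exactly `k` distinct
  in-neighbors chosen uniformly, self-connections allowed. Drawing without
  replacement is distributionally identical to drawing with replacement and
  redrawing duplicates, and keeps the in-degree exactly `k`. Fractional `K`
  is not meaningful here, so `regular` requires integer `K`.
* `poisson` / `exponential`: one **out-degree** per node is drawn
  (exponential draws are rounded to the nearest integer and floored at 0;
  a `min_degree=1` flag floors at 1 instead). Each node's out-edges target
  distinct uniform nodes; out-degrees above `N` are capped at `N`. Poisson
  is the structurally homogeneous contrast; the exponential, with variance
  `K²` against the Poisson's `K`, is the heterogeneous case. With uniform
  targeting, in-degrees are approximately Poisson(`K`) under both choices —
  the two cases differ in how *influence* (out-degree) is distributed.
* Nodes that end up with **no regulators** hold a single-entry table: they
  freeze at that constant from their first update on. This is the minimal
  semantics consistent with the lookup-table formalism.

### Functional generation

Biases live on a domain `[a, b] ⊆ [0, 1]` with mean 0.5 by default:

* `point` — all nodes share one bias (homogeneous case);
* `triangular` — mode at the stated mean, endpoints at the domain (so an
  off-center mode gives an asymmetric triangle);
* `uniform` — uniform on the domain (standard deviation 0.288 on `[0,1]`);
* `gaussian` — Gaussian(mean, sd) truncated to the domain by rejection
  sampling; symmetric truncation preserves the mean.

Continuous kinds other than the Gaussian are inverse-CDF transforms of one
uniform stream, which makes variant comparisons sharing a seed maximally
paired (see *Seeding*).

### Temporal schemes

Node `a` updates at step `t` iff `t mod P_a = 0`; all nodes due at `t` read
the state at `t−1` (deterministic generalized-asynchronous semantics, no
within-step cascade).

* `synchronous`: `P_a = 1` — the classical, temporally homogeneous case.
* `out_degree`: `P_a = max(K⁺_a, 1)` — influential nodes update more
  slowly. The floor at 1 resolves the undefined period of a node with no
  out-edges.
* `ceil`: one shared period for all nodes, `⌈K⌉` of the sweep's mean
  connectivity by default (`ceil_mode="max_out_degree"` shares the largest
  realized out-degree instead). The default gives a smooth, K-dependent,
  temporally homogeneous contrast to out-degree updating.

### Perturbation protocol

Given `(X, O, T)`, at every step `t = O, 2O, … < T` (after the step update)
exactly `X` distinct uniformly chosen nodes have their state inverted. The
initial state (`t = 0`) is never perturbed: perturbing before any dynamics
has run would not probe the dynamics at all.

## Measures

* **Entropy**: per node, the plug-in estimator of the base-2 Shannon entropy
  of its binary time series, normalized to `[0, 1]`; `0·log 0 := 0`. No
  bias correction is applied, and the series is the **full trajectory
  including the initial state** (no burn-in). Complexity is computed per
  node as `C = 4·I·(1−I)` and then averaged across nodes.
* **Fragility**: paired design — the same network, schedule, and initial
  state are run once without and once with the protocol; `A = −Δℂ·Δx` with
  `Δx = X/(N·O)` (the runtime cancels algebraically). Replicate averages
  report the standard error of the mean, which sign claims are judged
  against; single-run fragility values are not meaningful on their own.
* **Curves**: ensemble means with standard errors at each grid point; the
  replication unit is a freshly generated network with one fresh random
  initial state. Area under a curve is the trapezoidal rule on the grid
  means. The *crossover* of a reference curve is the smallest grid point
  from which its mean strictly exceeds every other curve's mean there and at
  all later grid points.

## Seeding

Every stochastic component — topology, biases, tables, initial state,
perturbation draws — of every replicate at every grid point uses its own
`SeedSequence` child of the master seed, keyed by a stable path
`(stream, point, replicate, component)`. Consequences: results are
bit-reproducible for a fixed master seed; increasing the replicate count
leaves earlier replicates unchanged; and two curves computed with the same
seed and stream are paired replicate-by-replicate — variants that share a
component spec (say, the same structural distribution) see *identical*
draws for that component. The mean-symmetry and point-like-variant checks
in the test suite rely on this pairing.

## Default scales

Paper-scale sweeps (45 connectivities at spacing 0.2, 1000 networks per
point, 2000 steps; fragility grids at unit spacing with 1000 replicates and
200 steps) are the CLI defaults and are expensive — hours on one core. The
test suite and acceptance script use reduced settings chosen to finish in
minutes while keeping standard errors small enough for the qualitative
claims they check: classical regime ensembles at 300 networks, the
eight-case sweep at N=100 with 150 networks/point and 500 steps over
K ∈ [4, 8], fragility points at 200 replicates. All scales are plain
function arguments; nothing is hard-wired.

## What the generator emulates — and what it does not

The synthetic ensembles realize the study conditions themselves: quenched
random wiring, i.i.d. random tables, uniform random initial states. They do
not emulate features of real gene regulatory networks such as scale-free or
modular topology, canalizing or biologically constrained rule classes,
correlated initial conditions, or noise in the update rule itself. Passing
tests therefore validate the dynamics engine and the statistical machinery
on the idealized model class, not fidelity to any particular biological
network.

## Numerical choices and degenerate inputs

* Entropy terms with zero probability contribute exactly 0; entropies are
  clipped to `[0, 1]` to absorb float rounding at the boundaries.
* `node_complexity` accepts inputs within 1e-9 of `[0, 1]` and rejects
  anything further out; `critical_connectivity` rejects `p ∈ {0, 1}`
  (divergence).
* Tables of in-degree-0 nodes have length 1 (the constant); the step kernel
  computes table indices by a weighted bincount, which assigns those nodes
  index 0 without special-casing.
* Ties in the crossover statistic: "exceeds" is strict, so two curves that
  coincide numerically at a grid point block domination at that point.
* Serialized models store tables as 0/1 strings in index order; round-trips
  are lossless and byte-stable for a fixed seed.

## Known limitations

* **Transient sensitivity.** With the full-series plug-in estimator, a
  frozen node whose brief transient disagrees with its final value can score
  a large complexity (a 10% minority fraction maximizes `C`). Short runs
  (T ≈ 200) therefore put nontrivial complexity on ordered ensembles, and
  single-realization complexity values scatter widely — ensemble means with
  standard errors are the meaningful quantities. Alternative conventions
  (averaging entropies before applying `4x(1−x)`, discarding transients, or
  measuring change rates instead of state frequencies) shift complexity
  levels substantially while preserving most orderings; the package fixes
  the per-node full-series convention and reports it explicitly.
* **Saturating perturbations.** Fragility conclusions depend on the
  protocol's position in `(X, O)` space: very aggressive protocols (e.g.,
  flipping 40% of nodes every step) drive node entropies toward 1 in every
  regime and mask the antifragility that the same networks show at milder
  settings. Sweeps over `X` or `O` are the robust way to locate
  antifragility intervals.
* **Near-degenerate curve ties.** At reduced replication, the fully
  heterogeneous curve and its nearest functionally heterogeneous neighbors
  can be statistically indistinguishable over part of the grid, making the
  crossover statistic noise-dominated there; its seed-to-seed spread should
  be checked before interpreting a single value.
* Attractor detection, basin statistics, multi-valued states, and adaptive
  (rewiring) networks are out of scope.
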