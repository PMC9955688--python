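"""Entropy-based complexity and perturbation-based (anti)fragility measures.

For a binary series the normalized Shannon entropy is

    I = -(1/log2 b) * sum_i p_i log p_i,   b = 2,

with ``p_i`` the empirical symbol frequencies, so I is in [0, 1].  Node
complexity is the balance measure

    C = 4 * I * (1 - I),

maximal (1) at I = 1/2 and zero for both frozen (I = 0) and fully random
(I = 1) series.  Network complexity is the per-node complexity computed from
each node's temporal series, averaged over nodes.  High C operationalizes
critical-like dynamics between the ordered and chaotic regimes.

Fragility compares a run without perturbations (complexity C0) against a run
of the same network from the same initial state with the perturbation
protocol (complexity C):

    dx = X * (T/O) / (N * T) = X / (N * O)   (perturbation degree)
    dC = C - C0                              (complexity gain)
    A  = -dC * dx                            (fragility)

A < 0 marks antifragility (the network gains complexity from perturbation),
A near 0 robustness, A > 0 fragility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import Generator
from scipy import stats

from .dynamics import PerturbationProtocol, Schedule, Trajectory, build_schedule, random_state, run
from .netgen import (
    BiasDistributionSpec,
    DegreeDistributionSpec,
    RBNModel,
    SpecError,
    build_rbn,
)

__all__ = [
    "ComplexityResult",
    "FragilityResult",
    "MeanFragilityResult",
    "shannon_entropy",
    "node_complexity",
    "trajectory_complexity",
    "perturbation_degree",
    "complexity_gain",
    "fragility",
    "mean_fragility",
    "critical_connectivity",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ComplexityResult:
    """Per-node entropies/complexities and their network average."""

    node_entropy: np.ndarray
    node_complexity: np.ndarray
    network_complexity: float


@dataclass(frozen=True)
class FragilityResult:
    """Paired unperturbed/perturbed complexities and the fragility A."""

    c0: float
    c: float
    delta_c: float
    delta_x: float
    fragility: float


@dataclass(frozen=True)
class MeanFragilityResult:
    """Replicate-averaged fragility with its standard error."""

    mean: float
    se: float
    values: np.ndarray


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    """Entropy (base 2) of Bernoulli(p), elementwise; 0*log0 := 0."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    hp = np.where(p > 0, p, 1.0)
    hq = np.where(q > 0, q, 1.0)
    h = -(hp * np.log2(hp) + hq * np.log2(hq))
    return np.clip(h, 0.0, 1.0)


def shannon_entropy(series) -> float:
    """Normalized Shannon entropy of a binary sequence (plug-in estimator)."""
    series = np.asarray(series)
    if series.size == 0:
        raise SpecError("series must be nonempty")
    if not np.isin(series, (0, 1)).all():
        raise SpecError("series must be binary (0/1)")
    counts = np.bincount(series.astype(np.int64).ravel(), minlength=2)
    return float(stats.entropy(counts, base=2))


def node_complexity(entropy) -> float | np.ndarray:
    """Complexity C = 4*I*(1-I) of a normalized entropy value in [0, 1]."""
    entropy = np.asarray(entropy, dtype=float)
    if np.any(entropy < -_EPS) or np.any(entropy > 1 + _EPS):
        raise SpecError("entropy must lie in [0, 1]")
    entropy = np.clip(entropy, 0.0, 1.0)
    out = 4.0 * entropy * (1.0 - entropy)
    return float(out) if out.ndim == 0 else out


def trajectory_complexity(traj: Trajectory | np.ndarray) -> ComplexityResult:
    """Complexity of a trajectory: per-node over the node's full time series
    (including the initial state), then averaged across nodes."""
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj)
    if states.ndim != 2 or states.shape[0] < 1:
        raise SpecError("trajectory must be a nonempty T x N matrix")
    p_one = states.mean(axis=0)
    entropies = _binary_entropy(p_one)
    complexities = 4.0 * entropies * (1.0 - entropies)
    return ComplexityResult(
        node_entropy=entropies,
        node_complexity=complexities,
        network_complexity=float(complexities.mean()),
    )


def perturbation_degree(n_flips: int, period: int, n_steps: int, n_nodes: int) -> float:
    """Perturbation degree dx = X*(T/O) / (N*T), which simplifies to X/(N*O)."""
    if period < 1:
        raise SpecError("period (O) must be >= 1")
    if n_steps < 1:
        raise SpecError("n_steps (T) must be >= 1")
    if not 0 <= n_flips <= n_nodes:
        raise SpecError("n_flips (X) must satisfy 0 <= X <= N")
    return n_flips / (n_nodes * period)


def complexity_gain(c: float, c0: float) -> float:
    """Complexity gain dC = C - C0 (perturbed minus unperturbed)."""
    for v in (c, c0):
        if not -_EPS <= v <= 1 + _EPS:
            raise SpecError("complexities must lie in [0, 1]")
    return c - c0


def fragility(
    model: RBNModel,
    schedule: Schedule,
    init: np.ndarray,
    protocol: PerturbationProtocol,
    rng: Generator,
) -> FragilityResult:
    """Paired fragility: the same (model, schedule, init) is run without and
    with the perturbation protocol; A = -(C - C0) * dx."""
    c0 = trajectory_complexity(
        run(model, schedule, init, protocol.n_steps)
    ).network_complexity
    c = trajectory_complexity(
        run(model, schedule, init, protocol.n_steps, protocol=protocol, rng=rng)
    ).network_complexity
    dx = perturbation_degree(
        protocol.n_flips, protocol.period, protocol.n_steps, model.n_nodes
    )
    dc = complexity_gain(c, c0)
    return FragilityResult(c0=c0, c=c, delta_c=dc, delta_x=dx, fragility=-dc * dx)


def mean_fragility(
    n_nodes: int,
    structural: DegreeDistributionSpec,
    functional: BiasDistributionSpec,
    scheme: str,
    protocol: PerturbationProtocol,
    n_reps: int,
    rng: Generator,
    *,
    regenerate_networks: bool = True,
) -> MeanFragilityResult:
    """Average fragility over ``n_reps`` freshly generated (model, initial
    state) pairs; reports the mean and its standard error.

    With ``regenerate_networks=False`` a single network is generated and only
    the initial states (and perturbations) are redrawn per replicate.
    """
    if n_reps < 1:
        raise SpecError("n_reps must be >= 1")
    values = np.empty(n_reps)
    model = None
    schedule = None
    for j in range(n_reps):
        if model is None or regenerate_networks:
            model = build_rbn(n_nodes, structural, functional, rng)
            schedule = build_schedule(scheme, model.topology, mean_k=structural.mean_k)
        init = random_state(n_nodes, rng)
        values[j] = fragility(model, schedule, init, protocol, rng).fragility
    se = float(values.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return MeanFragilityResult(mean=float(values.mean()), se=se, values=values)


def critical_connectivity(p: float) -> float:
    """Critical connectivity Kc = [2p(1-p)]^-1 of the order-chaos transition
    for rule bias ``p`` (diverges as p approaches 0 or 1)."""
    if not 0.0 < p < 1.0:
        raise SpecError("p must lie strictly inside (0, 1)")
    return 1.0 / (2.0 * p * (1.0 - p))
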