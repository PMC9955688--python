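"""Generators for random Boolean networks (RBNs) with controllable heterogeneity.

An RBN is a directed graph of ``N`` binary nodes.  Node ``a`` carries an
ordered list of in-neighbors (its regulators) and a lookup table that assigns
a Boolean output to each of the ``2**k_in`` input configurations, where
``k_in`` is the number of (distinct) regulators.  The table entries are
generated independently: entry = 1 with probability ``p_a`` (the *bias* of
node ``a``).

Heterogeneity enters in two places here:

* **structural** -- the per-node out-degree is drawn from a distribution
  with mean ``K`` (Poisson for the homogeneous contrast, exponential for
  the heterogeneous case);
* **functional** -- the per-node bias ``p_a`` is drawn from a distribution
  with a fixed mean (a point mass for the homogeneous contrast).

Temporal heterogeneity (update schedules) lives in :mod:`hetrbn.dynamics`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import Generator
from scipy import stats

__all__ = [
    "SpecError",
    "DegreeDistributionSpec",
    "BiasDistributionSpec",
    "Topology",
    "RuleSet",
    "RBNModel",
    "sample_out_degrees",
    "wire_from_out_degrees",
    "build_regular_topology",
    "sample_biases",
    "build_rules",
    "build_rbn",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
]

DEGREE_KINDS = ("regular", "poisson", "exponential")
BIAS_KINDS = ("point", "gaussian", "uniform", "triangular")


class SpecError(ValueError):
    """Raised for invalid generator specifications or inputs."""


@dataclass(frozen=True)
class DegreeDistributionSpec:
    """Distribution of node out-degrees (or the fixed in-degree for ``regular``).

    Parameters
    ----------
    kind:
        ``"regular"`` (every node has exactly ``mean_k`` in-neighbors, the
        classical case), ``"poisson"`` (homogeneous structural case) or
        ``"exponential"`` (heterogeneous structural case; continuous draws
        are rounded to the nearest integer).
    mean_k:
        Average connectivity ``K``.  Must be a positive integer for
        ``regular``.
    min_degree:
        Floor applied to discretized exponential draws; 0 permits leaf
        nodes, 1 forces at least one out-edge.
    """

    kind: str
    mean_k: float
    min_degree: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEGREE_KINDS:
            raise SpecError(f"unknown degree distribution kind: {self.kind!r}")
        if not self.mean_k > 0:
            raise SpecError("mean_k must be positive")
        if self.kind == "regular" and float(self.mean_k) != int(self.mean_k):
            raise SpecError("regular degree distribution requires integer mean_k")
        if self.min_degree not in (0, 1):
            raise SpecError("min_degree must be 0 or 1")


@dataclass(frozen=True)
class BiasDistributionSpec:
    """Distribution of per-node rule biases ``p_a`` on a domain within [0, 1].

    ``point`` puts all mass at ``mean`` (the functionally homogeneous case).
    ``gaussian`` is a Gaussian(mean, sd) truncated to ``domain`` by rejection.
    ``uniform`` is uniform on ``domain``.  ``triangular`` has mode ``mean``
    with the stated domain endpoints (symmetric when the mode is the domain
    midpoint).
    """

    kind: str
    mean: float = 0.5
    sd: float = 0.0
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in BIAS_KINDS:
            raise SpecError(f"unknown bias distribution kind: {self.kind!r}")
        a, b = self.domain
        if not (0.0 <= a <= b <= 1.0):
            raise SpecError("bias domain must be an interval within [0, 1]")
        if not (a <= self.mean <= b):
            raise SpecError("bias mean must lie inside the domain")
        if self.sd < 0:
            raise SpecError("bias sd must be nonnegative")
        if self.kind == "gaussian" and self.sd == 0:
            raise SpecError("gaussian bias requires sd > 0 (use kind='point' for sd=0)")


@dataclass
class Topology:
    """Wiring of an RBN: per-node ordered in-neighbor lists.

    ``out_degree[a]`` equals the number of occurrences of ``a`` across all
    in-neighbor lists.  Self-connections are permitted; in-neighbor lists
    contain distinct nodes.
    """

    in_neighbors: list[np.ndarray]
    out_degree: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.n_nodes
        self.in_neighbors = [np.asarray(lst, dtype=np.int64) for lst in self.in_neighbors]
        for lst in self.in_neighbors:
            if lst.size and (lst.min() < 0 or lst.max() >= n):
                raise SpecError("in-neighbor index out of range")
        flat = (
            np.concatenate(self.in_neighbors)
            if self.in_neighbors
            else np.empty(0, dtype=np.int64)
        )
        self.out_degree = np.bincount(flat, minlength=n).astype(np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.in_neighbors)

    @property
    def in_degree(self) -> np.ndarray:
        return np.array([len(lst) for lst in self.in_neighbors], dtype=np.int64)


@dataclass
class RuleSet:
    """Per-node biases and Boolean lookup tables.

    ``tables[a]`` has exactly ``2**k_in(a)`` entries in {0, 1}; the input
    tuple is encoded with the *first listed* in-neighbor as the most
    significant bit.  Nodes with no regulators hold a single-entry table
    (a constant).
    """

    bias: np.ndarray
    tables: list[np.ndarray]

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.tables = [np.asarray(t, dtype=np.uint8) for t in self.tables]


@dataclass
class RBNModel:
    """A complete RBN dynamical system: wiring + rules + provenance."""

    topology: Topology
    rules: RuleSet
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k_in = self.topology.in_degree
        for a, table in enumerate(self.rules.tables):
            if table.size != 2 ** int(k_in[a]):
                raise SpecError(
                    f"node {a}: table size {table.size} inconsistent with in-degree {k_in[a]}"
                )

    @property
    def n_nodes(self) -> int:
        return self.topology.n_nodes


def sample_out_degrees(
    spec: DegreeDistributionSpec, n_nodes: int, rng: Generator
) -> np.ndarray:
    """Draw one out-degree per node from ``spec``.

    ``regular`` returns a constant vector; ``poisson`` draws i.i.d.
    Poisson(mean_k); ``exponential`` draws Exp(mean_k), rounds to the
    nearest integer and floors at ``spec.min_degree``.
    """
    if n_nodes < 1:
        raise SpecError("n_nodes must be >= 1")
    if spec.kind == "regular":
        return np.full(n_nodes, int(spec.mean_k), dtype=np.int64)
    if spec.kind == "poisson":
        return rng.poisson(spec.mean_k, size=n_nodes).astype(np.int64)
    draws = np.rint(rng.exponential(spec.mean_k, size=n_nodes)).astype(np.int64)
    return np.maximum(draws, spec.min_degree)


def wire_from_out_degrees(out_degrees: Sequence[int], rng: Generator) -> Topology:
    """Wire a network so node ``a`` regulates ``out_degrees[a]`` targets.

    Each node's targets are distinct nodes chosen uniformly at random
    (self-loops allowed); sampling without replacement is equivalent to
    drawing with replacement and redrawing duplicates.  Out-degrees larger
    than ``N`` are capped at ``N`` (all nodes become targets).
    """
    out_degrees = np.asarray(out_degrees, dtype=np.int64)
    if out_degrees.size and out_degrees.min() < 0:
        raise SpecError("out-degrees must be nonnegative")
    n = out_degrees.size
    sources: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    for a, d in enumerate(out_degrees):
        d_eff = int(min(d, n))
        if d_eff == 0:
            continue
        tgt = rng.choice(n, size=d_eff, replace=False)
        targets.append(tgt)
        sources.append(np.full(d_eff, a, dtype=np.int64))
    in_neighbors: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n)]
    if targets:
        src = np.concatenate(sources)
        tgt = np.concatenate(targets)
        order = np.lexsort((src, tgt))
        src, tgt = src[order], tgt[order]
        bounds = np.searchsorted(tgt, np.arange(n + 1))
        for b in range(n):
            lo, hi = bounds[b], bounds[b + 1]
            if hi > lo:
                in_neighbors[b] = src[lo:hi]
    return Topology(in_neighbors=in_neighbors)


def build_regular_topology(n_nodes: int, k: int, rng: Generator) -> Topology:
    """Classical wiring: every node has exactly ``k`` distinct in-neighbors
    chosen uniformly at random (self-connections allowed)."""
    if k < 1:
        raise SpecError("k must be >= 1")
    if k > n_nodes:
        raise SpecError("k cannot exceed the number of nodes")
    in_neighbors = [np.sort(rng.choice(n_nodes, size=k, replace=False)) for _ in range(n_nodes)]
    return Topology(in_neighbors=in_neighbors)


def sample_biases(
    spec: BiasDistributionSpec, n_nodes: int, rng: Generator
) -> np.ndarray:
    """Draw one rule bias per node from ``spec``; all values lie in the domain."""
    if n_nodes < 1:
        raise SpecError("n_nodes must be >= 1")
    a, b = spec.domain
    if spec.kind == "point":
        return np.full(n_nodes, float(spec.mean))
    if spec.kind == "uniform":
        return a + (b - a) * rng.random(n_nodes)
    if spec.kind == "triangular":
        if b == a:
            return np.full(n_nodes, float(a))
        c = (spec.mean - a) / (b - a)
        return stats.triang.ppf(rng.random(n_nodes), c, loc=a, scale=b - a)
    # gaussian: rejection-sample into the domain (truncated Gaussian)
    out = np.empty(n_nodes)
    filled = 0
    while filled < n_nodes:
        draw = rng.normal(spec.mean, spec.sd, size=2 * (n_nodes - filled))
        keep = draw[(draw >= a) & (draw <= b)]
        take = min(keep.size, n_nodes - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def build_rules(topology: Topology, biases: Sequence[float], rng: Generator) -> RuleSet:
    """Generate lookup tables: entry 1 with probability ``biases[a]``, i.i.d."""
    biases = np.asarray(biases, dtype=float)
    if biases.size != topology.n_nodes:
        raise SpecError("one bias per node is required")
    tables = [
        (rng.random(2 ** len(nbrs)) < biases[a]).astype(np.uint8)
        for a, nbrs in enumerate(topology.in_neighbors)
    ]
    return RuleSet(bias=biases, tables=tables)


def build_rbn(
    n_nodes: int,
    structural: DegreeDistributionSpec,
    functional: BiasDistributionSpec,
    rng: Generator,
    *,
    seed: int | None = None,
) -> RBNModel:
    """Compose a full model from structural and functional specs.

    For ``regular`` structure the classical fixed in-degree wiring is used;
    otherwise out-degrees are sampled and wired to uniform targets.
    Deterministic given the state of ``rng``.
    """
    if structural.kind == "regular":
        topology = build_regular_topology(n_nodes, int(structural.mean_k), rng)
    else:
        out_degrees = sample_out_degrees(structural, n_nodes, rng)
        topology = wire_from_out_degrees(out_degrees, rng)
    biases = sample_biases(functional, n_nodes, rng)
    rules = build_rules(topology, biases, rng)
    meta = {
        "n_nodes": n_nodes,
        "structural": {
            "kind": structural.kind,
            "mean_k": structural.mean_k,
            "min_degree": structural.min_degree,
        },
        "functional": {
            "kind": functional.kind,
            "mean": functional.mean,
            "sd": functional.sd,
            "domain": list(functional.domain),
        },
        "seed": seed,
    }
    return RBNModel(topology=topology, rules=rules, meta=meta)


# ---------------------------------------------------------------------------
# Serialization: JSON with tables as bitstrings (entry order = integer index
# 0..2**k-1; the first listed in-neighbor is the most significant input bit).
# ---------------------------------------------------------------------------


def model_to_json(model: RBNModel) -> str:
    doc = {
        "n_nodes": model.n_nodes,
        "in_neighbors": [lst.tolist() for lst in model.topology.in_neighbors],
        "bias": model.rules.bias.tolist(),
        "tables": ["".join("1" if v else "0" for v in t) for t in model.rules.tables],
        "meta": model.meta,
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(text: str) -> RBNModel:
    doc = json.loads(text)
    topology = Topology(in_neighbors=[np.asarray(x, dtype=np.int64) for x in doc["in_neighbors"]])
    tables = [np.frombuffer(t.encode(), dtype=np.uint8) - ord("0") for t in doc["tables"]]
    rules = RuleSet(bias=np.asarray(doc["bias"], dtype=float), tables=tables)
    return RBNModel(topology=topology, rules=rules, meta=doc.get("meta", {}))


def save_model(model: RBNModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> RBNModel:
    with open(path) as fh:
        return model_from_json(fh.read())
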