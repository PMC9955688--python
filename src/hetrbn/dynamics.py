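"""State evolution of RBNs under homogeneous or heterogeneous update schedules.

A node's next value is the lookup of its in-neighbors' current values in its
rule table.  In the classical (temporally homogeneous) case all nodes update
every step.  In the heterogeneous case node ``a`` updates only when the step
index ``t`` is a multiple of its period ``P_a``:

* ``synchronous`` -- ``P_a = 1`` for all nodes;
* ``out_degree``  -- ``P_a = max(K_a+, 1)``: the more nodes a node affects,
  the slower it is updated;
* ``ceil``        -- one shared period for all nodes, by default
  ``ceil(mean_k)`` (a temporally homogeneous contrast with a K-dependent
  activation period).

All nodes due at step ``t`` read the state at ``t-1`` (deterministic
generalized-asynchronous semantics: no within-step cascade).  An optional
perturbation protocol flips ``X`` randomly chosen node states whenever ``t``
is a positive multiple of ``O``, after the step update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.random import Generator

from .netgen import RBNModel, SpecError, Topology

__all__ = [
    "Schedule",
    "PerturbationProtocol",
    "Trajectory",
    "build_schedule",
    "random_state",
    "step",
    "apply_perturbation",
    "run",
]

SCHEMES = ("synchronous", "out_degree", "ceil")


@dataclass(frozen=True)
class Schedule:
    """Per-node update periods realizing a temporal (in)homogeneity scheme."""

    scheme: str
    periods: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", np.asarray(self.periods, dtype=np.int64))
        if self.periods.size and self.periods.min() < 1:
            raise SpecError("all update periods must be >= 1")


@dataclass(frozen=True)
class PerturbationProtocol:
    """External stressor: flip ``n_flips`` (X) random node states every
    ``period`` (O) steps over a runtime of ``n_steps`` (T)."""

    n_flips: int
    period: int
    n_steps: int

    def __post_init__(self) -> None:
        if self.n_flips < 0:
            raise SpecError("n_flips (X) must be >= 0")
        if self.period < 1:
            raise SpecError("period (O) must be >= 1")
        if self.n_steps < 1:
            raise SpecError("n_steps (T) must be >= 1")


@dataclass
class Trajectory:
    """A T x N binary state history; row 0 is the initial state."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise SpecError("trajectory states must be a T x N matrix")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.states, fmt="%d", delimiter=",")

    def to_png(self, path) -> None:
        """One pixel per state, time flowing downward (white = 1)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plt.imsave(path, self.states, cmap="gray", vmin=0, vmax=1)


def build_schedule(
    scheme: str,
    topology: Topology,
    mean_k: float | None = None,
    *,
    ceil_mode: str = "mean_k",
) -> Schedule:
    """Build per-node update periods for one of the three schemes.

    ``ceil`` requires ``mean_k`` when ``ceil_mode="mean_k"`` (shared period
    ``ceil(mean_k)``); ``ceil_mode="max_out_degree"`` instead shares the
    largest realized out-degree.
    """
    n = topology.n_nodes
    if scheme == "synchronous":
        periods = np.ones(n, dtype=np.int64)
    elif scheme == "out_degree":
        periods = np.maximum(topology.out_degree, 1)
    elif scheme == "ceil":
        if ceil_mode == "mean_k":
            if mean_k is None or mean_k <= 0:
                raise SpecError("ceil schedule requires a positive mean_k")
            shared = int(math.ceil(mean_k))
        elif ceil_mode == "max_out_degree":
            shared = max(int(topology.out_degree.max(initial=0)), 1)
        else:
            raise SpecError(f"unknown ceil_mode: {ceil_mode!r}")
        periods = np.full(n, shared, dtype=np.int64)
    else:
        raise SpecError(f"unknown schedule scheme: {scheme!r}")
    return Schedule(scheme=scheme, periods=periods)


def random_state(n_nodes: int, rng: Generator) -> np.ndarray:
    """Uniform random initial state: i.i.d. fair bits."""
    if n_nodes < 1:
        raise SpecError("n_nodes must be >= 1")
    return rng.integers(0, 2, size=n_nodes, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Compiled flat-array form of a model, cached on the model instance.  The
# per-step work is one gather, one weighted bincount (table index per node)
# and one table lookup, all vectorized over nodes.
# ---------------------------------------------------------------------------


class _Compiled:
    __slots__ = ("flat_in", "edge_owner", "weights", "flat_table", "table_offsets")

    def __init__(self, model: RBNModel) -> None:
        topo = model.topology
        n = topo.n_nodes
        self.flat_in = (
            np.concatenate(topo.in_neighbors)
            if n
            else np.empty(0, dtype=np.int64)
        )
        k_in = topo.in_degree
        self.edge_owner = np.repeat(np.arange(n), k_in)
        # first listed in-neighbor = most significant bit of the table index
        weights = np.concatenate(
            [2.0 ** np.arange(k - 1, -1, -1) for k in k_in]
        ) if self.flat_in.size else np.empty(0)
        self.weights = weights
        sizes = np.array([t.size for t in model.rules.tables], dtype=np.int64)
        self.table_offsets = np.concatenate(([0], np.cumsum(sizes)))[:-1]
        self.flat_table = (
            np.concatenate(model.rules.tables) if n else np.empty(0, dtype=np.uint8)
        )


def _compiled(model: RBNModel) -> _Compiled:
    comp = getattr(model, "_compiled_cache", None)
    if comp is None:
        comp = _Compiled(model)
        model._compiled_cache = comp
    return comp


def _lookup(comp: _Compiled, n: int, state: np.ndarray) -> np.ndarray:
    contrib = comp.weights * state[comp.flat_in]
    idx = np.bincount(comp.edge_owner, weights=contrib, minlength=n).astype(np.int64)
    return comp.flat_table[comp.table_offsets + idx]


def step(
    model: RBNModel, schedule: Schedule, state: np.ndarray, t: int
) -> np.ndarray:
    """Advance one step: nodes with ``t % P_a == 0`` take their table value
    (computed from the state at ``t-1``); all others keep their state."""
    state = np.asarray(state, dtype=np.uint8)
    if state.size != model.n_nodes:
        raise SpecError("state length must equal the number of nodes")
    comp = _compiled(model)
    due = (t % schedule.periods) == 0
    if not due.any():
        return state.copy()
    new_vals = _lookup(comp, model.n_nodes, state)
    return np.where(due, new_vals, state).astype(np.uint8)


def apply_perturbation(state: np.ndarray, n_flips: int, rng: Generator) -> np.ndarray:
    """Invert the bits of exactly ``n_flips`` distinct randomly chosen nodes."""
    state = np.asarray(state, dtype=np.uint8)
    n = state.size
    if not 0 <= n_flips <= n:
        raise SpecError("n_flips (X) must satisfy 0 <= X <= N")
    out = state.copy()
    if n_flips:
        idx = rng.choice(n, size=n_flips, replace=False)
        out[idx] ^= 1
    return out


def run(
    model: RBNModel,
    schedule: Schedule,
    init: np.ndarray,
    n_steps: int,
    protocol: PerturbationProtocol | None = None,
    rng: Generator | None = None,
) -> Trajectory:
    """Evolve the network for ``n_steps`` rows (row 0 = ``init``).

    For t = 1..n_steps-1 the state is stepped; if a protocol is given and
    ``t`` is a multiple of its period, ``n_flips`` random states are then
    inverted.  Without a protocol the trajectory is a deterministic function
    of (model, schedule, init).
    """
    init = np.asarray(init, dtype=np.uint8)
    if init.size != model.n_nodes:
        raise SpecError("init length must equal the number of nodes")
    if n_steps < 1:
        raise SpecError("n_steps must be >= 1")
    if protocol is not None:
        if protocol.n_steps != n_steps:
            raise SpecError("protocol.n_steps must equal the runtime n_steps")
        if protocol.n_flips > model.n_nodes:
            raise SpecError("protocol.n_flips cannot exceed the number of nodes")
        if rng is None:
            raise SpecError("a perturbation protocol requires an rng")
    comp = _compiled(model)
    n = model.n_nodes
    periods = schedule.periods
    states = np.empty((n_steps, n), dtype=np.uint8)
    states[0] = init
    state = init.copy()
    for t in range(1, n_steps):
        due = (t % periods) == 0
        if due.any():
            new_vals = _lookup(comp, n, state)
            state = np.where(due, new_vals, state).astype(np.uint8)
        if protocol is not None and protocol.n_flips and t % protocol.period == 0:
            idx = rng.choice(n, size=protocol.n_flips, replace=False)
            state = state.copy()
            state[idx] ^= 1
        states[t] = state
    return Trajectory(states=states)
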