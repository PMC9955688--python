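"""Seeded generation of tiny, exhaustively verifiable example networks.

These fixtures serve the test suite and CLI demos: networks small enough
(N <= 4) that every one of the 2**N initial states can be simulated by the
naive reference implementation and compared with the vectorized engine.
"""

from __future__ import annotations

import itertools
import json
import pathlib

import numpy as np

from . import netgen
from .dynamics import build_schedule, run
from .netgen import RBNModel, RuleSet, Topology
from .reference import naive_run

__all__ = ["xor_not_model", "random_tiny_model", "frozen_model", "make_fixtures"]


def xor_not_model() -> RBNModel:
    """Two-node hand model: node 0 = XOR of (node 0, node 1), node 1 = NOT
    node 0.  State (1, 0) is a fixed point: 1 XOR 0 = 1, NOT 1 = 0."""
    topology = Topology(in_neighbors=[np.array([0, 1]), np.array([0])])
    rules = RuleSet(bias=np.array([0.5, 0.5]), tables=[np.array([0, 1, 1, 0]), np.array([1, 0])])
    return RBNModel(topology=topology, rules=rules, meta={"name": "xor-not"})


def random_tiny_model(rng: np.random.Generator, n_max: int = 4) -> RBNModel:
    """A random model with N <= n_max, mixed in-degrees (0..N allowed)."""
    n = int(rng.integers(1, n_max + 1))
    out_degrees = rng.integers(0, n + 1, size=n)
    topology = netgen.wire_from_out_degrees(out_degrees, rng)
    biases = netgen.sample_biases(
        netgen.BiasDistributionSpec("uniform", 0.5, domain=(0.0, 1.0)), n, rng
    )
    rules = netgen.build_rules(topology, biases, rng)
    return RBNModel(topology=topology, rules=rules, meta={"name": "tiny-random"})


def frozen_model(n_nodes: int, rng: np.random.Generator, k: int = 2) -> RBNModel:
    """Model whose tables are all constant: it settles to the fixed point
    given by the constants as soon as every node has updated once."""
    topology = netgen.build_regular_topology(n_nodes, k, rng)
    consts = rng.integers(0, 2, size=n_nodes)
    tables = [np.full(2**k, c, dtype=np.uint8) for c in consts]
    return RBNModel(
        topology=topology,
        rules=RuleSet(bias=consts.astype(float), tables=tables),
        meta={"name": "frozen"},
    )


def make_fixtures(seed: int, out_dir, n_models: int = 5, n_steps: int = 20) -> list[pathlib.Path]:
    """Write tiny models, their exhaustively verified synchronous trajectories,
    and a human-readable sidecar of rule tables.  Idempotent for a fixed seed.

    Every emitted trajectory is checked against the naive reference simulator
    for all 2**N initial states before writing; a mismatch raises.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    models = [("xor_not", xor_not_model())]
    models += [(f"tiny{i}", random_tiny_model(rng)) for i in range(n_models - 1)]
    written = []
    for name, model in models:
        schedule = build_schedule("synchronous", model.topology)
        n = model.n_nodes
        for init in itertools.product((0, 1), repeat=n):
            fast = run(model, schedule, np.array(init, dtype=np.uint8), n_steps).states
            slow = naive_run(model, schedule, init, n_steps)
            if not np.array_equal(fast, slow):  # pragma: no cover - safety net
                raise AssertionError(f"engine/reference mismatch for fixture {name}")
        model_path = out_dir / f"{name}.model.json"
        netgen.save_model(model, model_path)
        traj = run(model, schedule, np.zeros(n, dtype=np.uint8), n_steps)
        traj_path = out_dir / f"{name}.trajectory.csv"
        traj.to_csv(traj_path)
        sidecar = {
            "name": name,
            "n_nodes": n,
            "in_neighbors": [lst.tolist() for lst in model.topology.in_neighbors],
            "rule_tables": ["".join(str(int(v)) for v in t) for t in model.rules.tables],
            "note": "table index encodes inputs with the first listed in-neighbor as MSB",
        }
        with open(out_dir / f"{name}.rules.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
        written += [model_path, traj_path]
    return written
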