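"""Naive pure-Python reference simulator.

A transparent, loop-based re-implementation of the update rule used to
cross-validate the vectorized engine on small networks.  Node ``a`` due at
step ``t`` (``t % P_a == 0``) takes the table entry indexed by its
in-neighbors' states at ``t-1``, the first listed in-neighbor being the most
significant bit.  Deliberately simple and slow; not for production runs.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Schedule
from .netgen import RBNModel

__all__ = ["naive_step", "naive_run"]


def naive_step(model: RBNModel, schedule: Schedule, state, t: int) -> list[int]:
    n = model.n_nodes
    state = [int(v) for v in state]
    new = list(state)
    for a in range(n):
        if t % int(schedule.periods[a]) == 0:
            idx = 0
            for nb in model.topology.in_neighbors[a]:
                idx = (idx << 1) | state[int(nb)]
            new[a] = int(model.rules.tables[a][idx])
    return new


def naive_run(model: RBNModel, schedule: Schedule, init, n_steps: int) -> np.ndarray:
    """Unperturbed trajectory as a T x N matrix, row 0 = init."""
    rows = [[int(v) for v in init]]
    state = rows[0]
    for t in range(1, n_steps):
        state = naive_step(model, schedule, state, t)
        rows.append(state)
    return np.array(rows, dtype=np.uint8)
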