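"""Ensemble sweep experiments: complexity-vs-K curves for the eight
homogeneity/heterogeneity combinations, functional and temporal parameter
variations, area-under-curve comparison, and fragility-vs-X/O curves.

Case notation: "Ho" homogeneous / "He" heterogeneous for each of the three
axes S (structural), T (temporal), F (functional).  The default mapping is

    HoS -> Poisson out-degrees        HeS -> exponential out-degrees
    HoT -> synchronous updating       HeT -> out-degree updating (or Ceil)
    HoF -> point bias at 0.5          HeF -> triangular bias, mode 0.5, [0,1]

Seeding is hierarchical: every stochastic component (topology, biases,
tables, initial state, perturbations) of every replicate at every grid point
draws from its own child of the master seed, keyed by a stable path
``(stream, point, replicate, component)``.  Two curves computed with the same
master seed and stream are therefore paired replicate-by-replicate: variants
that share a component spec see identical draws for that component.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import PerturbationProtocol, build_schedule, random_state, run
from .measures import fragility, perturbation_degree, trajectory_complexity
from .netgen import (
    BiasDistributionSpec,
    DegreeDistributionSpec,
    RBNModel,
    RuleSet,
    SpecError,
    build_regular_topology,
    build_rules,
    sample_biases,
    sample_out_degrees,
    wire_from_out_degrees,
)

__all__ = [
    "CaseLabel",
    "CurveResult",
    "all_cases",
    "case_specs",
    "ensemble_complexity",
    "complexity_curve",
    "eight_case_comparison",
    "curve_auc",
    "crossover_k",
    "fragility_point",
    "fragility_curves",
    "functional_variation_suite",
    "temporal_strategy_comparison",
    "plot_curves",
]

logger = logging.getLogger(__name__)

DEFAULT_HEF = BiasDistributionSpec(kind="triangular", mean=0.5, domain=(0.0, 1.0))
HOF = BiasDistributionSpec(kind="point", mean=0.5)

# component ids for seed derivation
_TOPO, _BIAS, _TABLES, _INIT, _PERTURB = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class CaseLabel:
    """One of the eight Ho/He combinations over the S, T, F axes."""

    structural: str = "Ho"
    temporal: str = "Ho"
    functional: str = "Ho"

    def __post_init__(self) -> None:
        for axis in (self.structural, self.temporal, self.functional):
            if axis not in ("Ho", "He"):
                raise SpecError("each axis must be 'Ho' or 'He'")

    @property
    def label(self) -> str:
        trio = (self.structural, self.temporal, self.functional)
        if trio == ("Ho",) * 3:
            return "3Ho"
        if trio == ("He",) * 3:
            return "3He"
        return f"{self.structural}S-{self.temporal}T-{self.functional}F"


def all_cases() -> list[CaseLabel]:
    """The eight combinations, 3Ho first and 3He last."""
    return [
        CaseLabel(structural=s, temporal=t, functional=f)
        for s, t, f in itertools.product(("Ho", "He"), repeat=3)
    ]


def case_specs(
    case: CaseLabel,
    mean_k: float,
    *,
    functional_spec: BiasDistributionSpec | None = None,
    temporal_scheme: str = "out_degree",
) -> tuple[DegreeDistributionSpec, BiasDistributionSpec, str]:
    """Map a case label at average connectivity ``mean_k`` to concrete specs."""
    structural = DegreeDistributionSpec(
        kind="poisson" if case.structural == "Ho" else "exponential", mean_k=mean_k
    )
    functional = HOF if case.functional == "Ho" else (functional_spec or DEFAULT_HEF)
    scheme = "synchronous" if case.temporal == "Ho" else temporal_scheme
    return structural, functional, scheme


@dataclass
class CurveResult:
    """A measured quantity along a swept parameter, with replicate statistics."""

    x_values: np.ndarray
    y_mean: np.ndarray
    y_se: np.ndarray
    n_reps: int
    label: str
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.y_mean = np.asarray(self.y_mean, dtype=float)
        self.y_se = np.asarray(self.y_se, dtype=float)
        if not (self.x_values.size == self.y_mean.size == self.y_se.size):
            raise SpecError("x_values, y_mean and y_se must have equal lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x_values,
                "y_mean": self.y_mean,
                "y_se": self.y_se,
                "n_reps": self.n_reps,
            }
        )

    def to_csv(self, path, *, sidecar: bool = True) -> None:
        """Write the curve as CSV plus a JSON sidecar with full provenance."""
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            with open(f"{path}.json", "w") as fh:
                json.dump({"label": self.label, "config": self.config}, fh, indent=1, sort_keys=True)


def _rng(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _spec_dict(spec) -> dict:
    if isinstance(spec, DegreeDistributionSpec):
        return {"kind": spec.kind, "mean_k": spec.mean_k, "min_degree": spec.min_degree}
    return {"kind": spec.kind, "mean": spec.mean, "sd": spec.sd, "domain": list(spec.domain)}


def _build_model(
    n_nodes: int,
    structural: DegreeDistributionSpec,
    functional: BiasDistributionSpec,
    seed: int,
    key: tuple[int, ...],
) -> RBNModel:
    """Model with component-separated seed streams (paired across variants)."""
    rng_topo = _rng(seed, key + (_TOPO,))
    if structural.kind == "regular":
        topology = build_regular_topology(n_nodes, int(structural.mean_k), rng_topo)
    else:
        out_degrees = sample_out_degrees(structural, n_nodes, rng_topo)
        topology = wire_from_out_degrees(out_degrees, rng_topo)
    biases = sample_biases(functional, n_nodes, _rng(seed, key + (_BIAS,)))
    rules = build_rules(topology, biases, _rng(seed, key + (_TABLES,)))
    return RBNModel(topology=topology, rules=rules)


def _realize_complexity(
    n_nodes: int,
    structural: DegreeDistributionSpec,
    functional: BiasDistributionSpec,
    scheme: str,
    mean_k: float,
    n_steps: int,
    seed: int,
    key: tuple[int, ...],
    ceil_mode: str = "mean_k",
) -> float:
    model = _build_model(n_nodes, structural, functional, seed, key)
    schedule = build_schedule(scheme, model.topology, mean_k=mean_k, ceil_mode=ceil_mode)
    init = random_state(n_nodes, _rng(seed, key + (_INIT,)))
    traj = run(model, schedule, init, n_steps)
    return trajectory_complexity(traj).network_complexity


def ensemble_complexity(
    n_nodes: int,
    structural: DegreeDistributionSpec,
    functional: BiasDistributionSpec,
    scheme: str,
    n_steps: int,
    n_networks: int,
    seed: int,
    *,
    stream: int = 0,
    point: int = 0,
    ceil_mode: str = "mean_k",
) -> np.ndarray:
    """Per-network complexities for ``n_networks`` freshly generated networks,
    one random initial state each, run for ``n_steps``."""
    if n_networks < 1:
        raise SpecError("n_networks must be >= 1")
    return np.array(
        [
            _realize_complexity(
                n_nodes,
                structural,
                functional,
                scheme,
                structural.mean_k,
                n_steps,
                seed,
                (stream, point, j),
                ceil_mode,
            )
            for j in range(n_networks)
        ]
    )


def complexity_curve(
    case: CaseLabel,
    n_nodes: int,
    k_grid,
    n_networks: int,
    n_steps: int,
    seed: int,
    *,
    functional_spec: BiasDistributionSpec | None = None,
    temporal_scheme: str = "out_degree",
    ceil_mode: str = "mean_k",
    stream: int = 0,
    label: str | None = None,
) -> CurveResult:
    """Mean network complexity (with SE) at each connectivity of ``k_grid``.

    At every grid point ``n_networks`` networks are generated per the case
    mapping and run for ``n_steps`` from one random initial state each.
    The paper-scale defaults (45 points at a 0.2 spacing, 1000 networks,
    2000 steps) are all caller-scalable.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0 or np.any(k_grid <= 0):
        raise SpecError("k_grid must contain positive connectivities")
    means, ses = [], []
    for i, k in enumerate(k_grid):
        structural, functional, scheme = case_specs(
            case, float(k), functional_spec=functional_spec, temporal_scheme=temporal_scheme
        )
        values = ensemble_complexity(
            n_nodes,
            structural,
            functional,
            scheme,
            n_steps,
            n_networks,
            seed,
            stream=stream,
            point=i,
            ceil_mode=ceil_mode,
        )
        means.append(values.mean())
        ses.append(values.std(ddof=1) / np.sqrt(values.size) if values.size > 1 else 0.0)
        logger.info(
            "%s K=%.2f: C=%.4f +- %.4f (n=%d)", case.label, k, means[-1], ses[-1], n_networks
        )
    config = {
        "case": case.label,
        "n_nodes": n_nodes,
        "k_grid": k_grid.tolist(),
        "n_networks": n_networks,
        "n_steps": n_steps,
        "seed": seed,
        "stream": stream,
        "temporal_scheme": temporal_scheme,
        "ceil_mode": ceil_mode,
        "functional_spec": _spec_dict(functional_spec or (HOF if case.functional == "Ho" else DEFAULT_HEF)),
    }
    return CurveResult(
        x_values=k_grid,
        y_mean=np.array(means),
        y_se=np.array(ses),
        n_reps=n_networks,
        label=label or case.label,
        config=config,
    )


def eight_case_comparison(
    n_nodes: int,
    k_grid,
    n_networks: int,
    n_steps: int,
    seed: int,
    *,
    functional_spec: BiasDistributionSpec | None = None,
    temporal_scheme: str = "out_degree",
) -> list[CurveResult]:
    """One complexity curve per Ho/He combination, with shared replication
    settings and a shared seed stream (replicate-level pairing)."""
    return [
        complexity_curve(
            case,
            n_nodes,
            k_grid,
            n_networks,
            n_steps,
            seed,
            functional_spec=functional_spec,
            temporal_scheme=temporal_scheme,
            stream=0,
        )
        for case in all_cases()
    ]


def curve_auc(curve: CurveResult) -> float:
    """Trapezoidal area under the curve's mean values."""
    if curve.x_values.size < 2:
        raise SpecError("AUC requires at least 2 grid points")
    return float(np.trapezoid(curve.y_mean, curve.x_values))


def crossover_k(curves: list[CurveResult], reference_label: str) -> float | None:
    """Smallest grid K from which the reference curve's mean strictly exceeds
    every other curve at that point and all later points; None if never."""
    ref = next((c for c in curves if c.label == reference_label), None)
    if ref is None:
        raise SpecError(f"no curve labelled {reference_label!r}")
    others = [c for c in curves if c is not ref]
    for c in others:
        if not np.array_equal(c.x_values, ref.x_values):
            raise SpecError("curves must share the same x grid")
    if not others:
        return float(ref.x_values[0])
    other_max = np.max([c.y_mean for c in others], axis=0)
    dominates = ref.y_mean > other_max
    # last index where domination fails, +1 = first index of the final run
    failing = np.nonzero(~dominates)[0]
    start = 0 if failing.size == 0 else int(failing[-1]) + 1
    if start >= dominates.size:
        return None
    return float(ref.x_values[start])


def fragility_point(
    n_nodes: int,
    structural: DegreeDistributionSpec,
    functional: BiasDistributionSpec,
    scheme: str,
    protocol: PerturbationProtocol,
    n_reps: int,
    seed: int,
    *,
    stream: int = 1,
    point: int = 0,
    ceil_mode: str = "mean_k",
) -> tuple[float, float]:
    """Mean fragility (and SE) over ``n_reps`` freshly generated (model,
    initial state) pairs under the hierarchical seed streams."""
    values = np.empty(n_reps)
    for j in range(n_reps):
        key = (stream, point, j)
        model = _build_model(n_nodes, structural, functional, seed, key)
        schedule = build_schedule(scheme, model.topology, mean_k=structural.mean_k, ceil_mode=ceil_mode)
        init = random_state(n_nodes, _rng(seed, key + (_INIT,)))
        values[j] = fragility(
            model, schedule, init, protocol, _rng(seed, key + (_PERTURB,))
        ).fragility
    se = float(values.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return float(values.mean()), se


def fragility_curves(
    case: CaseLabel,
    n_nodes: int,
    k_values,
    sweep: str,
    fixed: int,
    n_steps: int = 200,
    n_reps: int = 100,
    seed: int = 0,
    *,
    sweep_values=None,
    functional_spec: BiasDistributionSpec | None = None,
    temporal_scheme: str = "out_degree",
) -> list[CurveResult]:
    """Fragility-vs-X (``sweep="vs_X"``, O fixed) or fragility-vs-O
    (``sweep="vs_O"``, X fixed) curves, one per connectivity in ``k_values``.

    Default sweep grids use unit steps: X in 0..N, O in 1..50.
    """
    if sweep not in ("vs_X", "vs_O"):
        raise SpecError("sweep must be 'vs_X' or 'vs_O'")
    k_values = list(k_values)
    if not k_values:
        raise SpecError("k_values must be nonempty")
    if sweep_values is None:
        sweep_values = np.arange(0, n_nodes + 1) if sweep == "vs_X" else np.arange(1, 51)
    sweep_values = np.asarray(sweep_values, dtype=np.int64)
    curves = []
    for ki, k in enumerate(k_values):
        structural, functional, scheme = case_specs(
            case, float(k), functional_spec=functional_spec, temporal_scheme=temporal_scheme
        )
        means, ses = [], []
        for i, v in enumerate(sweep_values):
            x, o = (int(v), fixed) if sweep == "vs_X" else (fixed, int(v))
            protocol = PerturbationProtocol(n_flips=x, period=o, n_steps=n_steps)
            m, s = fragility_point(
                n_nodes,
                structural,
                functional,
                scheme,
                protocol,
                n_reps,
                seed,
                stream=1,
                point=ki * len(sweep_values) + i,
            )
            means.append(m)
            ses.append(s)
            logger.info("%s K=%s %s=%d: A=%.5f +- %.5f", case.label, k, sweep, v, m, s)
        config = {
            "case": case.label,
            "n_nodes": n_nodes,
            "k": k,
            "sweep": sweep,
            "fixed": fixed,
            "sweep_values": sweep_values.tolist(),
            "n_steps": n_steps,
            "n_reps": n_reps,
            "seed": seed,
        }
        curves.append(
            CurveResult(
                x_values=sweep_values.astype(float),
                y_mean=np.array(means),
                y_se=np.array(ses),
                n_reps=n_reps,
                label=f"{case.label} K={k}",
                config=config,
            )
        )
    return curves


def functional_variation_suite(
    variant: str,
    n_nodes: int = 100,
    k_grid=None,
    n_networks: int = 100,
    n_steps: int = 500,
    seed: int = 0,
    *,
    temporal_scheme: str = "out_degree",
) -> list[CurveResult]:
    """Complexity curves for variations of the functional distribution on the
    otherwise fully heterogeneous (3He) base case, with shared seed streams
    across variants for paired comparison.

    Variants: ``distribution_kind`` (point-like, four Gaussians, uniform,
    triangular), ``mean`` (triangular modes 0, 0.25, 0.5, 0.75, 1),
    ``domain_triangular`` / ``domain_uniform`` (nested symmetric domains).
    """
    if k_grid is None:
        k_grid = np.arange(1.0, 10.0, 0.5)
    full = (0.0, 1.0)
    if variant == "distribution_kind":
        specs = [("point-like", BiasDistributionSpec("point", 0.5))]
        specs += [
            (f"gaussian sd={sd}", BiasDistributionSpec("gaussian", 0.5, sd=sd, domain=full))
            for sd in (0.1, 0.25, 0.5, 1.0)
        ]
        specs += [
            ("uniform", BiasDistributionSpec("uniform", 0.5, domain=full)),
            ("triangular", BiasDistributionSpec("triangular", 0.5, domain=full)),
        ]
    elif variant == "mean":
        specs = [
            (f"mu={mu}", BiasDistributionSpec("triangular", mu, domain=full))
            for mu in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
    elif variant in ("domain_triangular", "domain_uniform"):
        kind = "triangular" if variant == "domain_triangular" else "uniform"
        domains = [(0.0, 1.0), (0.1, 0.9), (0.2, 0.8), (0.3, 0.7), (0.4, 0.6)]
        specs = [
            (f"D=[{a},{b}]", BiasDistributionSpec(kind, 0.5, domain=(a, b)))
            for a, b in domains
        ]
    else:
        raise SpecError(f"unknown variant: {variant!r}")
    case = CaseLabel("He", "He", "He")
    return [
        complexity_curve(
            case,
            n_nodes,
            k_grid,
            n_networks,
            n_steps,
            seed,
            functional_spec=spec,
            temporal_scheme=temporal_scheme,
            stream=2,
            label=name,
        )
        for name, spec in specs
    ]


def temporal_strategy_comparison(
    functional: str = "triangular",
    n_nodes: int = 100,
    k_grid=None,
    n_networks: int = 100,
    n_steps: int = 500,
    seed: int = 0,
) -> list[CurveResult]:
    """Out-degree vs Ceil updating under otherwise fully heterogeneous (3He)
    settings, for a triangular or uniform functional distribution."""
    if functional not in ("triangular", "uniform"):
        raise SpecError("functional must be 'triangular' or 'uniform'")
    if k_grid is None:
        k_grid = np.arange(1.0, 10.0, 0.5)
    spec = BiasDistributionSpec(functional, 0.5, domain=(0.0, 1.0))
    case = CaseLabel("He", "He", "He")
    return [
        complexity_curve(
            case,
            n_nodes,
            k_grid,
            n_networks,
            n_steps,
            seed,
            functional_spec=spec,
            temporal_scheme=scheme,
            stream=3,
            label=f"{scheme} ({functional})",
        )
        for scheme in ("out_degree", "ceil")
    ]


def plot_curves(curves: list[CurveResult], path, *, xlabel: str = "K", ylabel: str = "C", title: str | None = None) -> None:
    """Export a simple errorbar plot of one or more curves (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        ax.errorbar(c.x_values, c.y_mean, yerr=c.y_se, label=c.label, capsize=2)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
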