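"""Seeded random-network generators and the benchmark harness.

Every generator is driven by a single ``numpy.random.default_rng(seed)``
instance — no global randomness — so an identical :class:`GeneratorSpec`
always yields a byte-identical edge list.  Self-loops are never generated.

Models
------
``erdos-renyi-np``     every ordered pair (u, v), u != v, is an arc with
                       probability p, independently.
``erdos-renyi-nm``     exactly m distinct arcs drawn uniformly.
``tf-target-bipartite`` arcs only from TF nodes; every target receives at
                       least one incoming arc.
``planted-hub``        one node with arcs to all others plus optional noise
                       arcs; the unique minimum dominating set is the hub.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import resolve_component_policy
from .errors import SolverTimeout
from .graph_model import RegulatoryNetwork
from .mcds_heuristic import run_heuristic
from .mcds_ilp import solve_mcds_ilp
from .mds_ilp import solve_mds
from .result import jaccard

MODELS = ("erdos-renyi-np", "erdos-renyi-nm", "tf-target-bipartite", "planted-hub")
METHODS = ("mds-ilp", "mcds-ilp", "mcds-heuristic")


@dataclass(frozen=True)
class GeneratorSpec:
    model: str
    n: int
    p: float | None = None
    m: int | None = None
    n_tf: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected {MODELS}")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.model in ("erdos-renyi-np", "tf-target-bipartite", "planted-hub"):
            p = 0.0 if self.p is None else self.p
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p must lie in [0, 1], got {p}")
        if self.model == "erdos-renyi-nm":
            if self.m is None or not (0 <= self.m <= self.n * (self.n - 1)):
                raise ValueError(f"m must lie in [0, n(n-1)], got {self.m}")
        if self.model == "tf-target-bipartite":
            if self.n_tf is None or not (1 <= self.n_tf <= self.n):
                raise ValueError("tf-target-bipartite needs 1 <= n_tf <= n")


def _node_names(n: int, prefix: str = "g") -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate(spec: GeneratorSpec) -> RegulatoryNetwork:
    """Materialize the network a spec describes (deterministic per spec)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.model == "erdos-renyi-np":
        names = _node_names(n)
        draws = rng.random((n, n))
        arcs = [
            (names[i], names[j])
            for i in range(n)
            for j in range(n)
            if i != j and draws[i, j] < (spec.p or 0.0)
        ]
        return RegulatoryNetwork.from_arcs(arcs, nodes=names)
    if spec.model == "erdos-renyi-nm":
        names = _node_names(n)
        total = n * (n - 1)
        chosen = rng.choice(total, size=spec.m, replace=False)
        arcs = []
        for flat in sorted(int(c) for c in chosen):
            i, rest = divmod(flat, n - 1)
            j = rest if rest < i else rest + 1  # skip the diagonal
            arcs.append((names[i], names[j]))
        return RegulatoryNetwork.from_arcs(arcs, nodes=names)
    if spec.model == "tf-target-bipartite":
        n_tf = spec.n_tf or 1
        tfs = _node_names(n_tf, prefix="tf")
        targets = _node_names(n - n_tf, prefix="t")
        arcs = []
        for t in targets:
            arcs.append((tfs[int(rng.integers(n_tf))], t))
        p = spec.p or 0.0
        if p > 0:
            draws = rng.random((n_tf, len(targets)))
            for i in range(n_tf):
                for j, t in enumerate(targets):
                    if draws[i, j] < p:
                        arcs.append((tfs[i], t))
        return RegulatoryNetwork.from_arcs(
            arcs,
            nodes=tfs + targets,
            is_tf={v: True for v in tfs} | {v: False for v in targets},
        )
    # planted-hub
    names = _node_names(n)
    hub = names[0]
    arcs = [(hub, v) for v in names[1:]]
    p = spec.p or 0.0
    if p > 0 and n > 1:
        draws = rng.random((n, n))
        for i in range(1, n):
            for j in range(n):
                if i != j and draws[i, j] < p:
                    arcs.append((names[i], names[j]))
    return RegulatoryNetwork.from_arcs(arcs, nodes=names)


def benchmark_grid(
    sizes,
    densities,
    seeds,
    methods=METHODS,
    time_limit: float | None = None,
    max_iterations: int = 1000,
    component_policy: str = "auto",
) -> pd.DataFrame:
    """Run solvers over an Erdős–Rényi (n, p) grid; one row per (instance, method).

    Timeout rows are kept with ``status="timeout"`` and size of the best
    incumbent when one exists.  ``jaccard_vs_ilp`` compares each heuristic
    solution with the exact MCDS on the same instance (NaN when either is
    missing).
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)!r}")
    rows = []
    for n in sizes:
        for p in densities:
            for seed in seeds:
                spec = GeneratorSpec(model="erdos-renyi-np", n=n, p=p, seed=seed)
                net = generate(spec)
                selection = resolve_component_policy(net, component_policy)
                solutions: dict[str, frozenset] = {}
                for method in methods:
                    t0 = time.perf_counter()
                    status, size, iters, genes = "ok", None, None, None
                    try:
                        if method == "mds-ilp":
                            res = solve_mds(net, time_limit=time_limit)
                        elif method == "mcds-ilp":
                            res = solve_mcds_ilp(
                                selection.network,
                                time_limit=time_limit,
                                max_iterations=max_iterations,
                                component_kind=selection.rationale,
                            )
                        else:
                            res = run_heuristic(net, component_policy=component_policy)
                        status = res.status
                        size = res.size
                        iters = res.metadata.get("iterations")
                        genes = res.as_set()
                        solutions[method] = genes
                    except SolverTimeout as exc:
                        status = "timeout"
                        if exc.incumbent is not None:
                            size = exc.incumbent.size
                    rows.append(
                        {
                            "model": "erdos-renyi-np",
                            "n": n,
                            "p": p,
                            "seed": seed,
                            "component": selection.rationale,
                            "component_size": selection.component.size,
                            "method": method,
                            "size": size,
                            "status": status,
                            "iterations": iters,
                            "wall_time": time.perf_counter() - t0,
                        }
                    )
                heur = solutions.get("mcds-heuristic")
                ilp = solutions.get("mcds-ilp")
                jac = jaccard(heur, ilp) if heur is not None and ilp is not None else np.nan
                for row in rows[-len(methods):]:
                    row["jaccard_vs_ilp"] = jac
    return pd.DataFrame(rows)
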