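"""Exact Minimum weakly-Connected Dominating Set via iterative cut generation.

Variables: a binary y_v per node and a binary x_e per edge of the underlying
undirected graph (antiparallel arcs merged — the tree-cardinality constraint
counts each connection once).  The initial relaxation has

    sum_e x_e  =  sum_v y_v - 1          (selected edges form a spanning tree
                                          of the selection, necessary only)
    y_u + sum_{v in in_neighbors(u)} y_v >= 1   for every node u (domination)
    x_e <= y_u,  x_e <= y_v              for every edge e = {u, v}

and is re-solved after adding, for every connected component S of a
disconnected incumbent selection and every j in S, the cut

    sum_{e in E(S)} x_e  <=  sum_{i in S \\ {j}} y_i,

which forces the selected edges inside S to form a forest rooted outside j,
eliminating that disconnected incumbent.  Cuts accumulate across iterations
and the loop stops at the first incumbent whose selection is weakly
connected — by construction the proven optimum of the full program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .components import Component
from .errors import InternalSolverError, SolverTimeout, UsageError
from .graph_model import (
    RegulatoryNetwork,
    UnderlyingUndirectedGraph,
    underlying_undirected,
)
from .result import CONNECTOR, DOMINATOR, DominatingSetResult
from .validity import (
    is_dominating,
    is_weakly_connected_selection,
    weak_components_of_selection,
)

BACKEND = "scipy-highs"


@dataclass
class MCDSIlpState:
    """Variable and constraint bookkeeping for the constraint-generation loop."""

    net: RegulatoryNetwork
    nodes: list[str] = field(init=False)
    edges: list[tuple[str, str]] = field(init=False)
    undirected: UnderlyingUndirectedGraph = field(init=False)
    cut_log: list[tuple[frozenset[str], str]] = field(default_factory=list)
    iteration: int = 0
    incumbents: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = list(self.net.node_order)
        self.undirected = underlying_undirected(self.net)
        idx = {v: i for i, v in enumerate(self.nodes)}
        self.edges = sorted(self.undirected.edges, key=lambda e: (idx[e[0]], idx[e[1]]))
        self._node_idx = idx
        self._edge_idx = {e: i for i, e in enumerate(self.edges)}
        self._cut_keys: set[tuple[frozenset[str], str]] = set()

    # -- constraint assembly ------------------------------------------------

    @property
    def n_vars(self) -> int:
        return len(self.nodes) + len(self.edges)

    def _edge_index(self, u: str, v: str) -> int | None:
        iu, iv = self._node_idx[u], self._node_idx[v]
        e = (u, v) if iu < iv else (v, u)
        return self._edge_idx.get(e)

    def base_constraints(self) -> list[LinearConstraint]:
        n, m = len(self.nodes), len(self.edges)
        # tree cardinality: sum x - sum y = -1
        row = np.concatenate([-np.ones(n), np.ones(m)])
        tree = LinearConstraint(row.reshape(1, -1), lb=-1.0, ub=-1.0)
        # domination: y_u + sum_{v in in(u)} y_v >= 1
        rows, cols = [], []
        for i, u in enumerate(self.nodes):
            rows.append(i)
            cols.append(i)
            for v in self.net.in_neighbors(u):
                rows.append(i)
                cols.append(self._node_idx[v])
        dom = LinearConstraint(
            sp.csc_array(
                (np.ones(len(rows)), (np.array(rows), np.array(cols))),
                shape=(n, self.n_vars),
            ),
            lb=1.0,
            ub=np.inf,
        )
        constraints = [tree, dom]
        # valid inequalities x_e <= y_u and x_e <= y_v
        if m:
            rows, cols, vals = [], [], []
            for j, (u, v) in enumerate(self.edges):
                for r, endpoint in ((2 * j, u), (2 * j + 1, v)):
                    rows += [r, r]
                    cols += [n + j, self._node_idx[endpoint]]
                    vals += [1.0, -1.0]
            edge_caps = LinearConstraint(
                sp.csc_array(
                    (np.array(vals), (np.array(rows), np.array(cols))),
                    shape=(2 * m, self.n_vars),
                ),
                lb=-np.inf,
                ub=0.0,
            )
            constraints.append(edge_caps)
        constraints.extend(self._cut_constraints())
        return constraints

    def _cut_constraints(self) -> list[LinearConstraint]:
        if not self.cut_log:
            return []
        n = len(self.nodes)
        rows, cols, vals = [], [], []
        for r, (s, j) in enumerate(self.cut_log):
            for u in s:
                for v in s:
                    if self._node_idx[u] < self._node_idx[v]:
                        k = self._edge_idx.get((u, v))
                        if k is not None:
                            rows.append(r)
                            cols.append(n + k)
                            vals.append(1.0)
            for i in s:
                if i != j:
                    rows.append(r)
                    cols.append(self._node_idx[i])
                    vals.append(-1.0)
        a = sp.csc_array(
            (np.array(vals), (np.array(rows), np.array(cols))),
            shape=(len(self.cut_log), self.n_vars),
        )
        return [LinearConstraint(a, lb=-np.inf, ub=0.0)]


def check_weak_connectivity(
    selected, graph: UnderlyingUndirectedGraph
) -> list[set[str]]:
    """Connected components of the selection in the underlying undirected graph."""
    selected = set(selected)
    if not selected:
        raise UsageError("empty selection")
    return weak_components_of_selection(selected, graph)


def add_component_cuts(state: MCDSIlpState, components: list[set[str]]) -> MCDSIlpState:
    """Register one cut per (component S, vertex j in S); duplicates are skipped.

    Singleton components yield a vacuous cut (E(S) is empty) which is logged
    anyway — a defensive branch, unreachable under the tree-cardinality
    constraint with two or more selected nodes.
    """
    if len(components) < 2:
        raise UsageError("selection already connected; no cuts to add")
    for s in components:
        fs = frozenset(s)
        for j in sorted(s, key=state._node_idx.__getitem__):
            key = (fs, j)
            if key in state._cut_keys:
                continue
            state._cut_keys.add(key)
            state.cut_log.append(key)
    return state


def split_roles(selected, net: RegulatoryNetwork) -> dict[str, str]:
    """Post-hoc dominator/connector labelling of an MCDS.

    A member is a connector when the rest of the set still dominates the
    graph without it but falls apart (loses weak connectivity) when it is
    removed — i.e. it is kept purely to hold the set together.  Everyone
    else is a dominator.
    """
    sel = set(selected)
    roles = {}
    for v in selected:
        rest = sel - {v}
        if (
            rest
            and is_dominating(rest, net)
            and not is_weakly_connected_selection(rest, net)
        ):
            roles[v] = CONNECTOR
        else:
            roles[v] = DOMINATOR
    return roles


def _as_network(component) -> RegulatoryNetwork:
    if isinstance(component, RegulatoryNetwork):
        return component
    if isinstance(component, Component):
        return RegulatoryNetwork.from_arcs(
            component.induced_arcs, nodes=component.member_nodes
        )
    raise TypeError(f"expected RegulatoryNetwork or Component, got {type(component)}")


def solve_mcds_ilp(
    component,
    time_limit: float | None = None,
    max_iterations: int = 1000,
    component_kind: str | None = None,
) -> DominatingSetResult:
    """Proven-minimum weakly connected dominating set of a connected input.

    ``component`` is a weakly connected :class:`RegulatoryNetwork` or
    :class:`Component` (disconnected input raises ``UsageError`` — run
    component selection first).  ``time_limit`` bounds each backend solve;
    ``max_iterations`` caps the cut-generation loop.
    """
    net = _as_network(component)
    if net.n_nodes == 0:
        raise UsageError("cannot solve MCDS on an empty network")
    if len(weak_components_of_selection(net.node_order, underlying_undirected(net))) > 1:
        raise UsageError(
            "input is not weakly connected; select a component first "
            "(components.select_component)"
        )
    state = MCDSIlpState(net)
    n, m = len(state.nodes), len(state.edges)
    c = np.concatenate([np.ones(n), np.zeros(m)])
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    proven_optimal = True
    while True:
        state.iteration += 1
        if state.iteration > max_iterations:
            incumbent = None
            if state.incumbents:
                last = state.incumbents[-1]
                incumbent = DominatingSetResult(
                    genes=tuple(net.sort_nodes(last)),
                    roles={v: DOMINATOR for v in last},
                    method="mcds-ilp",
                    status="feasible",
                    component_kind=component_kind,
                    metadata={"disconnected": True, "iterations": state.iteration - 1},
                )
            raise SolverTimeout(
                f"cut-generation iteration cap ({max_iterations}) reached",
                incumbent=incumbent,
            )
        res = milp(
            c=c,
            constraints=state.base_constraints(),
            integrality=np.ones(state.n_vars),
            bounds=Bounds(0.0, 1.0),
            options=options,
        )
        if res.status == 2:
            raise InternalSolverError("MCDS relaxation reported infeasible")
        if res.x is None:
            raise SolverTimeout("MCDS time limit expired without an incumbent")
        if res.status != 0:
            proven_optimal = False
        selected = frozenset(
            v for v, yi in zip(state.nodes, res.x[:n]) if yi > 0.5
        )
        state.incumbents.append(selected)
        comps = check_weak_connectivity(selected, state.undirected)
        if len(comps) == 1:
            break
        before = len(state.cut_log)
        add_component_cuts(state, comps)
        if len(state.cut_log) == before:
            raise InternalSolverError(
                "disconnected incumbent produced no new cuts; loop would not terminate"
            )
    genes = tuple(net.sort_nodes(selected))
    result = DominatingSetResult(
        genes=genes,
        roles=split_roles(genes, net),
        method="mcds-ilp",
        status="optimal" if proven_optimal else "feasible",
        component_kind=component_kind,
        metadata={
            "backend": BACKEND,
            "time_limit": time_limit,
            "iterations": state.iteration,
            "cuts_added": len(state.cut_log),
            "incumbent_sizes": [len(s) for s in state.incumbents],
            "n_node_vars": n,
            "n_edge_vars": m,
        },
    )
    if not is_dominating(genes, net) or not is_weakly_connected_selection(genes, net):
        raise InternalSolverError("backend returned an invalid MCDS")
    return result
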