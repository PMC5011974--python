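"""Exact Minimum Dominating Set for directed graphs.

Integer program: one binary indicator x_v per node, one covering constraint
per node u,

    x_u + sum_{v in in_neighbors(u)} x_v >= 1,

minimizing the number of selected nodes.  Solved with the HiGHS
branch-and-cut backend via :func:`scipy.optimize.milp`, which proves
optimality.  No preprocessing is applied: isolated nodes and nodes with no
in-neighbors are forced into the solution by their own covering constraint.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import InternalSolverError, SolverTimeout, UsageError
from .graph_model import RegulatoryNetwork
from .result import DOMINATOR, DominatingSetResult
from .validity import is_dominating

BACKEND = "scipy-highs"


def build_mds_model(net: RegulatoryNetwork):
    """Covering-constraint matrix for the MDS integer program.

    Returns ``(nodes, A)`` where row u of the sparse matrix ``A`` has ones at
    u itself and at every in-neighbor of u (|V| variables, |V| constraints).
    """
    nodes = list(net.node_order)
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for i, u in enumerate(nodes):
        rows.append(i)
        cols.append(i)
        for v in net.in_neighbors(u):
            rows.append(i)
            cols.append(idx[v])
    n = len(nodes)
    a = sp.csc_array(
        (np.ones(len(rows)), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    return nodes, a


def solve_mds(
    net: RegulatoryNetwork,
    time_limit: float | None = None,
    tf_only: bool = False,
) -> DominatingSetResult:
    """Proven-minimum directed dominating set of ``net``.

    ``tf_only`` restricts candidate dominators to nodes flagged as
    transcription factors; the model may then be infeasible (a non-TF node
    with no TF regulator cannot be covered), which raises ``UsageError``.
    """
    if net.n_nodes == 0:
        raise UsageError("cannot solve MDS on an empty network")
    nodes, a = build_mds_model(net)
    n = len(nodes)
    ub = np.ones(n)
    if tf_only:
        for i, v in enumerate(nodes):
            if not net.is_tf.get(v, False):
                ub[i] = 0.0
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=np.ones(n),
        constraints=[LinearConstraint(a, lb=1.0, ub=np.inf)],
        integrality=np.ones(n),
        bounds=Bounds(np.zeros(n), ub),
        options=options,
    )
    if res.status == 2:  # infeasible
        if tf_only:
            raise UsageError(
                "no dominating set exists with dominators restricted to TFs"
            )
        raise InternalSolverError(
            "MDS model reported infeasible, but V itself is always feasible"
        )
    if res.x is None:
        raise SolverTimeout("MDS time limit expired without an incumbent")
    selected = tuple(v for v, xi in zip(nodes, res.x) if xi > 0.5)
    status = "optimal" if res.status == 0 else "feasible"
    result = DominatingSetResult(
        genes=selected,
        roles={v: DOMINATOR for v in selected},
        method="mds-ilp",
        status=status,
        metadata={
            "backend": BACKEND,
            "time_limit": time_limit,
            "tf_only": tf_only,
            "n_variables": n,
            "n_constraints": n,
        },
    )
    if not is_dominating(result.genes, net):
        raise InternalSolverError("backend returned a non-dominating solution")
    return result
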