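"""Brute-force reference solvers for certifying the optimizers on small inputs.

Subsets are enumerated in increasing cardinality; the first feasible
cardinality is the optimum and every feasible subset of that cardinality is
recorded as a witness.  No pruning beyond the cardinality ordering — clarity
over speed — so hard size guards apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .errors import UsageError
from .graph_model import RegulatoryNetwork, underlying_undirected
from .validity import is_dominating, weak_components_of_selection

MDS_MAX_NODES = 15
MCDS_MAX_NODES = 12


@dataclass(frozen=True)
class OracleResult:
    minimum_size: int
    optimal_sets: tuple[tuple[str, ...], ...]  # lexicographically sorted witnesses
    subsets_examined: int


def _enumerate(net: RegulatoryNetwork, feasible, start: int) -> OracleResult:
    nodes = list(net.node_order)
    examined = 0
    for r in range(start, len(nodes) + 1):
        witnesses = []
        for subset in combinations(nodes, r):
            examined += 1
            if feasible(set(subset)):
                witnesses.append(tuple(sorted(subset)))
        if witnesses:
            return OracleResult(
                minimum_size=r,
                optimal_sets=tuple(sorted(witnesses)),
                subsets_examined=examined,
            )
    raise UsageError("no feasible subset exists")  # unreachable for domination


def brute_force_mds(net: RegulatoryNetwork) -> OracleResult:
    """Exact directed MDS by exhaustive enumeration (|V| <= 15)."""
    if net.n_nodes == 0:
        raise UsageError("empty network")
    if net.n_nodes > MDS_MAX_NODES:
        raise UsageError(
            f"brute-force MDS is guarded at {MDS_MAX_NODES} nodes, got {net.n_nodes}"
        )
    return _enumerate(net, lambda s: is_dominating(s, net), start=0)


def brute_force_mcds(net: RegulatoryNetwork) -> OracleResult:
    """Exact directed weakly-connected MDS by enumeration (|V| <= 12)."""
    if net.n_nodes == 0:
        raise UsageError("empty network")
    if net.n_nodes > MCDS_MAX_NODES:
        raise UsageError(
            f"brute-force MCDS is guarded at {MCDS_MAX_NODES} nodes, got {net.n_nodes}"
        )
    ug = underlying_undirected(net)
    if len(weak_components_of_selection(net.node_order, ug)) > 1:
        raise UsageError("input is not weakly connected; no MCDS exists")

    def feasible(s: set[str]) -> bool:
        return (
            is_dominating(s, net)
            and len(weak_components_of_selection(s, ug)) == 1
        )

    return _enumerate(net, feasible, start=1)
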