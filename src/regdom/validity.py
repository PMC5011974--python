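"""Independent validity checkers for dominating-set solutions.

These are deliberately simple, definition-level checks used both by callers
and by the solvers' own post-conditions; the test suite additionally
cross-checks them against brute force.
"""

from __future__ import annotations

from typing import Iterable

from .graph_model import RegulatoryNetwork, UnderlyingUndirectedGraph, underlying_undirected


def is_dominating(selected: Iterable[str], net: RegulatoryNetwork) -> bool:
    """True iff every node of ``net`` is selected or has a selected in-neighbor."""
    selected = set(selected)
    for v in net.node_order:
        if v in selected:
            continue
        if not (net.in_neighbors(v) & selected):
            return False
    return True


def uncovered_nodes(selected: Iterable[str], net: RegulatoryNetwork) -> list[str]:
    """Nodes neither selected nor dominated, in input order."""
    selected = set(selected)
    return [
        v
        for v in net.node_order
        if v not in selected and not (net.in_neighbors(v) & selected)
    ]


def weak_components_of_selection(
    selected: Iterable[str], graph: UnderlyingUndirectedGraph
) -> list[set[str]]:
    """Connected components of the undirected subgraph induced by ``selected``.

    Plain iterative BFS; component order follows the graph's node order.
    """
    selected = set(selected)
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in graph.node_order:
        if start not in selected or start in seen:
            continue
        comp = {start}
        queue = [start]
        seen.add(start)
        while queue:
            v = queue.pop()
            for w in graph.neighbors(v):
                if w in selected and w not in seen:
                    seen.add(w)
                    comp.add(w)
                    queue.append(w)
        comps.append(comp)
    return comps


def is_weakly_connected_selection(
    selected: Iterable[str], net: RegulatoryNetwork
) -> bool:
    """True iff the selected nodes induce a weakly connected (nonempty) subgraph."""
    selected = set(selected)
    if not selected:
        return False
    return len(weak_components_of_selection(selected, underlying_undirected(net))) == 1
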