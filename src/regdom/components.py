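"""Strong/weak component decomposition and the component-selection rule.

A connected dominating set only exists on a connected input, so when a
network is not weakly connected the solver must be pointed at a component.
The selection rule: if the whole network is weakly connected use it as-is;
otherwise compare the densities of the largest weakly connected component
(LCC) and the largest strongly connected component (LSCC) and take the
denser one (density ties favour the LCC, which covers more of the network).

Component density is |arcs| / (n * (n - 1)); singletons get density 0
(their MCDS problem is trivial and the formula would divide by zero).
Self-loops are excluded from the arc count so that density stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import UsageError
from .graph_model import Arc, RegulatoryNetwork, underlying_undirected

SCC = "SCC"
WCC = "WCC"


@dataclass(frozen=True)
class Component:
    """A node-induced subnetwork tagged with how it was found."""

    member_nodes: tuple[str, ...]  # in first-appearance order of the parent
    kind: str  # SCC | WCC
    induced_arcs: frozenset[Arc]
    density: float

    @property
    def size(self) -> int:
        return len(self.member_nodes)


@dataclass(frozen=True)
class ComponentSelection:
    component: Component
    rationale: str  # whole | lcc | lscc
    network: RegulatoryNetwork  # induced subnetwork ready for a solver


def _make_component(net: RegulatoryNetwork, members: set[str], kind: str) -> Component:
    ordered = tuple(net.sort_nodes(members))
    induced = frozenset(
        (u, v) for (u, v) in net.arcs if u in members and v in members
    )
    n = len(members)
    if n < 2:
        density = 0.0
    else:
        n_arcs = sum(1 for (u, v) in induced if u != v)
        density = n_arcs / (n * (n - 1))
    return Component(
        member_nodes=ordered, kind=kind, induced_arcs=induced, density=density
    )


def _sorted_components(net: RegulatoryNetwork, comps: list[Component]) -> list[Component]:
    # size descending, ties by earliest first-appearance member
    return sorted(
        comps,
        key=lambda c: (-c.size, min(net.order_index(v) for v in c.member_nodes)),
    )


def strongly_connected_components(net: RegulatoryNetwork) -> list[Component]:
    """Partition into strongly connected components (Tarjan-style).

    Sorted by size descending; ties broken by the earliest-appearing member.
    """
    g = net.to_networkx()
    comps = [_make_component(net, set(s), SCC) for s in nx.strongly_connected_components(g)]
    return _sorted_components(net, comps)


def weakly_connected_components(net: RegulatoryNetwork) -> list[Component]:
    """Partition by connectivity of the underlying undirected graph."""
    g = net.to_networkx()
    comps = [_make_component(net, set(s), WCC) for s in nx.weakly_connected_components(g)]
    return _sorted_components(net, comps)


def component_network(net: RegulatoryNetwork, component: Component) -> RegulatoryNetwork:
    """The induced subnetwork of ``net`` on a component's members."""
    return net.subnetwork(component.member_nodes)


def select_component(net: RegulatoryNetwork) -> ComponentSelection:
    """Pick the part of the network on which a connected dominating set is solved.

    Returns the whole network (as a WCC-kind component) when it is weakly
    connected; otherwise the denser of LCC and LSCC, preferring the LCC on a
    density tie.
    """
    if net.n_nodes == 0:
        raise UsageError("cannot select a component of an empty network")
    wccs = weakly_connected_components(net)
    if wccs[0].size == net.n_nodes:
        return ComponentSelection(
            component=wccs[0], rationale="whole", network=net
        )
    lcc = wccs[0]
    lscc = strongly_connected_components(net)[0]
    if lscc.density > lcc.density:
        chosen, rationale = lscc, "lscc"
    else:
        chosen, rationale = lcc, "lcc"
    return ComponentSelection(
        component=chosen,
        rationale=rationale,
        network=component_network(net, chosen),
    )


def resolve_component_policy(net: RegulatoryNetwork, policy: str) -> ComponentSelection:
    """Resolve ``auto|whole|lcc|lscc`` into a concrete selection."""
    if policy == "auto":
        return select_component(net)
    if net.n_nodes == 0:
        raise UsageError("empty network")
    if policy == "whole":
        wccs = weakly_connected_components(net)
        if wccs[0].size != net.n_nodes:
            raise UsageError(
                "network is not weakly connected; use --component auto|lcc|lscc"
            )
        return ComponentSelection(component=wccs[0], rationale="whole", network=net)
    if policy == "lcc":
        lcc = weakly_connected_components(net)[0]
        return ComponentSelection(
            component=lcc, rationale="lcc", network=component_network(net, lcc)
        )
    if policy == "lscc":
        lscc = strongly_connected_components(net)[0]
        return ComponentSelection(
            component=lscc, rationale="lscc", network=component_network(net, lscc)
        )
    raise UsageError(f"unknown component policy {policy!r}")


def is_weakly_connected(net: RegulatoryNetwork) -> bool:
    if net.n_nodes == 0:
        return False
    return len(weak_components(net)) == 1


def weak_components(net: RegulatoryNetwork) -> list[set[str]]:
    """Weak components as plain node sets (no Component wrapper)."""
    from .validity import weak_components_of_selection

    return weak_components_of_selection(
        net.node_order, underlying_undirected(net)
    )
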