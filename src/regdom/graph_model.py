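"""Directed regulatory-network data model and format readers/writers.

The central type is :class:`RegulatoryNetwork`: an immutable directed graph
over opaque gene-identifier strings, with an optional transcription-factor
flag per node and an optional sign label per arc.  Node identity is the
verbatim, case-sensitive string; the order of first appearance in the input
is recorded and used as the final tie-break in every downstream algorithm so
that outputs are deterministic.

Self-loops (autoregulation) are kept as data but are excluded from
neighborhoods, degrees and the underlying undirected edge set: a self-loop
can never make a non-selected gene dominated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import NetworkParseError, UsageError

FORMATS = ("tsv-edgelist", "sif", "graphml")

Arc = tuple[str, str]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed gene regulatory network.

    Parameters
    ----------
    node_order:
        All nodes, in order of first appearance in the source.
    arcs:
        Set of (regulator, target) pairs; a set, never a multiset.
    is_tf:
        Optional transcription-factor flag per node (absent nodes -> unknown).
    arc_sign:
        Optional label per arc (activation/inhibition/...), carried through
        but never consulted by any solver.
    """

    node_order: tuple[str, ...]
    arcs: frozenset[Arc]
    is_tf: Mapping[str, bool] = field(default_factory=dict)
    arc_sign: Mapping[Arc, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = set(self.node_order)
        if len(self.node_order) != len(nodes):
            raise ValueError("duplicate entries in node_order")
        for u, v in self.arcs:
            if u not in nodes or v not in nodes:
                raise ValueError(f"arc ({u!r}, {v!r}) has endpoint outside node set")
        # adjacency caches; object.__setattr__ because the dataclass is frozen
        succ: dict[str, set[str]] = {v: set() for v in self.node_order}
        pred: dict[str, set[str]] = {v: set() for v in self.node_order}
        for u, v in self.arcs:
            if u != v:  # self-loops excluded from neighborhoods
                succ[u].add(v)
                pred[v].add(u)
        object.__setattr__(self, "_succ", succ)
        object.__setattr__(self, "_pred", pred)
        object.__setattr__(
            self, "_order_index", {v: i for i, v in enumerate(self.node_order)}
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arcs(
        cls,
        arcs: Iterable[Arc],
        nodes: Iterable[str] = (),
        is_tf: Mapping[str, bool] | None = None,
        arc_sign: Mapping[Arc, str] | None = None,
    ) -> "RegulatoryNetwork":
        """Build a network from an arc iterable.

        ``nodes`` may supply extra (possibly isolated) nodes and controls
        first-appearance order for the nodes it lists; arc endpoints not in
        ``nodes`` are appended in the order they appear in ``arcs``.
        """
        order: list[str] = []
        seen: set[str] = set()
        for v in nodes:
            if v not in seen:
                seen.add(v)
                order.append(v)
        arc_list = []
        for u, v in arcs:
            arc_list.append((u, v))
            for w in (u, v):
                if w not in seen:
                    seen.add(w)
                    order.append(w)
        return cls(
            node_order=tuple(order),
            arcs=frozenset(arc_list),
            is_tf=dict(is_tf or {}),
            arc_sign=dict(arc_sign or {}),
        )

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.node_order)

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def order_index(self, v: str) -> int:
        """Position of ``v`` in first-appearance order (the global tie-break)."""
        return self._order_index[v]

    def sort_nodes(self, nodes: Iterable[str]) -> list[str]:
        """Sort a node iterable by first-appearance order."""
        return sorted(nodes, key=self._order_index.__getitem__)

    def in_neighbors(self, v: str) -> set[str]:
        """Nodes ``u`` with an arc (u, v); self-loops excluded."""
        if v not in self._order_index:
            raise KeyError(f"unknown node {v!r}")
        return set(self._pred[v])

    def out_neighbors(self, v: str) -> set[str]:
        """Nodes ``w`` with an arc (v, w); self-loops excluded."""
        if v not in self._order_index:
            raise KeyError(f"unknown node {v!r}")
        return set(self._succ[v])

    def in_degree(self, v: str) -> int:
        return len(self._pred[v])

    def out_degree(self, v: str) -> int:
        return len(self._succ[v])

    # -- derived graphs ----------------------------------------------------

    def subnetwork(self, members: Iterable[str]) -> "RegulatoryNetwork":
        """Node-induced subnetwork, preserving first-appearance order."""
        members = set(members)
        unknown = members - set(self.node_order)
        if unknown:
            raise KeyError(f"unknown nodes: {sorted(unknown)!r}")
        order = tuple(v for v in self.node_order if v in members)
        arcs = frozenset(
            (u, v) for (u, v) in self.arcs if u in members and v in members
        )
        return RegulatoryNetwork(
            node_order=order,
            arcs=arcs,
            is_tf={v: f for v, f in self.is_tf.items() if v in members},
            arc_sign={a: s for a, s in self.arc_sign.items() if a in arcs},
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_order)
        g.add_edges_from(self.arcs)
        return g


@dataclass(frozen=True)
class UnderlyingUndirectedGraph:
    """The undirected graph obtained by forgetting arc directions.

    Antiparallel arcs merge into one edge; self-loops are dropped.  Each
    edge is stored once as ``(u, v)`` with ``u`` before ``v`` in
    first-appearance order.
    """

    node_order: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        adj: dict[str, set[str]] = {v: set() for v in self.node_order}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        object.__setattr__(self, "_adj", adj)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v: str) -> set[str]:
        return set(self._adj[v])


def underlying_undirected(net: RegulatoryNetwork) -> UnderlyingUndirectedGraph:
    """Forget direction: one undirected edge per adjacent unordered pair."""
    idx = {v: i for i, v in enumerate(net.node_order)}
    edges = set()
    for u, v in net.arcs:
        if u == v:
            continue
        edges.add((u, v) if idx[u] < idx[v] else (v, u))
    return UnderlyingUndirectedGraph(node_order=net.node_order, edges=frozenset(edges))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise UsageError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def read_network(path: str | os.PathLike, fmt: str = "tsv-edgelist") -> RegulatoryNetwork:
    """Read a directed network from ``path`` in the named dialect.

    Duplicate arc lines collapse to a single arc.  Raises
    :class:`NetworkParseError` (with a line number for the text dialects) on
    malformed input and :class:`UsageError` on an unknown format name.
    """
    _check_format(fmt)
    if fmt == "graphml":
        return _read_graphml(path)
    arcs: list[Arc] = []
    signs: dict[Arc, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split("\t")
            if fmt == "tsv-edgelist":
                if lineno == 1 and len(tokens) >= 2 and (
                    tokens[0].strip().lower() == "regulator"
                    and tokens[1].strip().lower() == "target"
                ):
                    continue  # header row
                if len(tokens) not in (2, 3) or not tokens[0] or not tokens[1]:
                    raise NetworkParseError(
                        f"expected 'regulator<TAB>target[<TAB>sign]', got {line!r}",
                        line_number=lineno,
                    )
                u, v = tokens[0], tokens[1]
                if len(tokens) == 3 and tokens[2]:
                    signs[(u, v)] = tokens[2]
            else:  # sif
                if len(tokens) != 3 or not all(tokens):
                    raise NetworkParseError(
                        f"expected 'source<TAB>relation<TAB>target', got {line!r}",
                        line_number=lineno,
                    )
                u, v = tokens[0], tokens[2]
                signs[(u, v)] = tokens[1]
            arcs.append((u, v))
    return RegulatoryNetwork.from_arcs(arcs, arc_sign=signs)


def _read_graphml(path: str | os.PathLike) -> RegulatoryNetwork:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # malformed XML etc.
        raise NetworkParseError(f"cannot parse GraphML: {exc}") from exc
    g = g.to_directed(as_view=False) if not g.is_directed() else g
    arcs = []
    signs = {}
    is_tf = {}
    for u, v, data in g.edges(data=True):
        arcs.append((str(u), str(v)))
        if "sign" in data:
            signs[(str(u), str(v))] = str(data["sign"])
    for v, data in g.nodes(data=True):
        if "is_tf" in data:
            is_tf[str(v)] = bool(data["is_tf"]) and str(data["is_tf"]).lower() not in (
                "false",
                "0",
            )
    return RegulatoryNetwork.from_arcs(
        arcs, nodes=[str(v) for v in g.nodes], is_tf=is_tf, arc_sign=signs
    )


def write_network(
    net: RegulatoryNetwork, path: str | os.PathLike, fmt: str = "tsv-edgelist"
) -> None:
    """Write ``net`` to ``path``; arc order is deterministic (input order)."""
    _check_format(fmt)
    key = lambda a: (net.order_index(a[0]), net.order_index(a[1]))  # noqa: E731
    arcs = sorted(net.arcs, key=key)
    if fmt == "graphml":
        g = nx.DiGraph()
        for v in net.node_order:
            if v in net.is_tf:
                g.add_node(v, is_tf=bool(net.is_tf[v]))
            else:
                g.add_node(v)
        for u, v in arcs:
            if (u, v) in net.arc_sign:
                g.add_edge(u, v, sign=net.arc_sign[(u, v)])
            else:
                g.add_edge(u, v)
        nx.write_graphml(g, path)
        return
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in arcs:
            sign = net.arc_sign.get((u, v))
            if fmt == "tsv-edgelist":
                fh.write(f"{u}\t{v}\t{sign}\n" if sign else f"{u}\t{v}\n")
            else:  # sif
                fh.write(f"{u}\t{sign or 'regulates'}\t{v}\n")
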