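"""Three-phase greedy heuristic for directed weakly-connected dominating sets.

Node colors: white = uncovered, gray = dominated, black = dominator,
dark gray = connector.

Phase 1 repeatedly turns the most useful white node black (by default the
one covering the most still-white out-neighbors; optionally by static
out-degree) and grays its white out-neighbors, until nothing is white.
Phase 2 glues the black nodes together: while the black/dark-gray structure
has more than one weak component, the outside node adjacent (either arc
direction) to the most structure members is colored dark gray.  Phase 3
prunes: nodes are scanned in ascending out-degree and removed whenever the
remainder still dominates the graph and stays weakly connected, restarting
the scan after every removal.

All ties fall through the same cascade — phase-specific degree rules first,
then order of first appearance in the input — so a given input file always
produces the identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .components import resolve_component_policy
from .errors import UsageError
from .graph_model import RegulatoryNetwork, underlying_undirected
from .result import CONNECTOR, DOMINATOR, DominatingSetResult
from .validity import is_dominating, weak_components_of_selection

WHITE = "white"
GRAY = "gray"
BLACK = "black"
DARKGRAY = "darkgray"


@dataclass
class ColoringState:
    """Mutable per-node coloring plus an append-only trace of color changes."""

    colors: dict[str, str]
    trace: list[tuple[str, str]] = field(default_factory=list)

    def set_color(self, node: str, color: str) -> None:
        self.colors[node] = color
        self.trace.append((node, color))

    def of(self, color: str) -> set[str]:
        return {v for v, c in self.colors.items() if c == color}

    def structure(self) -> set[str]:
        """Current connected-dominating-set candidates (black + dark gray)."""
        return {v for v, c in self.colors.items() if c in (BLACK, DARKGRAY)}


def phase1_dominators(net: RegulatoryNetwork, rank: str = "coverage") -> ColoringState:
    """Greedy dominator selection until no node is white.

    ``rank="coverage"`` scores a white node by its number of still-white
    out-neighbors; ``rank="static"`` uses its static out-degree.  Ties break
    by higher in-degree, then first-appearance order.
    """
    if rank not in ("coverage", "static"):
        raise UsageError(f"unknown phase-1 ranking {rank!r}")
    state = ColoringState(colors={v: WHITE for v in net.node_order})
    white = set(net.node_order)
    while white:
        def score(v: str) -> tuple:
            gain = (
                len(net.out_neighbors(v) & white)
                if rank == "coverage"
                else net.out_degree(v)
            )
            return (-gain, -net.in_degree(v), net.order_index(v))

        pick = min(white, key=score)
        state.set_color(pick, BLACK)
        white.discard(pick)
        for w in net.out_neighbors(pick):
            if w in white:
                state.set_color(w, GRAY)
                white.discard(w)
    return state


def phase2_connectors(state: ColoringState, net: RegulatoryNetwork) -> ColoringState:
    """Add connector nodes until the structure is one weak component.

    The pick is the outside node adjacent (ignoring arc direction) to the
    most structure members; ties break by higher out-degree, then higher
    in-degree, then first-appearance order.  Requires a weakly connected
    input, otherwise no amount of connectors can ever finish.
    """
    ug = underlying_undirected(net)
    if len(weak_components_of_selection(net.node_order, ug)) > 1:
        raise UsageError("input component is not weakly connected")
    structure = state.structure()
    while len(weak_components_of_selection(structure, ug)) > 1:
        outside = [v for v in net.node_order if v not in structure]

        def score(v: str) -> tuple:
            adjacency = len(ug.neighbors(v) & structure)
            return (
                -adjacency,
                -net.out_degree(v),
                -net.in_degree(v),
                net.order_index(v),
            )

        pick = min(outside, key=score)
        state.set_color(pick, DARKGRAY)
        structure.add(pick)
    return state


def phase3_prune(state: ColoringState, net: RegulatoryNetwork) -> DominatingSetResult:
    """Remove redundant members, smallest out-degree first, to a fixed point.

    A member is removable when the remaining structure is still a directed
    dominating set of the component and still induces a weakly connected
    subgraph.  The scan restarts after every removal.  Removed members are
    re-colored gray (they are necessarily dominated by what remains).
    """
    ug = underlying_undirected(net)
    structure = state.structure()
    removed = 0
    changed = True
    while changed:
        changed = False
        candidates = sorted(
            structure,
            key=lambda v: (net.out_degree(v), -net.in_degree(v), net.order_index(v)),
        )
        for v in candidates:
            rest = structure - {v}
            if not rest:
                continue
            if is_dominating(rest, net) and len(
                weak_components_of_selection(rest, ug)
            ) == 1:
                state.set_color(v, GRAY)
                structure = rest
                removed += 1
                changed = True
                break
    roles = {}
    for v in structure:
        roles[v] = DOMINATOR if state.colors[v] == BLACK else CONNECTOR
    genes = tuple(net.sort_nodes(structure))
    return DominatingSetResult(
        genes=genes,
        roles=roles,
        method="mcds-heuristic",
        status="heuristic",
        metadata={
            "n_dominators": sum(1 for r in roles.values() if r == DOMINATOR),
            "n_connectors": sum(1 for r in roles.values() if r == CONNECTOR),
            "n_pruned": removed,
        },
    )


def run_heuristic(
    net: RegulatoryNetwork,
    component_policy: str = "auto",
    rank: str = "coverage",
) -> DominatingSetResult:
    """Component selection followed by the three phases.

    Returns the heuristic connected dominating set of the selected
    component, with per-phase tallies and the selection rationale recorded
    in the result metadata.
    """
    selection = resolve_component_policy(net, component_policy)
    comp_net = selection.network
    state = phase1_dominators(comp_net, rank=rank)
    n_phase1 = len(state.of(BLACK))
    state = phase2_connectors(state, comp_net)
    n_phase2 = len(state.of(DARKGRAY))
    result = phase3_prune(state, comp_net)
    metadata = dict(result.metadata)
    metadata.update(
        {
            "component": selection.rationale,
            "component_size": selection.component.size,
            "component_density": selection.component.density,
            "phase1_black": n_phase1,
            "phase2_darkgray": n_phase2,
            "rank": rank,
            "trace": tuple(state.trace),
        }
    )
    return DominatingSetResult(
        genes=result.genes,
        roles=result.roles,
        method=result.method,
        status=result.status,
        component_kind=selection.rationale,
        metadata=metadata,
    )
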