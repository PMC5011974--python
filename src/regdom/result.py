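"""Solution container shared by the exact and heuristic solvers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

DOMINATOR = "dominator"
CONNECTOR = "connector"


@dataclass(frozen=True)
class DominatingSetResult:
    """A (connected) dominating set with per-node roles and provenance.

    ``genes`` is ordered by first appearance in the input network.  ``roles``
    maps each member to ``"dominator"`` or ``"connector"``.  ``status`` is
    ``"optimal"`` (proven), ``"feasible"`` (exact solver stopped early) or
    ``"heuristic"``.  ``component_kind`` records which part of the network
    was solved (``"whole"``, ``"lcc"`` or ``"lscc"``); ``None`` when the
    caller passed a bare graph.  ``metadata`` holds solver bookkeeping
    (iteration counts, per-phase tallies, backend name, ...) sufficient to
    reproduce the run.
    """

    genes: tuple[str, ...]
    roles: Mapping[str, str]
    method: str
    status: str
    component_kind: str | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def dominators(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.roles[g] == DOMINATOR)

    @property
    def connectors(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.roles[g] == CONNECTOR)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def jaccard(a, b) -> float:
    """Jaccard index |A∩B| / |A∪B|; 1.0 for two empty sets."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
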