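"""Hypergeometric overlap significance and Benjamini-Hochberg adjustment.

The test asks how surprising it is to see ``x`` annotated genes in a result
set of size ``N`` drawn without replacement from a network of ``M`` genes of
which ``k`` are annotated.  Two tail conventions are provided:

* ``inclusive-tail``: P(X >= x) = 1 - sum_{i=0}^{x-1} pmf(i)  (default)
* ``strict-tail``:    P(X > x)  = 1 - sum_{i=0}^{x}   pmf(i)

The inclusive tail is the standard enrichment convention (the observed
overlap counts as evidence); the strict tail is kept as an option because
some sources print the formula that way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

CONVENTIONS = ("inclusive-tail", "strict-tail")


@dataclass(frozen=True)
class HypergeomCounts:
    """Population M, annotated-in-population k, sample N, annotated-in-sample x."""

    M: int
    k: int
    N: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.M):
            raise ValueError(f"need 0 <= k <= M, got k={self.k}, M={self.M}")
        if not (0 <= self.N <= self.M):
            raise ValueError(f"need 0 <= N <= M, got N={self.N}, M={self.M}")
        if not (0 <= self.x <= min(self.N, self.k)):
            raise ValueError(
                f"need 0 <= x <= min(N, k), got x={self.x}, N={self.N}, k={self.k}"
            )


def hypergeom_pvalue(
    counts: HypergeomCounts, convention: str = "inclusive-tail"
) -> float:
    """Upper-tail hypergeometric p-value under the chosen convention."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected {CONVENTIONS}")
    cutoff = counts.x - 1 if convention == "inclusive-tail" else counts.x
    p = float(hypergeom.sf(cutoff, counts.M, counts.k, counts.N))
    return min(1.0, max(0.0, p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR), input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
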