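# regdom

Identification of key-player and master-regulator genes in directed gene
regulatory networks via **Minimum Dominating Sets (MDS)** and **Minimum
weakly-Connected Dominating Sets (MCDS)**.

A node set *D* dominates a directed network when every gene is in *D* or is
regulated by a member of *D*; an MCDS additionally induces a weakly
connected subgraph (dominators plus the connectors holding them together).
The package provides:

- `graph_model` — directed-network data model; TSV edge-list, SIF and
  GraphML readers/writers; deterministic first-appearance node ordering.
- `components` — strong/weak component decomposition and the
  density-based rule choosing between the whole network, the largest weak
  component (LCC) and the largest strong component (LSCC).
- `mds_ilp` — exact MDS: one covering constraint per node, solved to
  proven optimality with the HiGHS backend (`scipy.optimize.milp`).
- `mcds_ilp` — exact MCDS: node and edge indicator variables, a
  spanning-tree cardinality constraint, valid inequalities `x_e <= y_u`,
  `x_e <= y_v`, and iterative generation of connectivity cuts
  (one per connected component of a disconnected incumbent and vertex in it).
- `mcds_heuristic` — three-phase greedy heuristic with white / gray /
  black / dark-gray coloring: greedy domination, connector insertion,
  smallest-out-degree pruning. Fully deterministic tie-breaking.
- `stats` — hypergeometric overlap test (inclusive tail `P(X >= x)` by
  default, strict tail optional) and Benjamini–Hochberg adjustment.
- `synthetic` — seeded Erdős–Rényi / bipartite / planted-hub generators
  and a benchmark grid comparing the solvers (sizes, Jaccard overlap).
- `oracle` — brute-force reference solvers (size-guarded) certifying the
  optimizers on small instances.

## CLI

A single entry point `regdom` with subcommands:

```bash
# component decomposition (TSV: id, kind, size, density, members)
regdom components --input net.tsv

# exact minimum dominating set of the whole network
regdom mds --input net.tsv --output mds.tsv

# minimum connected dominating set of the auto-selected component
regdom mcds --method ilp --input net.tsv --component auto
regdom mcds --method heuristic --input net.tsv --trace

# significance of an overlap (inclusive upper tail)
regdom hypergeom --M 176 --k 15 --N 29 --x 7        # -> 0.004
regdom bh-adjust pvalues.txt

# seeded synthetic networks and solver benchmarks
regdom generate --model erdos-renyi-np --n 60 --p 0.2 --seed 1 --output er.tsv
regdom benchmark --sizes 8,10 --densities 0.2,0.4 --seeds 0,1,2 --output grid.tsv

# brute-force certification of small instances
regdom oracle mcds --input toy.tsv
```

Solver commands that write an output file also write
`<output>.manifest.json` with everything needed to re-run them. Exit
codes: 0 success, 1 usage error, 2 solver timeout (incumbent written when
available).

Input formats: TSV edge list (`regulator<TAB>target[<TAB>sign]`, `#`
comments, optional header), SIF (`source<TAB>relation<TAB>target`) and
GraphML. Self-loops are parsed but excluded from all domination and
connectivity computations.

## Tests

```bash
python -m pytest -q tests/
```

The suite cross-checks both ILP solvers against brute-force enumeration on
hundreds of seeded random digraphs, validates the heuristic output with
independent domination/connectivity checkers, and property-tests the
component decomposition against a transitive-closure oracle.

Note: `tests/test_acceptance.py::test_criterion_2_breast_cancer_pvalue` is
expected to fail: the inclusive-tail p-value for (M=1169, k=228, N=70,
x=20) is ~0.0386, which truncates to the published 0.03 but rounds to 0.04;
the test asserts the rounding form as specified.

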