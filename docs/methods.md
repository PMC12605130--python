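# Methods

## Model and scope

`qcomplex` analyses a simplicial complex given as an ordered list of
simplices (vertex sets) over a finite vertex set. Two modelling choices
shape everything downstream:

* **Stored simplices are the analysis units.** Faces are implicit and
  maximality is not enforced: if one record's vertex set is contained
  in another's, both are kept. This matches data where each record is
  an observed interaction (a publication, a trial) rather than a
  geometric construction; all metrics are defined over the stored
  records. Duplicate records are likewise retained by default
  (`keep_duplicates=True`) — two identical interactions are two
  interactions — with an explicit flag to collapse them. Only
  duplicate vertices *within* a record are always removed (set
  semantics).
* **Complexes are immutable.** q-connected components for all levels
  `0..d_max` are computed on the first request (threshold the
  connectivity matrix Π at each q, restrict to simplices of dimension
  ≥ q, run a connected-components search) and cached; no invalidation
  is needed. A lone eligible simplex forms its own component. Worst
  case time is `O(d_max · s_max · m²)`; memory scales with the total
  vertex count over simplices. Component ids are assigned in ascending
  order of each component's smallest simplex index so labelings are
  deterministic.

Graphs enter through the clique complex: every maximal clique
(Bron–Kerbosch enumeration via networkx) becomes a simplex, isolated
vertices become 0-simplices, and cliques are sorted lexicographically
because enumeration order is implementation-defined. Nonzero entries
are edges, the diagonal is ignored, and an asymmetric matrix is an
error rather than being silently symmetrised — malformed input should
fail loudly. The graph's node ids are adopted as the vertex universe,
so projections and vertex metrics align with the input matrix.

## Graded parameters

All per-level series share the domain `q = 0..d_max` and are stored
q-ascending with explicit q keys; the descending "vector" notation is a
display convention (`GradedSeries.descending()`).

* FSV `Q_q`: component counts, `1 ≤ Q_q ≤ n_q`.
* SSV `n_q`: simplices of dimension ≥ q; non-increasing, `n_0 = m`,
  and equal to the high-q cumulative sum of the per-dimension simplex
  counts.
* TSV `Q̄_q = 1 − Q_q/n_q ∈ [0, 1)`: 0 when every eligible simplex is
  isolated, approaching 1 when many simplices share few components.
* Topological entropy: participation counts use dimension **exactly**
  q. This reading makes the counts sum over q to each vertex's
  simplex-membership total, consistent with the identity
  `D = diag(ΛᵀΛ)`; counting dimension ≥ q instead is exposed as
  `cumulative=True`. Natural logarithms are used; any base cancels in
  the ratio. Degenerate levels are conventions chosen to keep the
  series bounded and plots well defined: no simplex of dimension
  exactly q → NaN (dropped from tidy tables by default, zero-filled in
  batch arrays); a single participating vertex (`M_q ≤ 1`) → 0.
* Shared-face counts pair simplices with `Π_ij ≥ q` (cumulative),
  mirroring the q-nearness definition; the exact-q variant is available
  via `cumulative=False`. Together with the per-dimension simplex
  count these back the usual six-panel summary plot.

Tidy export fixes the column order (Vector, q, Value, extras…); a full
6-series grid over `d_max+1` levels is available with
`drop_undefined=False`.

## Projections, filtering, batches

`simplex_projection` connects vertices co-occurring in a simplex of
dimension ≥ q, optionally weighted by the co-occurrence count; the
filter-then-count order (only simplices of dimension ≥ q contribute
weights) is the documented choice where the convention is ambiguous.
At `q = 0` the projection of a graph's clique complex returns exactly
the graph. `clique_filter` keeps the edges lying inside a maximal
clique of ≥ q+1 vertices, implemented as clique complex → projection →
mask with the original edges; its output is a subset of the input edges
and the operation is idempotent at fixed q.

Batch extraction maps a collection of adjacency matrices to an array of
shape (networks × series × levels), zero-padding every series at high q
to a common domain (default: the collection's largest dimension). The
estimator-style wrappers record only this common q-domain in `fit`;
`transform` is pure.

## Consensus permutation test

Groups of same-node networks are compared through consensus networks:
binarize each network, keep edges whose occurrence frequency is ≥ the
inclusion threshold (default 0.95, inclusive; threshold 1.0 is the
intersection). The test statistic is the element-wise absolute
difference of the two consensus clique complexes' graded-parameter
arrays padded to a common `max_order` — absolute difference gives a
two-sided test per (series, q) cell where the literature names the
procedure but not the functional form. The null distribution permutes
group labels (sampling without replacement, group sizes preserved); the
add-one estimator `p = (1 + #{permuted ≥ observed}) / (1 + R)` keeps
p-values in (0, 1]. No multiple-testing correction is applied by
default, matching per-q reporting conventions; Benjamini–Hochberg is
available (`adjust="bh"`).

## Synthetic generators

The simulation study pairs scale-free networks with degree-matched
configurational networks. Preferential attachment uses the
Barabási–Albert rule seeded with a star on `m+1` nodes, so each graph
has exactly `(n − m)·m` edges; the full-scale preset is 100 networks of
100 nodes with `m = 8` (`DEFAULT_STUDY`), with a 50-node, `m = 10`
variant as `SMALL_STUDY`. Configurational partners realize each
scale-free graph's exact degree sequence with the deterministic
Havel–Hakimi construction (graphicality validated by Erdős–Gallai);
randomized degree-preserving double-edge swaps are off by default since
the plain construction is the stated algorithm. Havel–Hakimi wires
high-degree vertices together, producing a dense core with larger
cliques than preferential attachment yields at equal degrees — the
higher-order contrast the study measures.

What the generators do *not* emulate: weighted or signed edges,
empirical degree-sequence noise, node semantics shared across samples
(consensus analysis of generated ensembles is only meaningful because
node indices play the role of shared labels). Passing tests therefore
demonstrate correctness of the machinery and the qualitative
scale-free/configurational contrast, not quantitative claims about any
empirical network.

A `reference_complex()` fixture — four simplices over seven vertices,
built synthetically to satisfy a standard set of published constraints
(Π11=3, Π12=2, a 2-face between σ1 and σ2, a single shared vertex
between σ1 and σ3, component counts 2/2/2/1 from q=3 down to 0) — backs
documentation and tests alongside the two-triangle worked example.

## Problem sizes and numerical choices

Verification workloads are sized to run comfortably on one CPU: 500
random complexes (≤ 12 simplices over ≤ 10 vertices) for the
component-oracle equivalence; 100 replicates of 10+10 scale-free
networks (30 nodes, `m = 4`) with 200 resamples each for null
calibration of the permutation test, with the per-cell rejection rate
at α = 0.05 checked against the 99% binomial envelope; exhaustive
enumeration of all 20 splits for the 3+3 deterministic-group
cross-check. Tolerances elsewhere are exact integer comparisons or
float comparisons at numpy defaults; the only tie-break of note is the
smallest-member rule for component ids.

## Known limitations

No boundary operators, Betti numbers or persistent homology; no
directed or weighted simplices; complexes are static (no streaming
updates). The consensus construction is plain frequency thresholding —
distance- or density-preserving consensus schemes are out of scope. The
CLI reads whole ensembles into memory; very large simplex lists are
bounded by the `O(m²)` connectivity matrix.
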