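# qcomplex

Q-analysis of simplicial complexes for higher-order network analysis.

Pairwise graphs miss group interactions: a triangle of edges cannot say
whether three nodes interacted once as a group or three times in pairs.
`qcomplex` represents a system as a *simplicial complex* — a list of
simplices, each a set of vertices acting together (a paper's author
team, a clique of co-active brain regions) — and quantifies its
structure level by level with Q-analysis. It is aimed at researchers in
network science, systems biology and network physiology who want
hypergraph-grade descriptions of their data with ordinary
NumPy/pandas tooling.

## The method

For a complex with `m` simplices over `n` vertices, the incidence
matrix Λ (`m×n`, `Λ_ij = 1` iff vertex `j ∈ σ_i`) gives the
**connectivity matrix**

    Π = Λ·Λᵀ − Ω        (Ω the all-ones matrix),

whose entry `Π_ij` is the dimension of the largest face shared by
simplices `i` and `j` (−1 if disjoint) and whose diagonal holds the
simplex dimensions. Two simplices are *q-near* when `Π_ij ≥ q`; chains
of q-nearness partition the simplices of dimension ≥ q into
*q-connected components*. Sweeping `q` from 0 to the complex dimension
`d` yields the graded descriptors:

* **FSV** `Q_q` — number of q-connected components;
* **SSV** `n_q = |{σ : dim σ ≥ q}|`;
* **TSV** `Q̄_q = 1 − Q_q/n_q` — normalised connectedness in `[0, 1)`;
* **topological entropy** `S_Q(q) = −Σ_i p_i^q ln p_i^q / ln M_q`, the
  normalised entropy of vertex participation in dimension-q simplices;
* **topological dimensionality** `D(v) = diag(ΛᵀΛ)_v`, the number of
  simplices containing vertex `v` — the higher-order analogue of degree.

Complexes can be built directly from simplex lists or from a graph's
adjacency matrix via its maximal cliques (the clique complex). For
group comparisons, each group of same-node networks is reduced to a
*consensus network* (edges present in ≥ a threshold fraction of the
group) and the groups' graded parameters are compared with a
label-permutation test.

## Worked example

Two triangles sharing an edge, `⟨v1,v2,v3⟩` and `⟨v2,v3,v4⟩`:

```python
from qcomplex import SimplicialComplex, graded_parameters, topological_dimensionality

K = SimplicialComplex([["v1", "v2", "v3"], ["v2", "v3", "v4"]])
print(graded_parameters(K, ["FSV", "SSV", "TSV"]).to_dataframe())
```

```
  Vector  q  Value
0    FSV  0    1.0
1    FSV  1    1.0
2    FSV  2    2.0
3    SSV  0    2.0
4    SSV  1    2.0
5    SSV  2    2.0
6    TSV  0    0.5
7    TSV  1    0.5
8    TSV  2    0.0
```

Both simplices have dimension 2, so `n_q = 2` at every level. They
share the edge `⟨v2,v3⟩`, a 1-face: at `q ≤ 1` they merge into one
component (`Q_0 = Q_1 = 1`, `Q̄ = 0.5`), while at `q = 2` no 2-face is
shared and each triangle stands alone (`Q_2 = 2`, `Q̄_2 = 0`). In the
descending-q notation these are the vectors `Q = [2,1,1]`,
`n = [2,2,2]`, `Q̄ = [0, 0.5, 0.5]`.

```python
print(topological_dimensionality(K).to_dataframe())
```

```
  Node  Topological Dimensionality
0   v1                           1
1   v2                           2
2   v3                           2
3   v4                           1
```

The shared vertices v2 and v3 sit in both simplices; the sum (6) equals
the total vertex slots across simplices.

A command-line interface covers the same ground for files:

```
qcomplex vectors interactions.txt --vectors FSV -o fsv.csv
qcomplex components interactions.txt --q 1 -o components.csv
qcomplex simulate study/ --nodes 30 --m 4 --samples 10 --seed 0
qcomplex permtest study/scale_free study/configurational --seed 0 -o test.csv
```

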