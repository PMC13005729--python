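# Methods

## Statistical model

Over-representation of a term is tested with the one-sided hypergeometric
upper tail: for a query of n genes drawn from a background universe of N
genes, the probability of observing at least the k genes shared with a term
of size K is P(X ≥ k) with X ~ Hypergeom(N, K, n). This equals a one-sided
Fisher exact test and uses the "≥ k" (not "> k") convention, so k = 0 gives
p = 1 and the p-value is never 0. The background defaults to the union of a
library's gene sets; users may supply a larger universe, in which case a
query can be disjoint from every term and yields an empty result rather
than an error. The universe choice matters: a tight union-background makes
the test conservative for broad queries, and web services that use a fixed
genome-wide background will give different p-values for the same overlap.

Raw p-values are Benjamini–Hochberg step-up adjusted. The test family is
one (library × condition × regulation) enrichment run — each run is an
independent screen — and comprises every term with overlap k ≥ 1. The
minimum-overlap filter (`min_genes`, default 3) and the significance filter
(p_adj < `padj_max`, default 0.05) are applied *after* adjustment, so
neither changes the adjusted values. Within a stratum the significant terms
are sorted by p_adj (ties: larger overlap first, then term name) and the
top `top_n` (default 5, the intended usage scale) are retained.

When a log2 fold-change column and a threshold t are given, each condition
is first split into an upregulated (log2FC ≥ +t) and a downregulated
(log2FC ≤ −t) list; genes strictly inside (−t, +t) belong to neither
defensibly and are dropped with a logged count. A tie at t = 0 is assigned
up. Gene symbols are whitespace-trimmed and upper-cased on input — the
matching convention of the common human gene-set libraries; no identifier
conversion or species mapping is attempted.

## Term clustering

Each retained term is represented by the genes it matched in the input
lists, unioned across conditions and regulations (a term enriched both up
and down is a single node; regulation is re-attached at the pooling stage).
This choice — matched genes rather than full library sets — makes the
similarity structure dataset-specific; `build_term_gene_map_full` provides
the library-set alternative. Pairwise Jaccard similarities J = |A∩B|/|A∪B|
weight an undirected graph; edges with J < ts are pruned (ts default 0.3,
chosen as a mid-range default — the sweep described below is the intended
way to pick ts for a given dataset).

Communities come from the Walktrap random-walk agglomeration (walk length
4, the algorithm's canonical default, exposed as a parameter) as
implemented in igraph. Every cut of the merge dendrogram is scored with
weighted Newman modularity Q = Σ_c (e_cc − a_c²), computed by this package,
and the best cut is returned; ties go to the coarser partition, which
favours summarisation and makes the choice deterministic. Isolated nodes
are singleton clusters. An edgeless graph has no defined modularity; the
threshold sweep reports 0 there by convention. Cluster ids are relabelled
1..C by decreasing size, ties broken by the lexicographically smallest
member, so identical inputs give identical labels.

`evaluate_thresholds` rebuilds the graph and reruns Walktrap over a ts
grid, reporting edge count (non-increasing in ts), connected-component
count (non-decreasing) and modularity, the profile users inspect to choose
ts.

## P-value pooling

Per (cluster × condition × regulation) cell, the contributing terms'
p-values are combined with one of:

- **Fisher:** survival of χ²(2k) at −2 Σ ln pᵢ;
- **Stouffer:** upper normal tail at Σ zᵢ / √k, zᵢ = Φ⁻¹(1 − pᵢ);
- **weighted Z:** upper normal tail at Σ wᵢzᵢ / √(Σ wᵢ²);
- **Cauchy combination:** p = ½ − arctan(T)/π with
  T = Σ wᵢ tan((½ − pᵢ)π) / Σ wᵢ.

All four return exactly p for a single input. The default is Cauchy because
terms in one cluster share genes and are therefore strongly dependent; the
Cauchy combination keeps its level under arbitrary dependence, whereas
Fisher/Stouffer assume independence and can be anticonservative here.
Default weights for the weighted methods are each term's overlap gene count
(more matched genes, more evidence); an equal-weights rule is available.

Pooling uses **adjusted** p-values, keeping per-library multiplicity
accounted for inside clusters (a raw-p switch exists). Values are floored
at 1e-10 before pooling — so the log/probit/tangent transforms never see
0, at the cost of a documented bias for anything genuinely below the floor
— and the pooled value is capped at the same floor, which also keeps
−log10 heatmap scales readable. A term retained from several databases in
the same cell is collapsed to one entry (minimum adjusted p, union of
overlap genes) before pooling, so one biological signal is not counted
twice. No multiple-testing correction is applied across the pooled
cluster × condition cells; they are descriptive summaries, not a second
inference layer.

## Annotation

Cluster labelling is delegated to any LLM: a deterministic prompt lists
each cluster's member terms (optionally with source databases) and demands
`cluster_id<TAB>label` reply lines, which `parse_annotation_reply` maps
back onto clusters (unknown ids are reported, unlabelled clusters get a
"Cluster <id>" placeholder). Prompts covering more than 200 terms are split
into numbered parts of at most 200 terms because very long term lists can
truncate LLM replies. No network calls are made by the package itself; the
optional Enrichr download helper is the only network code and is outside
the tested contract.

## Cluster coherence

For every term in a cluster of size ≥ 2, the coherence report gives the
Jaccard similarity between the term's gene set and the union of the other
members' gene sets; the mean over those terms summarises a clustering's
gene-level homogeneity and is the metric used to compare partitions.
Singletons are undefined (reported as missing) rather than 0, so a
partition is not rewarded for isolating terms.

## Synthetic benchmark

`generate_fixture` plants a known cluster structure: `n_blocks` blocks of
`terms_per_block` terms (30 genes each by default) built from a per-block
core plus per-term periphery plus a small global pool, sized so that
within-block pairs have Jaccard ≈ 0.8 and cross-block pairs ≈ 0.05 (the
overlap parameters are target Jaccards; |A∩B| = 2gJ/(1+J) for equal set
sizes g). Conditions receive blocks round-robin, so every block is enriched
somewhere; each condition's gene list is its blocks' genes (log2FC
magnitudes 1–3, sign alternating by block so the up/down split is
exercised) plus 5 decoy genes outside the library with log2FC ~ N(0, 0.3).
Defaults are 3 blocks × 4 terms × 4 conditions — small enough that the
whole pipeline runs in well under a second while leaving all filters
non-trivial.

The generator emulates redundancy through shared genes only. Real
enrichment results also contain hierarchically nested terms, heavy-tailed
term sizes, between-condition correlation and genes missing from the
library background in a biased way; none of that is modelled. Passing the
recovery tests therefore shows the machinery is correct (exact recovery is
achievable by construction for ts between the two planted Jaccard levels),
not that any particular ts will resolve a real dataset — for real data the
threshold sweep and the coherence report are the guides.

## Numerical and design notes

- Hypergeometric tails come from scipy (`hypergeom.sf(k-1, N, K, n)`) and
  are clamped into (0, 1]; BH uses statsmodels; both are verified against
  exact independent references in the test suite.
- Modularity tie-breaks, cluster relabelling and all output orderings
  (sorted terms, sorted gene lists, sorted JSON keys) are deterministic;
  figures are written without timestamp metadata, making whole runs
  byte-reproducible — verified by running the pipeline twice per test.
- Hierarchical ordering of heatmap rows/columns uses average linkage on
  Euclidean distances of the −log10 matrix with lexicographically
  pre-sorted labels, so leaf orders are reproducible. Absent
  cluster × condition cells are drawn as 0: absence of evidence is not
  significance, and imputing would invent signal.
- A failed run removes its partial outputs and reports the failing stage
  in the raised error.
- Known limitations: no GSEA-style ranked statistics, no semantic
  (ontology-graph) similarity, no genome-wide default background, and the
  pooled p-values inherit whatever bias the floor introduces below 1e-10.
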