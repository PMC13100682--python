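# topofc

Multiscale persistent-homology analysis of correlation networks, built
for brain functional-connectivity (FC) matrices but applicable to any
cohort of square symmetric correlation matrices.

Connectivity studies usually compare edge weights or graph-theoretic
summaries between groups (e.g. young vs. elderly, patient vs. control).
Persistent homology (PH) instead tracks *mesoscale topology*: as a
distance threshold grows, connected components (H0), loops (H1) and
voids (H2) appear and disappear, and the resulting birth–death pairs
summarize the network across all scales at once.  `topofc` computes

- **global measures** — persistent entropy of the barcode, the L¹ and L²
  norms of the first persistence landscape, and 1-/2-Wasserstein and
  bottleneck distances between subjects' diagrams;
- **node-level measures** — *node persistence* NP(v) and *node
  frequency* NF(v), which localize the H1 signal to individual nodes via
  representative cycles;
- the surrounding statistics: two-sample t tests with
  Benjamini–Hochberg FDR, Spearman correlations, a resampling
  enrichment null for node annotations, and a node-order-permutation
  protocol quantifying how robust the node measures are to the
  (non-unique) choice of representative cycles.

## The model

Each subject's correlation matrix C is converted to a distance matrix

    D_ij = 2 (1 − C_ij),        D_ij ∈ [0, 2],

using only positive correlations (non-positive entries are assigned the
maximal distance 2 by default; a square-root variant and a clamping
policy are available behind flags).  A Vietoris–Rips filtration is built
over D — a simplex enters at the largest pairwise distance among its
vertices — and persistence is computed by mod-2 boundary-matrix
reduction.  For every finite H1 pair (bᵢ, dᵢ) the reduced column of the
death triangle is a representative cycle gᵢ, an edge set whose latest
edge is the birth edge.  With β₁ finite pairs and *persistence extent*
`max dᵢ − min bᵢ`, the node measures are

    NP(v) = Σ_{gᵢ ∋ v} (dᵢ − bᵢ) / (max dᵢ − min bᵢ),
    NF(v) = |{ gᵢ : v ∈ gᵢ }|.

Representative cycles are deterministic for a fixed node order but not
unique across orders, so `topofc robustness` recomputes NP/NF under R
node-order permutations and reports per-node MAD and MAD/M dispersion
and the R×R Spearman matrix of node rankings.

## Worked example

The package ships a synthetic cohort generator whose defaults emulate a
parcellated FC study at desk scale: 30 nodes, one planted 8-node ring
whose loop strength is raised for group B, four background communities
on a mesoscale gradient, and per-subject noise.

```bash
topofc simulate --out cohort --seed 3
topofc nodes cohort cohort/groups.tsv --labels cohort/labels.tsv --out results
```

`results/node_comparisons.tsv` then contains one row per node and
measure; for the planted ring nodes it looks like (seed 3, abridged):

```
measure           feature  mean_A   mean_B   t        p_raw      p_adj      significant
node_persistence  n000     0.3398   0.4026   -2.9083  6.0386e-03 3.0193e-02 True
node_persistence  n001     0.3355   0.4023   -4.1661  1.7200e-04 2.5844e-03 True
node_persistence  n008     0.0674   0.0426    1.6329  1.1075e-01 3.5509e-01 False
```

The planted nodes (`n000`–`n007`) carry strongly significant
node-persistence differences in the planted direction (group B's ring is
stronger, so its loop persists longer and NP is higher), while
background nodes such as `n008` do not.  `topofc global` and
`topofc rsn` run the brain-wide and community-level workflows on the
same inputs, and `topofc robustness -R 5` reports the rank stability of
the node measures across node orders (mean pairwise Spearman ≈ 0.96 on
this cohort).

Real inputs are delimited text matrices (one per subject, optional
header row of node names), a two-column node→community label table and
a two-column subject→group table — see `topofc --help`.

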