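# Methods

## Pipeline

Each subject contributes one square symmetric correlation matrix C with
unit diagonal and entries in [−1, 1], validated on ingestion (asymmetry
beyond 1e−9 is an error unless `--symmetrize` is passed; node order is
file order and is preserved end-to-end because representative cycles
depend on it).

**Distance transform.** D = 2(1 − C) (default) or D = √(2(1 − C))
behind a flag; both are monotone decreasing in C and map [0, 1] into
[0, 2].  Only positive correlations are treated as carrying
connectivity signal: entries with C ≤ 0 are assigned the maximal
distance 2 (`max_distance`, default) so the pair enters the filtration
last, or clamped to C = 0 before the formula (`clamp_zero`).  The two
variants and policies are recorded in the output's transform tag.  The
linear formula is the default because, restricted to positive
correlations, it exactly attains the documented [0, 2] range; the
square-root variant is the classical correlation metric and is kept
first-class because the two are genuinely different conventions in use.

**Rips filtration.** All simplices up to a requested dimension are
enumerated; a simplex's filtration value is the maximum pairwise
distance among its vertices, so the distinct filtration values are a
subset of {0} ∪ {matrix entries}.  Ties are broken by (value,
dimension, lexicographic vertex tuple).  This total order makes
diagrams *and* representative cycles bit-reproducible for a fixed node
order.  Full enumeration is O(n^(d+1)); the node-level workflow needs
dimension 2 only (n = 200 ⇒ ~1.3M triangles, still tractable), while
H2 entropy needs dimension 3, which the CLI restricts to n ≤ 60 unless
`--full-homology` is passed.

**Persistence and representatives.** Standard mod-2 column reduction of
the boundary matrix in filtration order, with columns stored as Python
integers used as bitsets (XOR of long integers is fast enough that no
compiled backend is needed at desk scale; any clearing/twist
optimization would be admissible provided outputs stay bit-identical).
A paired column (i, j) yields the bar (value(i), value(j)) in dimension
dim(i); unpaired simplices are essential classes with infinite death.
Zero-persistence pairs (birth = death, which occur whenever an edge and
a triangle share a filtration value) are retained in the diagram object
but excluded from every downstream measure — they carry no geometric
signal, and the node-frequency count should reflect geometrically real
holes only.  For each finite H1 pair the reduced column of the death
triangle is an edge set with zero mod-2 boundary whose latest edge is
the birth edge; that edge set is the representative cycle and its
vertex set defines node membership.  Representatives of this kind are
deterministic per node order but not unique across orders, which is
precisely why the robustness protocol exists rather than being hidden.

## Measures

**Persistent entropy** of the finite bars eᵢ = (dᵢ − bᵢ)/L,
PE = −Σ eᵢ log eᵢ, pooled over homology dimensions 0–2 by default for
the brain-wide workflow (per-dimension available); natural log by
default with a base-2 flag — group-difference directions are base
invariant.  Essential classes are excluded (the formula requires finite
deaths); an empty selection raises rather than silently returning 0.

**Persistence landscapes** are kept as exact piecewise-linear functions:
the k-th largest of the tent functions max(0, min(t − b, d − t)) can
kink only at tent endpoints and at up-slope/down-slope crossings
(bᵢ + dⱼ)/2, so evaluating at those O(m²) candidate points and pruning
collinear points is exact, with no grid discretization.  L¹ and L² norms
integrate each linear segment in closed form (trapezoid and
w(y₀² + y₀y₁ + y₁²)/3 respectively), so the values are deterministic and
testable against closed forms.

**Diagram distances** use the standard optimal partial matching with
L∞ ground metric and diagonal projections at cost (d − b)/2.
Wasserstein-p is solved exactly as a square assignment problem
(`scipy.optimize.linear_sum_assignment` on the (n+m)×(n+m) augmented
cost matrix); bottleneck by binary search over the candidate costs with
a bipartite perfect-matching feasibility check.  Both are verified in
the tests against full matching enumeration on small diagrams.

**Node persistence / node frequency.** NP(v) sums (dᵢ − bᵢ)/extent over
representative cycles containing v, with extent = max dᵢ − min bᵢ over
the subject's finite H1 pairs; NF(v) counts the cycles.  When β₁ = 0
all nodes get 0 and the extent is reported as undefined rather than
raising — subjects without 1-cycles are legitimate.  Two exact
conservation identities follow from the definitions and are asserted on
every synthetic subject: Σᵥ NF(v) = Σᵢ |vertices(gᵢ)| and
Σᵥ NP(v) = Σᵢ |vertices(gᵢ)|(dᵢ − bᵢ)/extent.

## Statistics

Group comparisons are pooled-variance Student t tests by default (Welch
behind a flag; the variant is recorded in outputs), two-tailed for
scalar measures and per-node measures, one-tailed (intra < inter) for
the diagram-distance samples.  No covariates are modelled.  BH-FDR is
applied within explicit families — per measure for global and
node-level analyses, per measure or per community for the
community-level workflow — because family boundaries change the
correction and should be a visible, configurable choice.  Degenerate
features (zero variance in both groups, equal means) get p = 1 and a
flag.  The enrichment null resamples B same-size node sets uniformly,
computes Z = (obs − mean)/sd per term and a one-sided upper-tail normal
p (enrichment, not depletion); terms with sd = 0 are NaN-flagged except
in the trivial whole-universe case, where Z = 0.

The robustness protocol draws R node-order permutations from substreams
spawned off a master seed (adding permutations never changes earlier
ones), recomputes NP/NF through the full pipeline per permutation, maps
values back to original node identity, and reports per-node MAD and
MAD/M (unscaled, NaN-flagged at median 0) with quartiles, the R×R
matrix of mean pairwise Spearman rank correlations (average ranks for
ties; two identical constant vectors count as ρ = 1, a constant vector
against a non-constant one is skipped as uninformative), and
per-permutation significant-node counts when a group table is supplied.

## Synthetic cohorts

The generator's defaults are the package's reference study conditions;
they are constructed as an explicit latent-factor Gram matrix, so every
template is positive semidefinite by design, and they were chosen to
put the planted signal in the regime the node measures are meant for —
a topologically rich background in which one loop carries a group
effect.

- 30 nodes: an 8-node planted ring plus four background communities of
  6, 6, 5, 5 nodes.
- Background node i loads √aᵢ on a global factor (aᵢ ~ U centred on
  `base_between` = 0.10) and √bᵢ on its community factor (bᵢ ~ U centred
  on `base_within` = 0.35), and sits on a large latent circle
  contributing `bg_circle` · cos(ψᵢ − ψⱼ) with `bg_circle` = 0.22.  The
  circle is a closed mesoscale gradient across the communities: it
  guarantees background 1-cycles in every subject.  This matters
  because the extent normalizer in NP is anchored by the background's
  earliest birth and latest death; a background that can be hole-free
  (as a plain block-constant template often is at n = 30) makes NP
  collapse to 1 on the planted nodes for some subjects and destroys the
  group comparison's power.  Real connectivity matrices always carry
  β₁ ≫ 1, so a hole-free background would also be the wrong thing to
  emulate.
- Ring nodes form a tight module on their own latent circle:
  corr = l + q·cos(2πΔ/8) with l = `ring_base` = 0.8 and
  q = `ring_strength`(1 − l), `ring_strength` = 0.7; they attach to
  every outside node at √(l·aₖ).  The ring's adjacent edges are the
  shortest distances in the graph, so the loop closes before anything
  else exists and its representative is pinned to the planted nodes
  under any node order; it dies internally at the ring's chord scale.
- The group effect adds `effect_delta` = 0.25 to `ring_strength` for
  group B, which moves the planted birth earlier and the chord-scale
  death later — lengthening the planted bar at both ends — without
  moving the extent anchors.  Planted persistence is monotone in
  `ring_strength` (tested on a grid).
- Per-subject noise is symmetric Gaussian with sd 0.04 on the
  off-diagonal (a modest subject-level variability), followed by an
  eigenvalue-clipping projection back to the correlation cone
  (`statsmodels.corr_clipped`, iterated; chosen over alternating
  projections because it converges in one pass on these mildly
  indefinite inputs with entry deviations below 0.01).  Cohorts are
  reproducible from a single seed via spawned substreams, so cohort
  prefixes are stable under size changes.
- 20 subjects per group, matching the scale at which per-node
  two-sample t tests at n = 30 features have stable normal behaviour.

What the generator does *not* emulate: BOLD time-series autocorrelation
and finite-sample correlation noise (noise is Gaussian on the
correlation scale), realistic network size (30 vs. 200 nodes), spatial
autocorrelation of parcels, and site/motion confounds.  Passing tests
therefore demonstrate the correctness and calibration of the machinery
under controlled topology, not performance claims about real cohorts.

## Numerical choices and degenerate inputs

- Filtration tie-break (value, dim, lexicographic) fixes all
  reduction-order ambiguity; identical inputs give bit-identical
  outputs, which the CLI tests assert by hashing output files.
- Measure serialization uses %.17g so all delimited artifacts
  round-trip losslessly (readers use pandas' round-trip float parser).
- Entropy of an empty bar selection, Spearman of a constant vector,
  MAD/M at median 0, and enrichment with a degenerate null are all
  flagged (error or NaN) rather than silently coerced to 0.
- Diagram distances between two empty diagrams are 0; a diagram against
  an empty one is matched entirely to the diagonal.
- t tests with both samples constant return t = 0, p = 1 (equal means)
  or p = 0 (unequal), flagged as degenerate.

## Problem sizes

The test suite and the acceptance script run cohorts of 30-node
matrices (40 subjects; 20 replicates for recovery and null calibration,
5 node-order permutations over 20 subjects for rank stability) and
verify the persistence core against brute-force GF(2) rank oracles on
100 random ≤8-point matrices.  These sizes exercise every code path of
the paper-scale workflows (which differ only in n) while keeping a full
run in the tens of seconds.

## Known limitations

- Representative cycles are the reduction (JavaPlex-style)
  representatives; minimal-length or volume-optimal cycles are out of
  scope, and node measures inherit the representatives' node-order
  dependence — quantified, not removed, by the robustness protocol.
- Full H2 on 200-node matrices requires ~65M tetrahedra; the pure-Python
  reduction is not sized for that, hence the CLI's dimension guard.
- Wasserstein/bottleneck are exact but O((n+m)³); they are meant for
  subject-level H1 diagrams (tens to hundreds of points), not for
  pooled mega-diagrams.
- The enrichment null resamples nodes uniformly; it does not model
  spatial autocorrelation between annotations of neighbouring parcels.
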