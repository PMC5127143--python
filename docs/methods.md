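# Methods

## The model

`ssnphylo` classifies a set of protein sequences by the structure of their
*threshold similarity networks*. The input is reduced to a symmetric matrix
`S` of percent similarities `0 ≤ s_ij ≤ 100`; a similarity threshold
`σ` (percent) then defines a one-parameter family of undirected graphs
`M(σ)` with an edge between `i` and `j` iff the pair is valid and
`s_ij ≥ σ`. Because raising `σ` only deletes edges, the family is nested
and its connected components can only break apart as `σ` grows. The
sequence of component splits is the classification: groups of sequences
that stay mutually connected up to high thresholds are similar clusters
(clades, under the usual caveats), and the threshold at which a group
detaches measures how distinct it is.

Two derived objects make the splits explicit:

* **δ-distance scan.** Each network is summarised by its *neighborhood
  matrix* — all-pairs unweighted geodesic distances, with disconnected
  pairs set to a finite cap (`n`, one more than any realisable path
  length). The distance between two networks on the same node set is the
  mean absolute entrywise difference over ordered off-diagonal pairs,

      δ(A, B) = 1/(n(n−1)) · Σ_{i≠j} |D_A(i,j) − D_B(i,j)|,

  which is a true metric. Scanning δ(σ, σ+Δσ) along the grid produces a
  curve whose peaks mark *critical thresholds* σ_cst: when a community of
  size k detaches from the rest, ~2·k·(n−k) ordered pairs jump from a
  small geodesic distance to the cap, so component splits dominate the
  curve. δ is normalised and capped as above by default; both the cap and
  the normalisation are arguments, because the scan's *peak locations* are
  the robust output — absolute δ values depend on these conventions.

* **σ-height dendrogram.** Sweeping the grid upward and recording every
  component split as an internal node at that σ yields the merge tree of
  the family. This sweep is exactly single-linkage agglomerative
  clustering on dissimilarity `100 − s`, discretised to the grid (asserted
  against scipy's implementation in the tests). Heights are similarity
  percentages, not evolutionary distances, and simultaneous splits form a
  single multifurcation: taxa that separate jointly at one σ have
  comparably decayed similarity, which does not by itself make them a
  clade.

A *community* is a connected component with ≥ 2 members; singleton
components are isolated nodes. After the first split, each community is
treated as an independent network: `S` is restricted to its members and
the δ scan is rerun, recursively, until a community has fewer than 3
members or its δ-curve has no qualifying peak. Two-member communities are
excluded because they split trivially at their pairwise similarity.

## Similarity scores

Directed scores come from Smith–Waterman local alignment (BLOSUM62, gap
open 11 / extend 1 — blastp's defaults) via biopython's
`PairwiseAligner`; an optional engine delegates to a local `blastp`
binary. `s_ij` is the mean of the two directed scores. A pair is *valid*
only if the better of its two E-values is ≤ 1.0 (Karlin–Altschul with the
standard gapped BLOSUM62 parameters λ = 0.267, K = 0.041, search space
m·n); invalid pairs get similarity 0 and never an edge. The E ≤ 1.0 rule
is permissive by design — in practice it only removes pairs with no
credible local alignment at all.

Three percent-scale score functionals are available:

* `bitscore` (default): the pair's bit score divided by the larger self
  bit score, × 100. This is a whole-sequence similarity: it is ≈100 only
  for near-identical sequences and decays toward 0 with divergence.
* `positives`: positive-scoring columns over the alignment length of the
  best local alignment (the "similarity" column of a BLAST report).
* `identity`: identical columns over the alignment length.

The normalised bit score is the default because the per-alignment
percentages are properties of the *best local alignment only*: for deeply
diverged pairs that alignment is a short high-scoring segment, and a
perfect 15-residue segment reports 100% positives between biologically
unrelated 250-residue proteins. Under thresholding this is fatal — such a
pair can never be separated at any σ ≤ 100. Length-normalised scores are
the standard remedy in sequence-similarity-network practice; for
full-length homologous families (the regime where percent positives is
normally quoted) the two functionals give the same qualitative network
family, and `positives` remains one `--metric` flag away.

## Conventions and numerical choices

* **Boundary:** `s_ij = σ` keeps its edge (no-edge iff `s_ij < σ`).
* **Grid:** integer percent 0–100, step Δσ = 1 by default; critical
  thresholds are therefore integer percentages. The δ-curve has one point
  fewer than the grid.
* **Peak reporting:** δ(σ, σ+Δσ) compares the networks at the two ends of
  a grid interval; a peak is reported at the *upper* end, so the network
  built *at* σ_cst already exhibits the new community structure, and the
  dendrogram records a split at the first grid σ where the component is
  disconnected. A pair with s = 60 splits at σ_cst = 61.
* **Peak detection:** local maxima of the δ-curve (plateaus collapsed to
  their first point, endpoints eligible) kept if their height is at least
  `min_prominence_frac` (default 0.1) of the curve's maximum; the global
  maximum is always kept and has rank 1. The default fraction is a
  reproducible stand-in for reading "smaller peaks" off a figure; it is a
  parameter, not a tuned constant.
* **Recursion guard:** a δ peak can arise from path-length rearrangement
  without any component split, so the pipeline recurses only into
  communities strictly smaller than the set being analysed.
* **Degenerate inputs:** a single sequence yields a bare leaf; a constant
  matrix yields a one-spike δ-curve; clusters still connected at the top
  of the grid (e.g. identical sequences) are emitted as zero-length
  polytomies at height 100, keeping the Newick tree ultrametric.

## The synthetic generators

`planted_block_similarity` writes the target structure directly into `S`:
`K` groups with within-level `s_w`, between-level(s) `s_b < s_w`, plus
symmetric Gaussian noise (sd in percent) truncated to [0, 100] after
symmetrisation. It emulates the block pattern an orthologous protein
family leaves in a similarity matrix, and nothing else: no triangle-
inequality structure, no alignment artifacts, no E-value filtering. It
warns when the ±3 sd bands of the within and between levels overlap.

`simulate_protein_family` generates sequences under a star-of-stars
substitution process: a uniform random root; per group an ancestor at
Poisson(`d_between`·L) uniform substitutions from the root; per leaf
Poisson(`d_within`·L) further substitutions from its ancestor
(substitutions replace a residue with any of the other 19; sites can be
hit repeatedly). Defaults — 3 groups × 4 sequences, L = 250,
`d_between` = 1.5, `d_within` = 0.02 — give essentially saturated
between-group divergence and ≈95–99% within-group similarity, the shape
of a deep protein family. The process has no indels, no rate
heterogeneity and no empirical substitution preferences (JTT/WAG), so
passing tests show the *network pipeline* recovers planted structure from
realistic similarity bands; they say nothing about alignment quality on
real proteins with indels or composition bias.

With this generator the three between-group similarity maxima usually
fall in different grid cells, so the full network splits 1→2→3 across two
δ peaks, the first (larger) one being the global maximum. The planted
groups are therefore recovered the way the recursive procedure reports
them: one group detaches at the top-level dominant σ_cst, and the
remaining pair separates at the dominant σ_cst of the sub-community scan
— the same level-by-level pattern the method produces on real protein
families.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on desk-scale problems
chosen to exercise every code path while keeping a full run in seconds to
a few minutes: geodesic matrices vs a brute-force oracle on 200 random
graphs (n ≤ 10); nestedness over the full grid on 50 random matrices
(n ≤ 30); planted two-/three-block recovery over 20 noisy replicates
each; dendrogram vs single-linkage on 50 random matrices (n ≤ 20); and 20
end-to-end simulated families of 12 sequences × 250 residues.

## Known limitations

* Absolute δ values depend on the cap and normalisation conventions;
  only peak locations should be compared across implementations.
* Scores are computed from the single best local alignment per pair
  (BLAST's top-HSP convention); multi-domain proteins with repeated
  domains are summarised by their strongest match.
* The internal E-value uses raw (not edge-corrected) search-space sizes,
  so it is slightly conservative for short sequences relative to blastp's
  composition-adjusted statistics.
* Communities are connected components. Denser notions of modularity
  (e.g. edge-betweenness splitting of a connected network at fixed σ) are
  out of scope; the threshold sweep itself provides the hierarchy.
* All-vs-all Smith–Waterman is O(n²·L²); for hundreds of sequences use
  the `blastp` engine or precompute `S` externally and feed the TSV.
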