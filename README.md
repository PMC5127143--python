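# ssnphylo

Phylogenetic classification of protein families from **threshold
similarity networks**.

Given a set of protein sequences (for example the apolipoprotein E
orthologs of mammals, fish and amphibians), `ssnphylo` computes the
symmetric matrix `S` of pairwise percent similarities from local
alignments, builds the one-parameter family of networks `M(σ)` — an edge
between sequences `i` and `j` iff `s_ij ≥ σ` — and locates the *critical
similarity thresholds* `σ_cst` at which the network reorganises. Each
network is summarised by its matrix of geodesic (shortest-path) distances,
and adjacent networks are compared with the δ-distance

    δ(σ, σ+Δσ) = 1/(n(n−1)) · Σ_{i≠j} |D_σ(i,j) − D_{σ+Δσ}(i,j)|,

whose peaks mark community separations. Communities (connected components
with ≥ 2 members) are extracted at each `σ_cst`, every community is
re-analysed recursively as an independent network, and the whole sweep is
reported as an ultrametric dendrogram whose node heights are σ values —
equivalent to single-linkage clustering on dissimilarity `100 − s`.

Intended users: molecular evolution / comparative genomics researchers who
want an alignment-free-of-assumptions complement to model-based tree
inference, and anyone analysing sequence similarity networks (SSNs) who
needs principled thresholds instead of an arbitrary cutoff.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a small two-group protein family (six sequences of 200 residues,
two deeply diverged groups) and run the full pipeline:

```
$ ssnphylo simulate demo --mode family --groups 2 --per-group 3 \
      --length 200 --d-between 1.2 --d-within 0.03 --seed 8
wrote demo/family.fasta

$ ssnphylo run demo/family.fasta demo/out
INFO level C: sigma_cst=5 -> 2 communities (sizes [3, 3]), 0 isolates
INFO level C1: sigma_cst=93 -> 0 communities (sizes []), 3 isolates
INFO level C2: sigma_cst=95 -> 0 communities (sizes []), 3 isolates
analysed 6 sequences; report at demo/out/report.json
```

Reading the log: the dominant δ peak of the whole network is at
`σ_cst = 5%` — at that threshold the six sequences fall into the two
planted groups of three (between-group similarity is near the alignment
noise floor, so the groups separate at a very low threshold). Each group,
re-analysed as its own network (levels `C1`, `C2`), holds together until
its members disperse into isolated nodes at 93% and 95%, i.e. the
sequences within a group are 93–95% similar. The dendrogram written to
`demo/out/dendrogram.nwk` shows the same story with σ-heights as branch
lengths:

```
((G1S1:7,G1S2:7,G1S3:7):88,(G2S1:5,G2S2:5,G2S3:5):90):0;
```

`demo/out/` also contains the similarity matrix (`similarity.tsv`), one
δ-curve per analysed level (`delta_C.tsv`, `delta_C1.tsv`, ...), a
machine-readable `report.json` with every detected `σ_cst` and the
communities/isolates at it, and `pipeline.log`.

The stages are also available separately — `ssnphylo similarity`,
`scan`, `communities`, `dendrogram` — and accept a precomputed similarity
matrix as TSV, bypassing alignment. `ssnphylo fetch` retrieves named
accessions from NCBI (network required) while excluding records with
RefSeq status PREDICTED, for re-running published analyses from an
accession list. Everything is equally usable as a library:

```python
from ssnphylo import (FamilyDesign, simulate_protein_family,
                      compute_similarity, SigmaGrid, delta_curve,
                      detect_critical_thresholds, partition_at)

seqs = simulate_protein_family(FamilyDesign(seed=8))
S = compute_similarity(seqs)
curve = delta_curve(S, SigmaGrid())
for peak in detect_critical_thresholds(curve):
    print(peak.sigma_cst, [sorted(c) for c in
                           partition_at(S, peak.sigma_cst).communities])
```

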