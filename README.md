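# panfix

Correct phage pangenomes before phylogenetics: merge gene clusters that
hide distant homologs, fuse fragmented gene calls, and extract the
single-copy core genome.

## The problem

A pangenome workflow (gene calling + similarity clustering) makes two
characteristic mistakes on phages. First, phage homologs are often too
diverged for pairwise thresholds: clustering on the *minbit* heuristic
(pairwise bit score divided by the smaller self-alignment bit score,
threshold 0.35) leaves one gene family scattered across several clusters.
Second, homing endonucleases, intron-like elements, frameshift indels and
genomes reported with an arbitrary origin all split one gene into two or
more gene calls, which then masquerade as paralogs. Both errors shrink the
single-copy core genome (SCG) — the set of clusters with exactly one
member in every genome — and with it the signal available for concatenated
phylogenies.

## The method

Starting from amino-acid gene calls, their genome coordinates, and an
initial cluster table, the pipeline runs two analyses **in tandem on the
original clusters**, combines them, and finishes with a second
defragmentation pass:

1. **Cluster merging.** Each cluster's alignment becomes a
   position-specific log-odds profile. Every gene call is scored against
   every profile by local alignment. A cluster's *selfbit* — the minimum
   profile bit score among its own original members — is its significance
   threshold: a foreign call scoring ≥ selfbit links its cluster to the
   profile's cluster, and connected components of that cluster graph are
   merged. An optional absolute bit-score floor tightens the criterion.
2. **Defragmentation.** In every cluster holding two calls from the same
   genome, each such pair (A, B) in cluster G is scored with

   *relbit*(A,B) = bit(A,B) / mean<sub>C∈G∖{A,B}</sub> bit(A,C)  (both
   directions; the maximum is used), and

   *percent overlap* = |cols(A) ∩ cols(B)| / |cols(A) ∪ cols(B)| over the
   occupied columns of the cluster alignment.

   Pairs with both statistics strictly below 0.25 are fragments of one
   gene: they are fused N-terminus first with an `X` spacer at the
   junction, and affected clusters are re-aligned (the `X` scores zero
   against everything, so the spacer imposes a gap instead of attracting
   alignment).
3. **Round two.** Fragments whose pieces started in *different* clusters
   only become visible after merging, so defragmentation runs once more on
   the combined clusters.

Utility stages report the core/SCG summary, a concatenated SCG alignment
(with a partitions table) ready for tree inference, and a classification
of each fusion's likely cause — frameshift indel, selfish-element
insertion, or end-of-genome split — from the fragments' genomic
separation.

## Worked example

The package ships a synthetic-pangenome generator that plants every
phenomenon the pipeline corrects, with a truth manifest:

```bash
panfix simulate --out fixture --seed 11 --n-genomes 8 --n-families 10 \
    --n-split-families 1 --n-frameshift 1 --n-element 1 --n-end-split 1 \
    --n-decoys 1
panfix run --gene-calls fixture/calls.faa --coords fixture/coords.tsv \
    --clusters fixture/clusters.tsv --out corrected
```

which prints

```
clusters: 11  core: 10  single-copy core: 9
```

The fixture starts with 12 clusters, only 5 of them single-copy core: one
family is split into two clusters (`F000a`/`F000b`, cross-subfamily
identity ~30%), three families carry a fragmented gene call each, one
family carries a true paralog duplicate, and the planted selfish-element
ORF sits in a singleton cluster. After correction the two split clusters
are merged (11 clusters remain) and the three fragment pairs are fused,
so 9 clusters are single-copy core; the paralog-bearing family stays core
but, correctly, not single-copy.
`corrected/fragment_report.tsv` lists each evaluated pair with its relbit
and overlap values and decision; the paralog pair is reported with relbit
≈ 1 and overlap ≈ 1, i.e. rejected. `corrected/fragclass.tsv` gives one
cause per fused pair, and `corrected/concatenated_alignment.faa` holds the
genome-level SCG alignment for tree building.

The same works from Python:

```python
from panfix import FixtureConfig, generate, run_full, score_against_truth

state, manifest = generate(FixtureConfig(seed=11))
result = run_full(state)
print(score_against_truth(state, manifest))
```

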