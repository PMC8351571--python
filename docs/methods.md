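# Methods

## Scope and data model

`panfix` corrects an existing pangenome rather than building one: its
inputs are amino-acid gene calls (FASTA), a coordinate table (genome id,
gene-call id, start, stop, strand, genome length) and a cluster table
mapping gene calls to clusters. Coordinates are held 0-based half-open
internally; 1-based inclusive tables are converted on read. A single
trailing `*` stop symbol is stripped on read and never written; sequences
are otherwise restricted to the 20 standard residues plus `X`. Strand is
metadata only — gene calling is upstream of this package, and all scoring
operates on amino acids. When no cluster table is supplied, a bootstrap
stage clusters the calls itself: all-vs-all minbit (pairwise bit score
over the smaller self-alignment bit score), edges at minbit ≥ 0.35 — the
customary threshold for diverse phage proteomes — and connected components
as clusters. The bootstrap is a convenience for cluster-less inputs, not a
re-implementation of any particular Markov-clustering setup; it
deliberately implements only the plain components variant.

## Pairwise scoring

Local alignments are Smith–Waterman with affine gaps under BLOSUM62
(matrices are loadable from NCBI-format files). The gap convention
everywhere in the package is that a gap of length *k* costs
`open + k·extend`, defaults 10/1. Raw scores are converted to bits with
the Karlin–Altschul form `(λ·raw − ln K)/ln 2`, λ = 0.267, K = 0.041
(the customary gapped-BLOSUM62 values). Every statistic the pipeline
thresholds — minbit, selfbit, relbit — is a *ratio* of bit scores, so the
exact calibration constants cancel; they matter only for the optional
absolute bit-score floor on merge edges. Raw scores ≤ 0 are reported as 0
bits, the way a search tool reports no hit; such pairs contribute 0 to
relbit means. Composition-based score adjustment is deliberately not
implemented: plain scores keep the implementation exactly checkable
against a brute-force dynamic-programming oracle (the test suite demands
bit-exact agreement). `X` scores 0 against every residue, which makes the
fusion spacer alignment-neutral. Co-optimal alignments are resolved by the
alignment library's first reported traceback, which is deterministic for
fixed inputs. A plug-in seam accepts external search results instead
(blastp tabular `qseqid sseqid bitscore qstart qend sstart send`).

## Multiple alignment

Clusters are aligned with an internal progressive aligner: pairwise
distances `1 − raw(a,b)/min(raw(a,a), raw(b,b))` (score-only, clipped to
[0,1]), an average-linkage (UPGMA) guide tree, and global profile–profile
merges with affine gaps, profile columns scored as
frequency-weighted expected substitution scores. Average linkage is a
deliberate choice over neighbor joining: when a cluster contains the two
pieces of a fragmented gene, NJ tends to place the two fragments — which
share no sequence, hence sit far from everything — as a terminal cherry,
and once two unrelated pieces are pairwise-aligned they stack on top of
each other and can never be separated by later profile merges. Average
linkage attaches each piece to the growing full-length profile instead,
which carries the context needed to place it at the correct end. Gap and
`X` positions carry no frequency mass, so gappy columns score
proportionally less and spacers neither attract nor repel the alignment.
Ungapping any row always reproduces the input sequence exactly; this
conservation invariant is asserted after every alignment. An external
FASTA-in/aligned-FASTA-out aligner (MUSCLE- or MAFFT-style) can be
substituted via configuration; no fidelity to a specific external tool or
version is attempted.

## Cluster merging

Each cluster MSA becomes a position-specific log-odds profile: match
columns are those with ≤ 50 % gaps; emission probabilities are residue
counts with a 0.1-per-residue pseudocount, normalised and log-odds-scored
in bits against BLOSUM62 background frequencies. Profiles carry no learned
transition probabilities — the discriminative machinery of this method is
the per-cluster threshold, not HMM transition estimation — and
sequence-vs-profile scoring is local alignment over match columns with
affine gap penalties of 10 bits open / 1 bit extend. A plug-in parser for
HMMER `--tblout` per-sequence bit scores exists for users who want exact
HMMER semantics; it defaults to full-sequence scores.

The *selfbit* of a cluster is the minimum profile score among the
cluster's own original members; profiles and selfbits are computed once,
from the original clusters, before any merging. A hit edge (gene → foreign
cluster) requires score ≥ selfbit — the boundary case, a gene exactly
matching the weakest original member, qualifies; a `--strict-selfbit` flag
switches the comparison to strictly-greater for users who read the
criterion exclusively. An optional absolute minimum bit score prunes edges
further; raising it can only refine the resulting partition. Gene-level
edges are relabelled to cluster–cluster edges and connected components
(isolated clusters remaining singletons) define the merge; merged cluster
ids are the lexicographically smallest constituent id, and merged MSAs are
rebuilt from the union of member sequences rather than stitched from the
old profiles, which keeps the conservation invariant trivially true.

## Defragmentation

Candidate clusters are those holding ≥ 2 calls from one genome. For a
candidate pair (A, B) in cluster G:

* relbit(A,B) = bit(A,B) / mean over C ∈ G∖{A,B} of bit(A,C), computed in
  both directions, maximum taken. The mean excludes both focal calls —
  "the rest of the cluster" — and counts non-scoring pairs as 0, which
  penalises sparse clusters consistently. A cluster consisting of exactly
  the focal pair leaves the statistic uninformative (the denominator would
  be the pair itself, forcing 1); such pairs are reported as unevaluable,
  never fused.
* percent overlap is the Jaccard ratio of the two rows' occupied columns
  in the cluster MSA: symmetric, in [0,1], 1 iff the occupancy patterns
  coincide, 0 iff disjoint.

A pair is fused only when **both** statistics fall strictly below their
thresholds (defaults 0.25/0.25, CLI-configurable; boundary values are
rejected). The 0.25 defaults were originally chosen by visual inspection
of real alignments, so the CLI keeps them adjustable and the fragment
report records every evaluated pair's statistics for exactly that kind of
inspection. N/C order comes from the rows' median occupied column (ties:
first occupied column, then id). When a genome has ≥ 3 calls in one
cluster, accepted pairs are chained by connected components and fused in
alignment order, one `X` per junction — the natural extension of the
pairwise rule, and labelled as such in reports. Fusion conserves the
residue multiset, replaces the fragments with one call (coordinates the
enclosing span, provenance the ordered fragment ids), and queues the
cluster for re-alignment.

## Pipeline order

Round-1 defragmentation and cluster merging both read the *original*
cluster state and neither sees the other's edits ("in tandem"); the
combine step then applies the merge partition, applies round-1 fusions
inside the merged clusters (fragments travel with their clusters), and
re-aligns what changed. Round-2 defragmentation runs on the combined
clusters — this is the pass that catches fragments whose pieces began in
different clusters, which is the reason a second pass exists at all.
Fusions are final once accepted; they are not re-scored against
merged-cluster profiles. Stages are also exposed individually
(`merge-only`, `defrag-only`) and compose: on inputs without
round-2-only cases, defrag-only followed by merge-only reproduces the
full run's clusters. Everything is deterministic given the inputs; the
CLI exits 0/2/3 for success / invalid input / stage failure and logs every
threshold actually used.

## Core genome and cause classification

A cluster is core when every genome contributes ≥ 1 member, single-copy
core (SCG) when every genome contributes exactly one — a fused gene counts
once, which is the entire point of fusing. The concatenated SCG alignment
orders clusters lexicographically by id (the package's own convention; no
claim is made about any particular ordering being canonical), one row per
genome, with a partitions table (cluster, half-open column span) for
partitioned phylogenetic models and a relaxed-PHYLIP copy for tree tools.
Tree inference itself is out of scope.

Each fused pair is classified from its genomic layout: *end_split* when
one fragment starts within `end_margin` of coordinate 0 and the other
stops within `end_margin` of the genome length (checked first, because an
origin-spanning gene also shows a huge apparent separation);
*frameshift_indel* when the separation is ≤ `indel_max_gap` with no
intervening gene call; *element_insertion* when a call lies between the
fragments or the separation exceeds `indel_max_gap`; overlapping
fragments (negative separation, e.g. from a short duplication) are
reported unclassified rather than forced into a category. The defaults —
`end_margin` 1000 bp, `indel_max_gap` 100 bp — are this package's own:
selfish-element ORFs are typically ≥ 300 bp while frameshift splits
displace pieces by tens of bp. Classification is invariant to which piece
was N-terminal. The three categories reconstruct the standard causes; no
attempt is made to identify the interrupting element's family.

## Synthetic pangenomes

The generator plants every phenomenon with known truth so the whole
pipeline is testable without downloads. Defaults describe the study
conditions used throughout: 20 genomes × 40 families; member sequences
derived from family ancestors (lengths 80–400, sampled from BLOSUM62
background frequencies) by per-site substitution at target
member-to-ancestor identity 0.85, replacements drawn
BLOSUM62-conditionally (∝ background·2^(S/2)) so diverged members remain
profile-recognisable; five fragments per cause; three split families;
three true-paralog decoys. Coordinates are bookkeeping at 3 bp per
residue, laid out so the classifier's margins hold by construction:
frameshift pieces 3–50 bp apart, element pieces separated by a planted
300–1200 bp ORF (which is a real gene call in its own singleton cluster),
end-split pieces flanking the origin, and interior genes kept ≥ 1.2 kb
from genome ends.

Split families are built as four 22-residue motif blocks (mutated at
identity 0.95 per member) alternating with linkers that are
subfamily-specific and internally diverse (identity 0.55 to the subfamily
linker ancestor), yielding ~28–31 % cross-subfamily identity — below the
0.35 minbit a pairwise workflow would need, while the shared motifs remain
detectable by profiles. One member per subfamily is *partial*: a
contiguous slice spanning two motifs. That member sets the cluster's
selfbit at conserved-core level, the way real mergeable clusters carry
short or highly diverged members; without it, every member's own
contribution to its profile pushes the selfbit above what any
cross-subfamily homolog can reach, and profile merging of cleanly
separated subfamilies is impossible in principle. Optionally a fragment
can be planted *across* the two clusters of a split family
(`n_round2_fragments`), which is resolvable only in pipeline round 2.

What the generator does **not** emulate: insertions/deletions within
families (members are ancestor-length), realistic genome architecture
(operons, tRNAs, overlapping genes), sequencing or assembly error, and
compositional biases. Passing tests therefore demonstrate the pipeline's
logic — statistics, thresholds, ordering, bookkeeping — under controlled
divergence, not its end-to-end behaviour on real RefSeq phage sets, whose
outcomes additionally depend on the upstream gene caller and clusterer.

## Numerical choices

* Profile and pairwise dynamic programming use a column-sweep formulation
  with the in-column gap recurrence resolved by a running-max scan;
  batched profile scoring runs in float32 (scores are O(10²)–O(10³) bits,
  so rounding is ~10⁻³ bits and identical for identical inputs), final
  scores reported as float64.
* All report rows are fully sorted and floats formatted at fixed
  precision, so repeated runs are byte-identical.
* Ties in fragment ordering fall back from median occupied column to
  first occupied column to lexicographic id; cluster and merged-cluster
  ids are lexicographic minima; nothing depends on dict iteration order.
* Test and acceptance problem sizes (8–20 genomes, 10–40 families, 3–10
  replicate seeds) were chosen as the smallest sets at which every planted
  phenomenon occurs several times per replicate.

## Known limitations

* relbit is undefined for two-member clusters (reported, not fused), and
  weak for clusters of 3–4 members where the mean rests on one or two
  comparisons.
* The internal progressive aligner is adequate for the divergence levels
  the generator produces; heavily gapped real families may warrant the
  external-aligner seam.
* Fragments split across different contigs of draft assemblies are only
  handled insofar as they land in mergeable clusters; nucleotide-level
  breakpoint refinement is out of scope.
* The cause classifier sees only coordinates: an element insertion whose
  element was not called as a gene and sits within 100 bp is
  indistinguishable from a frameshift.
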