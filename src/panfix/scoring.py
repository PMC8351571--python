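"""Pairwise local alignment, bit scores, and minbit-based bootstrap clustering.

Bit scores follow the Karlin–Altschul normalisation
``bits = (lambda * raw - ln K) / ln 2`` with gapped-BLOSUM62 defaults
(lambda = 0.267, K = 0.041, gap open 11 / extend 1, a gap of length k
costing open + k * extend). A raw score <= 0 is reported as 0 bits,
mirroring how a search tool reports no hit.

The "X" residue (unknowns and fusion junctions) scores 0 against every
residue so it never attracts nor repels an alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import AA_ORDER, GeneCall, InputError

#: BLOSUM62 background residue frequencies (Robinson & Robinson, as used by
#: NCBI), in AA_ORDER.
BLOSUM62_BACKGROUND = np.array(
    [
        0.07422, 0.05161, 0.04465, 0.05363, 0.02469, 0.03426, 0.05431,
        0.07415, 0.02621, 0.06792, 0.09891, 0.05816, 0.02499, 0.04742,
        0.03854, 0.05723, 0.05089, 0.03228, 0.01303, 0.06441,
    ]
)
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()


def load_matrix(name_or_path: str = "BLOSUM62") -> substitution_matrices.Array:
    """Load a substitution matrix by name or from an NCBI-format file.

    The X row/column is forced to 0 everywhere. For BLOSUM62 the matrix is
    checked to be symmetric with row-maximal diagonal entries over the 20
    standard residues.
    """
    try:
        mat = substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        mat = substitution_matrices.read(name_or_path)
    mat = mat.copy()
    if "X" in mat.alphabet:
        for a in mat.alphabet:
            mat["X", a] = 0.0
            mat[a, "X"] = 0.0
    if name_or_path == "BLOSUM62":
        for a in AA_ORDER:
            for b in AA_ORDER:
                if mat[a, b] != mat[b, a]:
                    raise ValueError("BLOSUM62 load check: matrix not symmetric")
            if mat[a, a] < max(mat[a, b] for b in AA_ORDER if b != a):
                raise ValueError(f"BLOSUM62 load check: diagonal not row max at {a}")
    return mat


@dataclass
class ScoringParams:
    """Substitution matrix, affine gap costs and Karlin–Altschul parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    matrix: Optional[substitution_matrices.Array] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise InputError("Karlin-Altschul parameters must be positive")
        if self.matrix is None:
            self.matrix = load_matrix(self.matrix_name)

    def raw_to_bits(self, raw: float) -> float:
        if raw <= 0:
            return 0.0
        return (self.karlin_lambda * raw - math.log(self.karlin_k)) / math.log(2)


@dataclass
class PairwiseHit:
    """One local alignment between two sequences."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    query_span: Tuple[int, int]  # half-open residue interval
    subject_span: Tuple[int, int]


def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = params.matrix
    # cost(k) = open + k * extend  =>  first gap residue pays open + extend
    aln.open_gap_score = -(params.gap_open + params.gap_extend)
    aln.extend_gap_score = -params.gap_extend
    return aln


def local_align_raw(a: str, b: str, params: ScoringParams) -> float:
    """Optimal Smith–Waterman raw score (score-only fast path)."""
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    return float(_aligner(params).score(a, b))


def local_align_bits(
    a: str,
    b: str,
    params: ScoringParams,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseHit:
    """Optimal local alignment with spans, raw and bit scores."""
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    aligner = _aligner(params)
    alignments = aligner.align(a, b)
    raw = float(alignments.score)
    if raw <= 0:
        return PairwiseHit(query_id, subject_id, raw, 0.0, (0, 0), (0, 0))
    best = alignments[0]
    qspan = (int(best.coordinates[0][0]), int(best.coordinates[0][-1]))
    sspan = (int(best.coordinates[1][0]), int(best.coordinates[1][-1]))
    return PairwiseHit(query_id, subject_id, raw, params.raw_to_bits(raw), qspan, sspan)


def local_identity(a: str, b: str, params: ScoringParams) -> float:
    """Fractional identity over the optimal local alignment (0 when no hit)."""
    aligner = _aligner(params)
    alignments = aligner.align(a, b)
    if float(alignments.score) <= 0:
        return 0.0
    counts = alignments[0].counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def bit_score(a: str, b: str, params: ScoringParams) -> float:
    return params.raw_to_bits(local_align_raw(a, b, params))


def minbit(a: str, b: str, params: ScoringParams) -> float:
    """bit(a,b) divided by the smaller self bit score; symmetric in a, b."""
    self_a = bit_score(a, a, params)
    self_b = bit_score(b, b, params)
    denom = min(self_a, self_b)
    if denom <= 0:
        raise InputError("minbit undefined: a sequence has zero self bit score")
    return bit_score(a, b, params) / denom


def read_blast_tab(path: str) -> List[PairwiseHit]:
    """Plug-in seam: parse blastp tabular output (outfmt 6) as PairwiseHits.

    Expected fields: qseqid sseqid bitscore qstart qend sstart send
    (1-based inclusive coordinates, converted to half-open on read).
    """
    hits: List[PairwiseHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise InputError(f"blast tabular line has {len(parts)} fields: {line!r}")
            q, s, bits, qs, qe, ss, se = parts[:7]
            hits.append(
                PairwiseHit(
                    q, s, float("nan"), float(bits),
                    (int(qs) - 1, int(qe)), (int(ss) - 1, int(se)),
                )
            )
    return hits


def bootstrap_clusters(
    calls: Iterable[GeneCall],
    params: Optional[ScoringParams] = None,
    minbit_threshold: float = 0.35,
    prefix: str = "GC_",
) -> Dict[str, str]:
    """All-vs-all minbit graph clustering, for inputs with no prior clusters.

    Edges connect call pairs with minbit >= threshold (default 0.35, the
    standard choice for diverse phage proteomes); clusters are the connected
    components. Returns gene_call_id -> cluster_id with deterministic ids
    (prefix + lexicographically smallest member id).
    """
    params = params or ScoringParams()
    calls = sorted(calls, key=lambda c: c.id)
    if not calls:
        raise InputError("bootstrap clustering needs at least one gene call")
    selfbits = {c.id: bit_score(c.aa_seq, c.aa_seq, params) for c in calls}
    graph = nx.Graph()
    graph.add_nodes_from(c.id for c in calls)
    for i, a in enumerate(calls):
        for b in calls[i + 1:]:
            mb = bit_score(a.aa_seq, b.aa_seq, params) / min(
                selfbits[a.id], selfbits[b.id]
            )
            if mb >= minbit_threshold:
                graph.add_edge(a.id, b.id, weight=mb)
    out: Dict[str, str] = {}
    for comp in nx.connected_components(graph):
        cid = prefix + min(comp)
        for g in comp:
            out[g] = cid
    return out
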