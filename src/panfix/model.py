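"""Core in-memory objects shared by every pipeline stage.

The pipeline operates on amino-acid gene calls grouped into gene clusters.
Coordinates are stored 0-based half-open on the reported genome; strand is
carried as metadata only (gene calling happens upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

#: the 20 standard residues in NCBI substitution-matrix order
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: residues accepted in input sequences ("X" marks unknowns and fusion
#: junctions; a single trailing "*" stop symbol is stripped on read)
VALID_RESIDUES = frozenset(AA_ORDER) | {"X"}

GAP = "-"


class InputError(ValueError):
    """Invalid or inconsistent user input (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str, cluster_ids: Iterable[str] = ()):
        self.stage = stage
        self.cluster_ids = sorted(cluster_ids)
        suffix = f" [clusters: {', '.join(self.cluster_ids)}]" if self.cluster_ids else ""
        super().__init__(f"stage {stage!r}: {message}{suffix}")


@dataclass
class GeneCall:
    """One called ORF.

    ``provenance`` is empty for original calls; fused calls carry the ordered
    (N-terminal first) list of the original call ids they splice together.
    """

    id: str
    genome_id: str
    start: int  # 0-based, inclusive (bp)
    stop: int  # 0-based, exclusive (bp)
    strand: str  # "+" or "-"
    aa_seq: str
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 0 or self.stop <= self.start:
            raise InputError(
                f"gene call {self.id!r}: invalid coordinates [{self.start}, {self.stop})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"gene call {self.id!r}: strand must be '+' or '-'")
        if self.aa_seq.endswith("*"):
            self.aa_seq = self.aa_seq[:-1]
        if not self.aa_seq:
            raise InputError(f"gene call {self.id!r}: empty amino-acid sequence")
        bad = set(self.aa_seq) - VALID_RESIDUES
        if bad:
            raise InputError(
                f"gene call {self.id!r}: invalid residues {sorted(bad)!r}"
            )

    @property
    def is_fused(self) -> bool:
        return bool(self.provenance)

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass
class GenomeRecord:
    """A reported genome: its length and its gene calls ordered by start."""

    genome_id: str
    length: int
    gene_call_ids: List[str] = field(default_factory=list)


@dataclass
class Msa:
    """A per-cluster multiple sequence alignment (rows keyed by call id)."""

    cluster_id: str
    rows: List[Tuple[str, str]]

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __post_init__(self) -> None:
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            raise ValueError(f"MSA {self.cluster_id!r}: ragged rows {sorted(widths)}")

    def row(self, call_id: str) -> str:
        for cid, s in self.rows:
            if cid == call_id:
                return s
        raise KeyError(f"MSA {self.cluster_id!r} has no row for {call_id!r}")

    def ungapped(self, call_id: str) -> str:
        return self.row(call_id).replace(GAP, "")

    def occupied_columns(self, call_id: str) -> Set[int]:
        return {i for i, c in enumerate(self.row(call_id)) if c != GAP}


@dataclass
class FragmentPair:
    """A candidate fragmented gene: two same-genome calls in one cluster."""

    cluster_id: str
    call_a: str
    call_b: str
    relbit: Optional[float]  # None when unevaluable
    percent_overlap: Optional[float]
    n_term: Optional[str]
    decision: str  # "fused" | "rejected" | "unevaluable"
    round: int


@dataclass
class FragClassRecord:
    """Predicted cause of one fragmentation event."""

    call_a: str
    call_b: str
    genome_id: str
    separation_bp: int
    intervening_calls: int
    cause: str  # frameshift_indel | element_insertion | end_split | unclassified


@dataclass
class PangenomeState:
    """The evolving pangenome: genomes, calls (original + fused), clusters.

    ``clusters`` maps cluster id to the *live* member call ids; calls removed
    by fusion stay in ``calls`` so provenance and coordinates remain
    resolvable. ``stale`` lists clusters whose MSA must be rebuilt.
    """

    calls: Dict[str, GeneCall] = field(default_factory=dict)
    genomes: Dict[str, GenomeRecord] = field(default_factory=dict)
    clusters: Dict[str, Set[str]] = field(default_factory=dict)
    msas: Dict[str, Msa] = field(default_factory=dict)
    stale: Set[str] = field(default_factory=set)
    merge_map: Dict[str, str] = field(default_factory=dict)
    fragment_pairs: List[FragmentPair] = field(default_factory=list)
    fragclass_records: List[FragClassRecord] = field(default_factory=list)

    def assignment(self) -> Dict[str, str]:
        """Live mapping gene_call_id -> cluster_id."""
        out: Dict[str, str] = {}
        for cid, members in self.clusters.items():
            for g in members:
                if g in out:
                    raise InputError(
                        f"gene call {g!r} is assigned to clusters "
                        f"{out[g]!r} and {cid!r}"
                    )
                out[g] = cid
        return out

    def live_calls(self) -> Dict[str, GeneCall]:
        live = set().union(*self.clusters.values()) if self.clusters else set()
        return {g: self.calls[g] for g in live}

    def cluster_of(self, call_id: str) -> str:
        for cid, members in self.clusters.items():
            if call_id in members:
                return cid
        raise KeyError(call_id)
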