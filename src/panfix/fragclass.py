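"""Classify the likely cause of each fragmentation event.

Three mechanisms split a gene call: an indel introducing an early stop (the
pieces sit nearly adjacent on the genome), interruption by a selfish
element such as a homing endonuclease or intron-encoded ORF (a large gap,
usually containing the element's own gene call), and artificial splitting
across the ends of the reported (circularly permuted) genome. The rules
below reconstruct those categories from fragment separation alone; the
end-of-genome signature is diagnosed first because it also produces a
large apparent separation.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

from .model import (
    FragClassRecord,
    FragmentPair,
    GeneCall,
    GenomeRecord,
    InputError,
    PangenomeState,
)

#: fragments within this many bp of the genome's ends flag an end split;
#: homing-endonuclease ORFs are typically >=300 bp, so 1 kb is generous
DEFAULT_END_MARGIN = 1000
#: frameshift/indel splits displace the pieces by at most tens of bp
DEFAULT_INDEL_MAX_GAP = 100


def classify_pair(
    call_a: GeneCall,
    call_b: GeneCall,
    genome: GenomeRecord,
    all_calls: Optional[dict] = None,
    end_margin: int = DEFAULT_END_MARGIN,
    indel_max_gap: int = DEFAULT_INDEL_MAX_GAP,
) -> FragClassRecord:
    """Classify one fused pair from its genome coordinates.

    The decision is invariant to which fragment was N-terminal: only the
    genomic layout matters.
    """
    if call_a.genome_id != call_b.genome_id:
        raise InputError(
            f"cannot classify calls from different genomes: "
            f"{call_a.id!r} ({call_a.genome_id}), {call_b.id!r} ({call_b.genome_id})"
        )
    if call_a.genome_id != genome.genome_id:
        raise InputError("genome record does not match the calls' genome")
    upstream, downstream = sorted((call_a, call_b), key=lambda c: (c.start, c.id))
    separation = downstream.start - upstream.stop

    intervening = 0
    if all_calls:
        for other_id in genome.gene_call_ids:
            if other_id in (call_a.id, call_b.id) or other_id not in all_calls:
                continue
            other = all_calls[other_id]
            if other.start >= upstream.stop and other.stop <= downstream.start:
                intervening += 1

    near_start = min(call_a.start, call_b.start) < end_margin
    near_end = max(call_a.stop, call_b.stop) > genome.length - end_margin
    if near_start and near_end:
        cause = "end_split"
    elif 0 <= separation <= indel_max_gap and intervening == 0:
        cause = "frameshift_indel"
    elif intervening >= 1 or separation > indel_max_gap:
        cause = "element_insertion"
    else:
        cause = "unclassified"  # e.g. overlapping calls from a short duplication
    return FragClassRecord(
        call_a=min(call_a.id, call_b.id),
        call_b=max(call_a.id, call_b.id),
        genome_id=call_a.genome_id,
        separation_bp=separation,
        intervening_calls=intervening,
        cause=cause,
    )


def classify_fusions(
    state: PangenomeState,
    end_margin: int = DEFAULT_END_MARGIN,
    indel_max_gap: int = DEFAULT_INDEL_MAX_GAP,
) -> List[FragClassRecord]:
    """Classify every adjacent fragment pair of every fused call in a state.

    Chains of three or more fragments contribute one record per junction
    (consecutive fragments in genome-coordinate order).
    """
    records: List[FragClassRecord] = []
    for call in sorted(state.calls.values(), key=lambda c: c.id):
        if not call.is_fused:
            continue
        parts = sorted(
            (state.calls[p] for p in call.provenance), key=lambda c: (c.start, c.id)
        )
        genome = state.genomes[call.genome_id]
        for a, b in zip(parts, parts[1:]):
            records.append(
                classify_pair(
                    a, b, genome, all_calls=state.calls,
                    end_margin=end_margin, indel_max_gap=indel_max_gap,
                )
            )
    state.fragclass_records = records
    return records
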