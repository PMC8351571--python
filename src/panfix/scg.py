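"""Core-genome summary and the concatenated single-copy-core alignment.

A cluster is *core* when every genome contributes at least one member and
*single-copy core* (SCG) when every genome contributes exactly one. A fused
gene counts as one copy — that is the entire point of defragmentation: a
gene split in one genome otherwise evicts its whole cluster from the SCG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import GAP, InputError, Msa, PangenomeState, StageError

log = logging.getLogger("panfix")


@dataclass
class CoreSummary:
    """Per-cluster presence counts per genome, with core/SCG flags."""

    counts: Dict[str, Dict[str, int]]  # cluster_id -> genome_id -> n calls
    core: List[str]
    scg: List[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": cid,
                "n_genomes_present": sum(1 for v in by_g.values() if v > 0),
                "min_copies": min(by_g.values()),
                "max_copies": max(by_g.values()),
                "core": cid in set(self.core),
                "scg": cid in set(self.scg),
            }
            for cid, by_g in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id", "n_genomes_present", "min_copies", "max_copies",
                "core", "scg",
            ],
        )


def core_summary(state: PangenomeState) -> CoreSummary:
    """Count cluster membership per genome under the current assignment."""
    genome_ids = sorted(state.genomes)
    counts: Dict[str, Dict[str, int]] = {}
    for cid in sorted(state.clusters):
        by_g = {g: 0 for g in genome_ids}
        for call_id in state.clusters[cid]:
            by_g[state.calls[call_id].genome_id] += 1
        counts[cid] = by_g
    core = [c for c, by_g in counts.items() if by_g and min(by_g.values()) >= 1]
    scg = [c for c in core if set(counts[c].values()) == {1}]
    return CoreSummary(counts, sorted(core), sorted(scg))


def concatenated_alignment(
    state: PangenomeState, scg_ids: Sequence[str]
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Concatenate each genome's single row across the listed SCG clusters.

    Clusters are taken in lexicographic id order; the companion partitions
    table gives each cluster's half-open column span for partitioned
    phylogenetic models. An empty SCG list yields an empty alignment (with
    a warning) rather than an error.
    """
    summary = core_summary(state)
    scg_set = set(summary.scg)
    bad = sorted(set(scg_ids) - scg_set)
    if bad:
        raise InputError(f"clusters are not single-copy core: {bad}")
    genome_ids = sorted(state.genomes)
    if not scg_ids:
        log.warning("no single-copy core clusters; concatenated alignment is empty")
        return {g: "" for g in genome_ids}, pd.DataFrame(
            columns=["cluster_id", "start_column", "end_column"]
        )
    pieces: Dict[str, List[str]] = {g: [] for g in genome_ids}
    partitions = []
    offset = 0
    for cid in sorted(scg_ids):
        msa = state.msas.get(cid)
        if msa is None:
            raise StageError("scg", "cluster has no current MSA", [cid])
        by_genome = {
            state.calls[row_id].genome_id: row for row_id, row in msa.rows
        }
        for g in genome_ids:
            pieces[g].append(by_genome[g])
        partitions.append(
            {"cluster_id": cid, "start_column": offset, "end_column": offset + msa.width}
        )
        offset += msa.width
    rows = {g: "".join(pieces[g]) for g in genome_ids}
    widths = {len(s) for s in rows.values()}
    assert len(widths) == 1, "concatenated rows must share one width"
    return rows, pd.DataFrame(
        partitions, columns=["cluster_id", "start_column", "end_column"]
    )


def write_scg_outputs(
    state: PangenomeState, outdir: str | Path
) -> CoreSummary:
    """Emit core_summary.tsv, concatenated_alignment.faa, partitions.tsv,
    and a relaxed-PHYLIP copy for tree tools."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = core_summary(state)
    summary.to_frame().to_csv(out / "core_summary.tsv", sep="\t", index=False)
    rows, partitions = concatenated_alignment(state, summary.scg)
    with open(out / "concatenated_alignment.faa", "w") as fh:
        for g in sorted(rows):
            fh.write(f">{g}\n{rows[g]}\n")
    partitions.to_csv(out / "partitions.tsv", sep="\t", index=False)
    if rows and next(iter(rows.values())):
        with open(out / "concatenated_alignment.phy", "w") as fh:
            width = len(next(iter(rows.values())))
            fh.write(f"{len(rows)} {width}\n")
            for g in sorted(rows):
                fh.write(f"{g}  {rows[g]}\n")
    return summary
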