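"""On-disk artifacts: FASTA gene calls, coordinate/cluster tables, MSAs,
and the merge/fragment/SCG/fragclass reports.

Conventions
-----------
* Coordinates are 0-based half-open internally; tables written by this
  package use that convention. 1-based inclusive input tables are converted
  on read with ``one_based=True``.
* A single trailing "*" stop symbol is stripped from sequences on read and
  never written.
* Every report is TSV with a header and fully sorted rows, so diffs are
  stable across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GAP,
    GeneCall,
    GenomeRecord,
    InputError,
    Msa,
    PangenomeState,
)

log = logging.getLogger("panfix")

COORD_COLUMNS = ["genome_id", "gene_call_id", "start", "stop", "strand", "genome_length"]
CLUSTER_COLUMNS = ["gene_call_id", "genome_id", "cluster_id"]
_ANVIO_MAP = {
    "gene_callers_id": "gene_call_id",
    "genome_name": "genome_id",
    "gene_cluster_id": "cluster_id",
}


def read_gene_calls(
    fasta_path: str | Path,
    coords_path: str | Path,
    one_based: bool = False,
) -> Tuple[Dict[str, GeneCall], Dict[str, GenomeRecord]]:
    """Read amino-acid gene calls plus their genome coordinates.

    The FASTA ids must match the coordinate table's ``gene_call_id`` column
    exactly; any mismatch, duplicate id, or invalid interval is a hard error.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()

    table = pd.read_csv(coords_path, sep="\t", dtype=str)
    missing_cols = [c for c in COORD_COLUMNS if c not in table.columns]
    if missing_cols:
        raise InputError(f"coordinate table lacks columns: {missing_cols}")
    if table["gene_call_id"].duplicated().any():
        dups = sorted(table.loc[table["gene_call_id"].duplicated(), "gene_call_id"])
        raise InputError(f"duplicate gene_call_id rows in coordinate table: {dups}")

    table_ids = set(table["gene_call_id"])
    only_fasta = sorted(set(seqs) - table_ids)
    only_table = sorted(table_ids - set(seqs))
    if only_fasta or only_table:
        raise InputError(
            "FASTA/coordinate id mismatch: "
            f"only in FASTA {only_fasta}; only in table {only_table}"
        )

    calls: Dict[str, GeneCall] = {}
    lengths: Dict[str, int] = {}
    for row in table.itertuples(index=False):
        start, stop = int(row.start), int(row.stop)
        if one_based:
            start -= 1  # 1-based inclusive -> 0-based half-open
        if stop <= start:
            raise InputError(
                f"gene call {row.gene_call_id!r}: stop <= start "
                f"({stop} <= {start})"
            )
        calls[row.gene_call_id] = GeneCall(
            id=row.gene_call_id,
            genome_id=row.genome_id,
            start=start,
            stop=stop,
            strand=row.strand,
            aa_seq=seqs[row.gene_call_id],
        )
        glen = int(row.genome_length)
        prev = lengths.setdefault(row.genome_id, glen)
        if prev != glen:
            raise InputError(f"genome {row.genome_id!r}: inconsistent genome_length")
        if stop > glen:
            raise InputError(
                f"gene call {row.gene_call_id!r}: stop {stop} exceeds genome "
                f"length {glen}"
            )

    genomes: Dict[str, GenomeRecord] = {}
    for gid, glen in lengths.items():
        ids = sorted(
            (c.id for c in calls.values() if c.genome_id == gid),
            key=lambda i: (calls[i].start, i),
        )
        genomes[gid] = GenomeRecord(gid, glen, ids)
    return calls, genomes


def write_gene_calls(
    calls: Dict[str, GeneCall],
    genomes: Dict[str, GenomeRecord],
    fasta_path: str | Path,
    coords_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(c.aa_seq), id=c.id, description="")
        for c in sorted(calls.values(), key=lambda c: c.id)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "genome_id": c.genome_id,
            "gene_call_id": c.id,
            "start": c.start,
            "stop": c.stop,
            "strand": c.strand,
            "genome_length": genomes[c.genome_id].length,
        }
        for c in sorted(calls.values(), key=lambda c: c.id)
    ]
    pd.DataFrame(rows, columns=COORD_COLUMNS).to_csv(coords_path, sep="\t", index=False)


def read_cluster_table(
    path: str | Path,
    dialect: str = "generic-3col",
    all_call_ids: Optional[Iterable[str]] = None,
) -> Dict[str, str]:
    """Read a gene_call_id -> cluster_id mapping.

    ``generic-3col`` expects TSV columns gene_call_id, genome_id, cluster_id;
    ``anvio-summary`` expects gene_callers_id, genome_name, gene_cluster_id
    and tolerates (ignores) any extra columns. Calls listed under two
    clusters are a hard error. Calls in ``all_call_ids`` but absent from the
    table become fresh singleton clusters (with a logged warning).
    """
    if dialect not in ("generic-3col", "anvio-summary"):
        raise InputError(f"unknown cluster-table dialect {dialect!r}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "anvio-summary":
        missing = [c for c in _ANVIO_MAP if c not in table.columns]
        if missing:
            raise InputError(f"anvio-summary table lacks columns: {missing}")
        table = table.rename(columns=_ANVIO_MAP)
    missing = [c for c in ("gene_call_id", "cluster_id") if c not in table.columns]
    if missing:
        raise InputError(f"cluster table lacks columns: {missing}")

    mapping: Dict[str, str] = {}
    for row in table.itertuples(index=False):
        gid, cid = row.gene_call_id, row.cluster_id
        if gid in mapping and mapping[gid] != cid:
            raise InputError(
                f"gene call {gid!r} listed under clusters {mapping[gid]!r} and {cid!r}"
            )
        mapping[gid] = cid

    if all_call_ids is not None:
        for gid in sorted(all_call_ids):
            if gid not in mapping:
                singleton = f"singleton_{gid}"
                log.warning(
                    "gene call %r missing from cluster table; assigned %r",
                    gid, singleton,
                )
                mapping[gid] = singleton
    return mapping


def write_cluster_table(
    assignment: Dict[str, str], calls: Dict[str, GeneCall], path: str | Path
) -> None:
    rows = [
        {"gene_call_id": g, "genome_id": calls[g].genome_id, "cluster_id": c}
        for g, c in sorted(assignment.items())
    ]
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def write_msa(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, row in sorted(msa.rows):
            fh.write(f">{cid}\n{row}\n")


def read_msa(path: str | Path, cluster_id: str) -> Msa:
    rows = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Msa(cluster_id, sorted(rows))


def write_reports(state: PangenomeState, outdir: str | Path) -> None:
    """Emit every pipeline report into ``outdir`` (created if needed).

    Files: merge_report.tsv, fragment_report.tsv, fused_genes.faa,
    clusters.tsv, fragclass.tsv, and per-cluster MSAs under msa/.
    All tables carry headers even when empty; rows are fully sorted.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "msa").mkdir(exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc

    merge_rows = [
        {"old_cluster_id": old, "merged_cluster_id": new}
        for old, new in sorted(state.merge_map.items())
    ]
    pd.DataFrame(
        merge_rows, columns=["old_cluster_id", "merged_cluster_id"]
    ).to_csv(out / "merge_report.tsv", sep="\t", index=False)

    frag_rows = [
        {
            "cluster_id": p.cluster_id,
            "call_a": p.call_a,
            "call_b": p.call_b,
            "relbit": "" if p.relbit is None else f"{p.relbit:.6f}",
            "percent_overlap": (
                "" if p.percent_overlap is None else f"{p.percent_overlap:.6f}"
            ),
            "n_term": p.n_term or "",
            "decision": p.decision,
            "round": p.round,
        }
        for p in sorted(
            state.fragment_pairs, key=lambda p: (p.round, p.cluster_id, p.call_a, p.call_b)
        )
    ]
    pd.DataFrame(
        frag_rows,
        columns=[
            "cluster_id", "call_a", "call_b", "relbit", "percent_overlap",
            "n_term", "decision", "round",
        ],
    ).to_csv(out / "fragment_report.tsv", sep="\t", index=False)

    fused = sorted(
        (c for c in state.calls.values() if c.is_fused), key=lambda c: c.id
    )
    with open(out / "fused_genes.faa", "w") as fh:
        for c in fused:
            fh.write(f">{c.id} provenance={'+'.join(c.provenance)}\n{c.aa_seq}\n")

    write_cluster_table(state.assignment(), state.calls, out / "clusters.tsv")

    # corrected pangenome: the live calls (fused replacing their fragments),
    # re-usable as direct input to another run
    live = state.live_calls()
    write_gene_calls(
        live, state.genomes, out / "corrected_calls.faa", out / "corrected_coords.tsv"
    )

    fc_rows = [
        {
            "call_a": r.call_a,
            "call_b": r.call_b,
            "genome_id": r.genome_id,
            "separation_bp": r.separation_bp,
            "intervening_calls": r.intervening_calls,
            "cause": r.cause,
        }
        for r in sorted(state.fragclass_records, key=lambda r: (r.call_a, r.call_b))
    ]
    pd.DataFrame(
        fc_rows,
        columns=[
            "call_a", "call_b", "genome_id", "separation_bp",
            "intervening_calls", "cause",
        ],
    ).to_csv(out / "fragclass.tsv", sep="\t", index=False)

    for cid in sorted(state.msas):
        if cid in state.clusters:
            write_msa(state.msas[cid], out / "msa" / f"{_safe(cid)}.faa")


def _safe(cluster_id: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in cluster_id)
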