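"""Identify and fuse fragmented gene calls.

A gene split by an indel, an inserted selfish element, or the reported
genome's ends shows up as two same-genome calls in one cluster that (1)
occupy disjoint parts of the cluster alignment and (2) score far lower
against each other than against the rest of the cluster. Two statistics
capture this:

* ``relbit``: the pairwise bit score between the two calls divided by each
  call's mean bit score against the other cluster members (both directions;
  the maximum is used);
* ``percent overlap``: the Jaccard ratio of the two rows' occupied columns
  in the cluster MSA.

Pairs below both thresholds (default 0.25 / 0.25, strict <) are fused
N-terminal-first with a single "X" spacer at each junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .model import (
    FragmentPair,
    GeneCall,
    InputError,
    Msa,
    PangenomeState,
    StageError,
)
from .scoring import ScoringParams, bit_score

DEFAULT_RELBIT = 0.25
DEFAULT_OVERLAP = 0.25


def find_duplicate_clusters(state: PangenomeState) -> List[str]:
    """Clusters containing at least two calls from the same genome."""
    out = []
    for cid in sorted(state.clusters):
        seen: Set[str] = set()
        for g in state.clusters[cid]:
            genome = state.calls[g].genome_id
            if genome in seen:
                out.append(cid)
                break
            seen.add(genome)
    return out


def relbit(
    call_a: GeneCall,
    call_b: GeneCall,
    cluster_members: Sequence[GeneCall],
    params: Optional[ScoringParams] = None,
    _bit_cache: Optional[Dict[Tuple[str, str], float]] = None,
) -> Optional[float]:
    """Relative bit score of a candidate fragment pair.

    relbit(A,B) = bit(A,B) / mean over C in G\\{A,B} of bit(A,C), and
    likewise for B; the maximum of the two directions is returned. Pairs
    with no scoring alignment contribute 0 bits to the mean. When the
    cluster contains nobody besides A and B the statistic is uninformative
    and None is returned (the pair is "unevaluable").
    """
    params = params or ScoringParams()
    others = [c for c in cluster_members if c.id not in (call_a.id, call_b.id)]
    if not others:
        return None

    def bit(x: GeneCall, y: GeneCall) -> float:
        if _bit_cache is not None:
            key = (min(x.id, y.id), max(x.id, y.id))
            if key not in _bit_cache:
                _bit_cache[key] = bit_score(x.aa_seq, y.aa_seq, params)
            return _bit_cache[key]
        return bit_score(x.aa_seq, y.aa_seq, params)

    pair_bits = bit(call_a, call_b)
    mean_a = float(np.mean([bit(call_a, c) for c in others]))
    mean_b = float(np.mean([bit(call_b, c) for c in others]))
    return relbit_from_means(pair_bits, mean_a, mean_b)


def relbit_from_means(pair_bits: float, mean_a: float, mean_b: float) -> Optional[float]:
    """Compose the relative-bit statistic from its parts.

    Each direction divides the focal pair's bit score by that call's mean
    bit score against the rest of the cluster; the maximum of the two
    directions is the statistic. Directions with a zero mean are undefined;
    if both are, the pair is unevaluable (None).
    """
    vals = [pair_bits / m for m in (mean_a, mean_b) if m > 0]
    return max(vals) if vals else None


def fusion_decision(
    rb: Optional[float],
    po: float,
    relbit_thr: float = DEFAULT_RELBIT,
    overlap_thr: float = DEFAULT_OVERLAP,
) -> str:
    """Decision rule: fuse only when BOTH statistics fall strictly below
    their thresholds; boundary values are rejected."""
    if rb is None:
        return "unevaluable"
    return "fused" if (rb < relbit_thr and po < overlap_thr) else "rejected"


def percent_overlap(msa: Msa, call_a: str, call_b: str) -> float:
    """Jaccard overlap of the two rows' occupied (non-gap) MSA columns."""
    cols_a = msa.occupied_columns(call_a)
    cols_b = msa.occupied_columns(call_b)
    union = cols_a | cols_b
    if not union:
        return 0.0
    return len(cols_a & cols_b) / len(union)


def order_fragments(msa: Msa, call_a: str, call_b: str) -> Tuple[str, str]:
    """Return (n_term, c_term) by median occupied column; ties fall back to
    first occupied column, then lexicographic id."""

    def key(cid: str):
        cols = sorted(msa.occupied_columns(cid))
        return (float(np.median(cols)), cols[0], cid)

    first, second = sorted([call_a, call_b], key=key)
    return first, second


def call_fragments(
    state: PangenomeState,
    cluster_id: str,
    relbit_thr: float = DEFAULT_RELBIT,
    overlap_thr: float = DEFAULT_OVERLAP,
    round_no: int = 1,
    params: Optional[ScoringParams] = None,
) -> List[FragmentPair]:
    """Evaluate every same-genome pair in one cluster.

    A pair is fused iff relbit < relbit_thr AND percent_overlap < overlap_thr
    (strict inequalities: boundary values are rejected). Unevaluable pairs
    (cluster of exactly the focal pair) are reported with a sentinel.
    """
    params = params or ScoringParams()
    if cluster_id not in state.clusters:
        raise InputError(f"unknown cluster {cluster_id!r}")
    msa = state.msas.get(cluster_id)
    if msa is None:
        raise StageError("defrag", "cluster has no current MSA", [cluster_id])
    members = sorted(
        (state.calls[g] for g in state.clusters[cluster_id]), key=lambda c: c.id
    )
    by_genome: Dict[str, List[GeneCall]] = {}
    for c in members:
        by_genome.setdefault(c.genome_id, []).append(c)

    cache: Dict[Tuple[str, str], float] = {}
    pairs: List[FragmentPair] = []
    for genome in sorted(by_genome):
        calls = by_genome[genome]
        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                a, b = calls[i], calls[j]
                rb = relbit(a, b, members, params, _bit_cache=cache)
                po = percent_overlap(msa, a.id, b.id)
                decision = fusion_decision(rb, po, relbit_thr, overlap_thr)
                if decision == "unevaluable":
                    pairs.append(
                        FragmentPair(cluster_id, a.id, b.id, None, po, None,
                                     decision, round_no)
                    )
                    continue
                n_term, _ = order_fragments(msa, a.id, b.id)
                pairs.append(
                    FragmentPair(cluster_id, a.id, b.id, rb, po, n_term,
                                 decision, round_no)
                )
    return pairs


def fuse_sequences(parts: Sequence[GeneCall]) -> GeneCall:
    """Splice fragments N-terminal-first with one X spacer per junction."""
    if len(parts) < 2:
        raise InputError("a fusion needs at least two fragments")
    genomes = {c.genome_id for c in parts}
    if len(genomes) != 1:
        raise InputError(f"cannot fuse calls from different genomes: {sorted(genomes)}")
    provenance: List[str] = []
    for c in parts:
        provenance.extend(c.provenance if c.is_fused else [c.id])
    return GeneCall(
        id="+".join(c.id for c in parts),
        genome_id=parts[0].genome_id,
        start=min(c.start for c in parts),
        stop=max(c.stop for c in parts),
        strand=parts[0].strand,
        aa_seq="X".join(c.aa_seq for c in parts),
        provenance=provenance,
    )


def apply_fusions(
    state: PangenomeState,
    fragment_pairs: Iterable[FragmentPair],
    cluster_map: Optional[Dict[str, str]] = None,
) -> List[str]:
    """Apply accepted fusions; returns the clusters needing re-alignment.

    Accepted pairs within one cluster and genome are grouped into chains via
    connected components, then fused in N-to-C alignment order. A call
    accepted into pairs that resolve to different clusters is a hard error
    (it cannot fuse twice). ``cluster_map`` translates the pair's recorded
    cluster id when clusters were merged after evaluation.
    """
    accepted = [p for p in fragment_pairs if p.decision == "fused"]
    if not accepted:
        return []
    graph = nx.Graph()
    home: Dict[str, str] = {}
    evaluated_in: Dict[str, str] = {}
    n_term_of: Dict[frozenset, Optional[str]] = {}
    for p in accepted:
        cid = cluster_map.get(p.cluster_id, p.cluster_id) if cluster_map else p.cluster_id
        for g in (p.call_a, p.call_b):
            if home.setdefault(g, cid) != cid:
                raise StageError(
                    "fuse",
                    f"gene call {g!r} accepted for fusion in two clusters "
                    f"({home[g]!r}, {cid!r})",
                    [home[g], cid],
                )
            evaluated_in[g] = p.cluster_id
        graph.add_edge(p.call_a, p.call_b)
        n_term_of[frozenset((p.call_a, p.call_b))] = p.n_term

    affected: Set[str] = set()
    for comp in sorted(nx.connected_components(graph), key=min):
        cid = home[min(comp)]
        if cid not in state.clusters:
            raise InputError(f"fusion targets unknown cluster {cid!r}")
        # order N-to-C using the MSA the pairs were evaluated in (it is kept
        # around even after cluster merging); a two-fragment pair can fall
        # back to its recorded n_term
        msa = state.msas.get(evaluated_in[min(comp)])
        members = sorted(comp)
        if msa is not None and all(
            any(r == g for r, _ in msa.rows) for g in members
        ):
            def med(g: str):
                cols = sorted(msa.occupied_columns(g))
                return (float(np.median(cols)), cols[0], g)
            members = sorted(comp, key=med)
        elif len(members) == 2:
            n_term = n_term_of.get(frozenset(members))
            if n_term in members:
                members = [n_term] + [g for g in members if g != n_term]
        parts = [state.calls[g] for g in members]
        fused = fuse_sequences(parts)
        if fused.id in state.calls:
            raise StageError("fuse", f"duplicate fused id {fused.id!r}", [cid])
        state.calls[fused.id] = fused
        for g in comp:
            state.clusters[cid].discard(g)
        state.clusters[cid].add(fused.id)
        genome = state.genomes.get(fused.genome_id)
        if genome is not None:
            genome.gene_call_ids = [g for g in genome.gene_call_ids if g not in comp]
            genome.gene_call_ids.append(fused.id)
            genome.gene_call_ids.sort(key=lambda g: (state.calls[g].start, g))
        affected.add(cid)
    state.stale |= affected
    return sorted(affected)
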