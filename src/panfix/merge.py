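"""Merge gene clusters that contain distant homologs.

Each cluster's MSA becomes a position-specific log-odds profile; every gene
call is scored against every profile by local alignment. A cluster's
"selfbit" — the minimum profile bit score among its own original members —
acts as a per-cluster significance threshold: an outside call scoring at
least the weakest original member links its cluster to the profile's
cluster. Connected components of the resulting cluster graph define the
merged clusters.

Profiles are deliberately not full HMMs: the discriminative machinery here
is the selfbit threshold, not transition-probability estimation. A plug-in
seam accepts external per-sequence bit scores (HMMER ``--tblout`` format)
for users wanting exact HMMER semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from . import _dp
from .model import AA_ORDER, GAP, GeneCall, InputError, Msa
from .scoring import BLOSUM62_BACKGROUND

#: residue codes: 0..19 standard residues, 20 = X (scores 0), 21 = padding
_X_CODE = 20
_PAD_CODE = 21
_CODE = {a: i for i, a in enumerate(AA_ORDER)}
_CODE["X"] = _X_CODE

#: affine gap penalties for sequence-vs-profile alignment, in bits
PROFILE_GAP_OPEN = 10.0
PROFILE_GAP_EXTEND = 1.0


@dataclass
class ProfileModel:
    """Position-specific log-odds model (bits) for one cluster."""

    cluster_id: str
    match_columns: List[int]
    emissions: np.ndarray  # (n_match_columns, 22) bits; X=0, padding very negative
    background: np.ndarray
    selfbit: Optional[float] = None


@dataclass(frozen=True)
class HitEdge:
    """A gene call scoring above a foreign cluster's selfbit threshold."""

    gene_call_id: str
    target_cluster_id: str
    bit_score: float


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int64, count=len(seq))


def build_profile(
    msa: Msa,
    pseudocount: float = 0.1,
    background: Optional[np.ndarray] = None,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a profile from a cluster MSA.

    Match columns are those with at most ``max_gap_fraction`` gaps. Emission
    probabilities are residue counts with a Laplace-style pseudocount of
    ``pseudocount`` per residue, normalised, then converted to log-odds in
    bits against the background frequencies. X never contributes counts and
    scores 0 at every column.
    """
    bg = BLOSUM62_BACKGROUND if background is None else background
    n_rows = len(msa.rows)
    if n_rows == 0:
        raise InputError(f"cluster {msa.cluster_id!r}: empty MSA")
    counts = np.zeros((msa.width, 20))
    gaps = np.zeros(msa.width)
    for _, row in msa.rows:
        for j, c in enumerate(row):
            if c == GAP:
                gaps[j] += 1.0
            elif c != "X":
                counts[j, _CODE[c]] += 1.0
    match_cols = [j for j in range(msa.width) if gaps[j] / n_rows <= max_gap_fraction]
    if not match_cols:
        raise InputError(f"cluster {msa.cluster_id!r}: MSA has zero match columns")
    sub = counts[match_cols] + pseudocount
    probs = sub / sub.sum(axis=1, keepdims=True)
    logodds = np.log2(probs / bg)
    emissions = np.full((len(match_cols), 22), 0.0)
    emissions[:, :20] = logodds
    emissions[:, _X_CODE] = 0.0
    emissions[:, _PAD_CODE] = _dp.NEG
    return ProfileModel(msa.cluster_id, match_cols, emissions, bg)


def score_profile_batch(
    seqs: Sequence[str],
    profile: ProfileModel,
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> np.ndarray:
    """Best local sequence-vs-profile alignment score (bits) per sequence."""
    if not seqs:
        return np.zeros(0)
    if any(not s for s in seqs):
        raise InputError("cannot score an empty sequence against a profile")
    n = max(len(s) for s in seqs)
    codes = np.full((len(seqs), n), _PAD_CODE, dtype=np.int64)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = encode(s)
    return _dp.local_profile_scores(codes, profile.emissions, gap_open, gap_extend)


def score_profile(call: GeneCall, profile: ProfileModel, **kw) -> float:
    """Score one gene call against one profile (bits)."""
    return float(score_profile_batch([call.aa_seq], profile, **kw)[0])


def compute_selfbit(
    profile: ProfileModel, member_calls: Sequence[GeneCall], **kw
) -> ProfileModel:
    """Attach the selfbit threshold: the minimum score among original members."""
    if not member_calls:
        raise InputError(
            f"cluster {profile.cluster_id!r}: selfbit needs at least one member"
        )
    scores = score_profile_batch([c.aa_seq for c in member_calls], profile, **kw)
    profile.selfbit = float(scores.min())
    return profile


def build_hit_edgelist(
    all_calls: Sequence[GeneCall],
    profiles: Sequence[ProfileModel],
    assignment: Dict[str, str],
    abs_min_bit: Optional[float] = None,
    strict_selfbit: bool = False,
    batch_size: int = 128,
) -> List[HitEdge]:
    """Score every call against every foreign profile; keep significant hits.

    A hit qualifies when its score passes the profile's selfbit (>= by
    default; > with ``strict_selfbit``) and the optional absolute floor.
    Self-hits (a call against its own cluster's profile) never create edges.
    """
    calls = sorted(all_calls, key=lambda c: c.id)
    # batch by length so padding waste stays bounded
    order = sorted(range(len(calls)), key=lambda i: len(calls[i].aa_seq))
    edges: List[HitEdge] = []
    for profile in sorted(profiles, key=lambda p: p.cluster_id):
        if profile.selfbit is None:
            raise InputError(
                f"cluster {profile.cluster_id!r}: selfbit not computed"
            )
        for lo in range(0, len(order), batch_size):
            idx = order[lo: lo + batch_size]
            scores = score_profile_batch([calls[i].aa_seq for i in idx], profile)
            for i, sc in zip(idx, scores):
                call = calls[i]
                if assignment[call.id] == profile.cluster_id:
                    continue
                passes = sc > profile.selfbit if strict_selfbit else sc >= profile.selfbit
                if passes and (abs_min_bit is None or sc >= abs_min_bit):
                    edges.append(HitEdge(call.id, profile.cluster_id, float(sc)))
    edges.sort(key=lambda e: (e.gene_call_id, e.target_cluster_id))
    return edges


def read_hmmer_tblout(path: str) -> Dict[Tuple[str, str], float]:
    """Plug-in seam: parse HMMER ``--tblout`` per-sequence hits.

    Returns (sequence id, profile/query name) -> full-sequence bit score.
    """
    out: Dict[Tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                raise InputError(f"malformed tblout line: {line!r}")
            target, query, bits = parts[0], parts[2], float(parts[5])
            key = (target, query)
            out[key] = max(out.get(key, -math.inf), bits)
    return out


def merge_components(
    cluster_ids: Iterable[str],
    edges: Iterable[HitEdge],
    assignment: Dict[str, str],
) -> Dict[str, str]:
    """Connected components over cluster–cluster homology edges.

    Gene-to-cluster hit edges are relabelled as (call's original cluster,
    target cluster) edges; isolated clusters stay their own component. The
    merged id is the lexicographically smallest constituent cluster id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(cluster_ids)
    for e in edges:
        src = assignment.get(e.gene_call_id)
        if src is None:
            raise InputError(f"edge references unknown gene call {e.gene_call_id!r}")
        if e.target_cluster_id not in graph:
            raise InputError(f"edge references unknown cluster {e.target_cluster_id!r}")
        if src != e.target_cluster_id:
            graph.add_edge(src, e.target_cluster_id)
    partition: Dict[str, str] = {}
    for comp in nx.connected_components(graph):
        new_id = min(comp)
        for cid in comp:
            partition[cid] = new_id
    return partition
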