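"""Per-cluster multiple sequence alignment.

The default backend is an internal progressive aligner: pairwise
similarity-ratio distances from local alignment scores, an average-linkage
(UPGMA) guide tree, and profile–profile merges with affine gaps.
Average linkage matters when a cluster contains gene fragments: each
fragment attaches to the full-length profile (which carries its context)
instead of pairing with its sibling fragment, with which it shares no
sequence. The "X" residue scores 0 against everything and is excluded from
profile frequencies, so the spacer inserted at fusion junctions neither
attracts nor repels the alignment.

A plug-in seam can shell out to any external aligner with a
FASTA-in / aligned-FASTA-out contract (MUSCLE- or MAFFT-compatible) when
configured via ``backend="external"`` and ``external_cmd``.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import _dp
from .model import AA_ORDER, GAP, GeneCall, InputError, Msa, PangenomeState, StageError
from .scoring import ScoringParams, local_align_raw

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def _freq_matrix(rows: Sequence[str]) -> np.ndarray:
    """Per-column residue frequencies (20 standard residues).

    Gaps and X contribute no mass, so gappy or unknown-rich columns carry
    proportionally less substitution score.
    """
    width = len(rows[0])
    freq = np.zeros((width, 20))
    for row in rows:
        for j, c in enumerate(row):
            k = _AA_INDEX.get(c)
            if k is not None:
                freq[j, k] += 1.0
    return freq / len(rows)


def _matrix20(params: ScoringParams) -> np.ndarray:
    mat = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = params.matrix[a, b]
    return mat


def _merge(rows1: List[Tuple[str, str]], rows2: List[Tuple[str, str]],
           s20: np.ndarray, params: ScoringParams) -> List[Tuple[str, str]]:
    f1 = _freq_matrix([s for _, s in rows1])
    f2 = _freq_matrix([s for _, s in rows2])
    colscore = f1 @ s20 @ f2.T
    ops = _dp.global_profile_align(colscore, params.gap_open, params.gap_extend)
    new1, new2 = _dp.merge_profiles_by_ops(
        [s for _, s in rows1], [s for _, s in rows2], ops
    )
    return [(i, s) for (i, _), s in zip(rows1, new1)] + [
        (i, s) for (i, _), s in zip(rows2, new2)
    ]


def _guide_order(ids: List[str], seqs: Dict[str, str], params: ScoringParams):
    """Average-linkage (UPGMA) guide tree on similarity-ratio distances.

    The distance is 1 - raw(a,b) / min(raw(a,a), raw(b,b)), clipped to
    [0, 1] — a score-only quantity, so guide-tree construction needs no
    tracebacks. Returns a nested merge plan (binary tuples of ids); ids are
    pre-sorted so the result is independent of input order.
    """
    n = len(ids)
    selfscore = {i: local_align_raw(seqs[i], seqs[i], params) for i in ids}
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = local_align_raw(seqs[ids[i]], seqs[ids[j]], params)
            sim = raw / min(selfscore[ids[i]], selfscore[ids[j]])
            dm[i, j] = dm[j, i] = min(1.0, max(0.0, 1.0 - sim))
    tree = linkage(squareform(dm, checks=False), method="average")
    plans: List = list(ids)
    for a, b, _, _ in tree:
        pa, pb = plans[int(a)], plans[int(b)]
        plans.append((pa, pb) if _min_leaf(pa) <= _min_leaf(pb) else (pb, pa))
    return plans[-1]


def _min_leaf(p) -> str:
    while isinstance(p, tuple):
        p = _min_leaf(p[0])
    return p


def align_cluster(
    calls: Iterable[GeneCall],
    params: Optional[ScoringParams] = None,
    cluster_id: str = "cluster",
    backend: str = "internal",
    external_cmd: Optional[Sequence[str]] = None,
) -> Msa:
    """Align one cluster's sequences; single sequences pass through gap-free."""
    params = params or ScoringParams()
    items = sorted(((c.id, c.aa_seq) for c in calls), key=lambda t: t[0])
    if not items:
        raise InputError(f"cluster {cluster_id!r}: cannot align an empty cluster")
    if backend == "external":
        return _align_external(items, cluster_id, external_cmd)
    if backend != "internal":
        raise InputError(f"unknown aligner backend {backend!r}")
    if len(items) == 1:
        return Msa(cluster_id, list(items))
    seqs = dict(items)
    ids = [i for i, _ in items]
    s20 = _matrix20(params)
    if len(items) == 2:
        plan = (ids[0], ids[1])
    else:
        plan = _guide_order(ids, seqs, params)

    def build(p) -> List[Tuple[str, str]]:
        if isinstance(p, str):
            return [(p, seqs[p])]
        return _merge(build(p[0]), build(p[1]), s20, params)

    rows = sorted(build(plan), key=lambda t: t[0])
    msa = Msa(cluster_id, rows)
    for cid, row in msa.rows:
        if row.replace(GAP, "") != seqs[cid]:
            raise StageError(
                "align", f"row {cid!r} does not ungap to its input", [cluster_id]
            )
    return msa


def _align_external(
    items: List[Tuple[str, str]], cluster_id: str, cmd: Optional[Sequence[str]]
) -> Msa:
    """FASTA-in/aligned-FASTA-out external aligner (e.g. mafft, muscle)."""
    if not cmd:
        cmd = ["mafft", "--quiet", "--anysymbol"]
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        fin.write_text("".join(f">{i}\n{s}\n" for i, s in items))
        proc = subprocess.run(
            [*cmd, str(fin)], capture_output=True, text=True, check=False
        )
        if proc.returncode != 0:
            raise StageError("align", f"external aligner failed: {proc.stderr}",
                             [cluster_id])
        rows: List[Tuple[str, str]] = []
        name, buf = None, []
        for line in proc.stdout.splitlines() + [">"]:
            if line.startswith(">"):
                if name is not None:
                    rows.append((name, "".join(buf).upper()))
                name, buf = line[1:].split()[0] if len(line) > 1 else None, []
            else:
                buf.append(line.strip())
        return Msa(cluster_id, sorted(rows, key=lambda t: t[0]))


def realign_affected(
    state: PangenomeState,
    cluster_ids: Iterable[str],
    params: Optional[ScoringParams] = None,
    backend: str = "internal",
    external_cmd: Optional[Sequence[str]] = None,
) -> None:
    """Rebuild MSAs for exactly the listed clusters; others are untouched."""
    params = params or ScoringParams()
    for cid in sorted(set(cluster_ids)):
        if cid not in state.clusters:
            raise InputError(f"cannot realign unknown cluster {cid!r}")
        members = [state.calls[g] for g in state.clusters[cid]]
        state.msas[cid] = align_cluster(
            members, params, cid, backend=backend, external_cmd=external_cmd
        )
        state.stale.discard(cid)
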