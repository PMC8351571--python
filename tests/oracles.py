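"""Independent brute-force oracles, kept deliberately naive.

Nothing here shares code with the package's optimised implementations: the
Smith–Waterman oracle is a plain cubic-memory Gotoh table, the partition
oracle is a hand-written union-find, and the statistic oracles re-derive
their formulas by direct summation and column counting.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Tuple


def sw_raw(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Smith–Waterman raw score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = matrix[a[i - 1], b[j - 1]] + max(
                0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]
            )
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def bits_from_raw(raw: float, lam: float, k: float) -> float:
    if raw <= 0:
        return 0.0
    return (lam * raw - math.log(k)) / math.log(2)


def relbit_oracle(
    a: str, b: str, others: Sequence[str], matrix, gap_open, gap_extend, lam, k
):
    """Eq-style relative bit by direct summation over the other members."""
    if not others:
        return None

    def bit(x, y):
        return bits_from_raw(sw_raw(x, y, matrix, gap_open, gap_extend), lam, k)

    pair = bit(a, b)
    mean_a = sum(bit(a, c) for c in others) / len(others)
    mean_b = sum(bit(b, c) for c in others) / len(others)
    vals = [pair / m for m in (mean_a, mean_b) if m > 0]
    return max(vals) if vals else None


def percent_overlap_oracle(row_a: str, row_b: str) -> float:
    """Column-by-column intersection / union count of non-gap positions."""
    inter = union = 0
    for x, y in zip(row_a, row_b):
        occ_a, occ_b = x != "-", y != "-"
        if occ_a and occ_b:
            inter += 1
        if occ_a or occ_b:
            union += 1
    return inter / union if union else 0.0


class UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def partition_oracle(
    cluster_ids: Sequence[str], cluster_edges: Sequence[Tuple[str, str]]
) -> Dict[str, str]:
    """Union-find partition with smallest-member representative ids."""
    uf = UnionFind(cluster_ids)
    for a, b in cluster_edges:
        uf.union(a, b)
    groups: Dict[str, List[str]] = {}
    for c in cluster_ids:
        groups.setdefault(uf.find(c), []).append(c)
    out = {}
    for members in groups.values():
        rep = min(members)
        for c in members:
            out[c] = rep
    return out


def emissions_oracle(rows: Sequence[str], pseudocount: float, bg, aa_order: str):
    """Count-and-normalise per-column emission probabilities (gaps/X skipped)."""
    width = len(rows[0])
    out = []
    for j in range(width):
        counts = {a: pseudocount for a in aa_order}
        gaps = 0
        for r in rows:
            c = r[j]
            if c == "-":
                gaps += 1
            elif c in counts:
                counts[c] += 1
        total = sum(counts.values())
        probs = [counts[a] / total for a in aa_order]
        logodds = [math.log2(p / q) for p, q in zip(probs, bg)]
        out.append((gaps / len(rows), logodds))
    return out
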