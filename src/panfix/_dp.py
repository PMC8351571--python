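"""Vectorised affine-gap dynamic programming.

Two kernels share the same column-sweep structure, with the in-column
vertical-gap recurrence resolved by a running-max scan:

* a local (Smith–Waterman-style) scorer for batches of sequences against a
  position-specific profile, and
* a global profile–profile aligner with traceback, used by the progressive
  multiple aligner.

Gap convention everywhere: a gap of length k costs ``open + k * extend``.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

NEG = -1.0e30


def local_profile_scores(
    codes: np.ndarray,
    emissions: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> np.ndarray:
    """Best local alignment score of each encoded sequence against a profile.

    Parameters
    ----------
    codes : int array (n_seqs, max_len)
        Residue codes per sequence; positions past a sequence's end hold the
        padding code (last row of ``emissions``).
    emissions : float array (n_columns, n_codes)
        Per-profile-column scores for every residue code; the padding code's
        column must be strongly negative.
    """
    n_seqs, n = codes.shape
    dt = np.float32
    go1 = dt(gap_open + gap_extend)  # first gap residue
    ge = dt(gap_extend)
    idx = (np.arange(n + 1) * gap_extend).astype(dt)
    emis = emissions.astype(dt, copy=False)

    m_prev = np.full((n_seqs, n + 1), NEG, dtype=dt)
    ix_prev = np.full((n_seqs, n + 1), NEG, dtype=dt)
    iy_prev = np.full((n_seqs, n + 1), NEG, dtype=dt)
    m_j = np.empty_like(m_prev)
    ix_j = np.empty_like(m_prev)
    iy_j = np.empty_like(m_prev)
    diag = np.empty((n_seqs, n), dtype=dt)
    acc = np.empty_like(m_prev)
    best = np.zeros(n_seqs, dtype=dt)

    for j in range(emis.shape[0]):
        e_col = emis[j][codes]  # (n_seqs, n)
        np.maximum(m_prev[:, :-1], ix_prev[:, :-1], out=diag)
        np.maximum(diag, iy_prev[:, :-1], out=diag)
        np.maximum(diag, 0.0, out=diag)
        diag += e_col
        m_j[:, 0] = NEG
        m_j[:, 1:] = diag
        np.subtract(m_prev, go1, out=iy_j)
        iy_prev -= ge
        np.maximum(iy_j, iy_prev, out=iy_j)
        # vertical gaps within this column: running-max scan over rows
        np.add(m_j, idx, out=acc)
        np.maximum.accumulate(acc, axis=1, out=acc)
        ix_j[:, 0] = NEG
        np.subtract(acc[:, :-1], go1 + idx[:-1], out=ix_j[:, 1:])
        np.maximum(best, m_j.max(axis=1), out=best)
        m_prev, m_j = m_j, m_prev
        ix_prev, ix_j = ix_j, ix_prev
        iy_prev, iy_j = iy_j, iy_prev
    return np.maximum(best, 0.0).astype(np.float64)


def global_profile_align(
    colscore: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> List[str]:
    """Global affine-gap alignment of two profiles.

    ``colscore[i, j]`` is the score of pairing column i of profile 1 with
    column j of profile 2. Returns the edit path as a list of operations,
    'M' (pair columns), 'D' (profile-1 column vs gap), 'I' (gap vs
    profile-2 column), in order. Tie-breaking prefers M, then D, then I.
    """
    n, m = colscore.shape
    go1 = gap_open + gap_extend
    ge = gap_extend
    idx = np.arange(n + 1, dtype=np.float64) * ge

    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)  # vertical: consumes profile-1 columns
    I = np.full((n + 1, m + 1), NEG)  # horizontal: consumes profile-2 columns
    M[0, 0] = 0.0
    D[1:, 0] = -(go1 + np.arange(n) * ge)
    I[0, 1:] = -(go1 + np.arange(m) * ge)

    for j in range(1, m + 1):
        diag = np.maximum(M[:-1, j - 1], np.maximum(D[:-1, j - 1], I[:-1, j - 1]))
        M[1:, j] = colscore[:, j - 1] + diag
        I[:, j] = np.maximum(M[:, j - 1] - go1, I[:, j - 1] - ge)
        acc = np.maximum.accumulate(M[:, j] + idx)
        D[1:, j] = acc[:-1] - go1 - idx[:-1]

    ops: List[str] = []
    i, jj = n, m
    state = int(np.argmax([M[i, jj], D[i, jj], I[i, jj]]))
    tol = 1e-9
    while i > 0 or jj > 0:
        if state == 0:  # M
            ops.append("M")
            prev = np.array([M[i - 1, jj - 1], D[i - 1, jj - 1], I[i - 1, jj - 1]])
            i -= 1
            jj -= 1
            state = int(np.argmax(prev))
        elif state == 1:  # D
            ops.append("D")
            if jj > 0 and abs(D[i, jj] - (M[i - 1, jj] - go1)) <= tol:
                state = 0
            i -= 1
        else:  # I
            ops.append("I")
            if i > 0 and abs(I[i, jj] - (M[i, jj - 1] - go1)) <= tol:
                state = 0
            jj -= 1
        if i == 0 and jj == 0:
            break
        if i == 0 and state == 1:
            state = 2 if jj > 0 else 0
        if jj == 0 and state == 2:
            state = 1 if i > 0 else 0
    ops.reverse()
    return ops


def merge_profiles_by_ops(
    rows1: List[str], rows2: List[str], ops: List[str]
) -> Tuple[List[str], List[str]]:
    """Apply an edit path to two row sets, inserting gaps where required."""
    out1: List[List[str]] = [[] for _ in rows1]
    out2: List[List[str]] = [[] for _ in rows2]
    p1 = p2 = 0
    for op in ops:
        if op in ("M", "D"):
            for k, r in enumerate(rows1):
                out1[k].append(r[p1])
            p1 += 1
        else:
            for k in range(len(rows1)):
                out1[k].append("-")
        if op in ("M", "I"):
            for k, r in enumerate(rows2):
                out2[k].append(r[p2])
            p2 += 1
        else:
            for k in range(len(rows2)):
                out2[k].append("-")
    return ["".join(r) for r in out1], ["".join(r) for r in out2]
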