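"""Independent reference implementations used only as test oracles.

Each oracle is written in the most transparent form available (naive
loops, direct formula), deliberately sharing no code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def naive_gotoh(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Plain triple-matrix affine-gap global alignment, python loops only.

    Same conventions as the package aligner: a length-L gap costs
    open + L*extend; gap states open from the match state only; traceback
    prefers diagonal, then vertical, then horizontal on ties.
    Returns (score, matches, columns).
    """
    NEG = -1e9
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    V = [[NEG] * (m + 1) for _ in range(n + 1)]
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        H[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        V[i][0] = -(gap_open + gap_extend * i)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], V[i - 1][j - 1], H[i - 1][j - 1])
            V[i][j] = max(M[i - 1][j] - first, V[i - 1][j] - gap_extend)
            H[i][j] = max(M[i][j - 1] - first, H[i][j - 1] - gap_extend)
    finals = (M[n][m], V[n][m], H[n][m])
    score = max(finals)
    state = finals.index(score)  # prefers M, then V, then H
    i, j = n, m
    matches = 0
    cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
            if i or j:
                cell = (M[i][j], V[i][j], H[i][j])
                state = cell.index(max(cell))
        elif state == 1:
            state = 0 if M[i - 1][j] - first >= V[i - 1][j] - gap_extend else 1
            i -= 1
        else:
            state = 0 if M[i][j - 1] - first >= H[i][j - 1] - gap_extend else 2
            j -= 1
    return score, matches, cols


def exhaustive_motif_scan(seq: str, pattern, discriminant, max_mismatch, hydrophobic):
    """Position-by-position motif evaluation; returns [(start, mismatches)]."""
    out = []
    m = len(pattern)
    for start in range(1, len(seq) - m + 2):
        mism = 0
        ok = True
        for k, tok in enumerate(pattern):
            res = seq[start - 1 + k]
            if res == "X":
                good = False
            elif tok == "x":
                good = True
            elif tok == "h":
                good = res in hydrophobic
            else:
                good = res == tok
            if good:
                continue
            if (k + 1) in discriminant:
                ok = False
                break
            mism += 1
        if ok and mism <= max_mismatch:
            out.append((start, mism))
    return sorted(out, key=lambda t: (t[1], t[0]))


def stepup_bh(pvalues):
    """Direct Benjamini-Hochberg step-up from the definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.array(adj)


def pearson_chi2(table: np.ndarray) -> float:
    """Chi-square of independence computed directly from the definition."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())
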