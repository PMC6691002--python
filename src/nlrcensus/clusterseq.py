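"""Pairwise global-alignment identity and greedy incremental clustering.

A deterministic stand-in for CD-HIT at desk scale: full Needleman-Wunsch
(Gotoh affine-gap) alignment of every record against cluster
representatives, with identity defined as identical aligned residue pairs
divided by the length of the shorter sequence (CD-HIT's global-identity
convention).  Scoring is BLOSUM62 with gap open 11 / extend 1 (a gap of
length L costs 11 + L).

The forward pass is vectorized over alignment-matrix rows; the horizontal
affine state is resolved with a running-maximum (cumulative max) identity
so each row costs O(m) numpy work.  Traceback tie-breaks are fixed:
diagonal, then vertical gap, then horizontal gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

NEG = -1e9


@dataclass(frozen=True)
class AlignScoring:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0   # gap existence cost
    gap_extend: float = 1.0  # per-residue cost; length-L gap costs open + L*extend


DEFAULT_SCORING = AlignScoring()


@lru_cache(maxsize=4)
def _submat(name: str) -> tuple[dict[str, int], np.ndarray]:
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    return index, np.asarray(mat, dtype=float)


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.fromiter((index[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:  # pragma: no cover - ProteinRecord already validates
        raise ValueError(f"residue {exc} not in substitution matrix") from exc


@dataclass(frozen=True)
class PairwiseIdentity:
    id_a: str
    id_b: str
    identity: float
    aligned_length: int
    matches: int
    score: float


def _forward(a: np.ndarray, b: np.ndarray, S: np.ndarray, go: float, ge: float):
    """Gotoh forward pass; returns the three (n+1)x(m+1) state matrices.

    M[i,j]: best score ending in a residue pair a_i:b_j.
    V[i,j]: best score ending in a gap in b (vertical move).
    H[i,j]: best score ending in a gap in a (horizontal move).
    """
    n, m = len(a), len(b)
    first = go + ge  # cost of the first residue of a gap
    M = np.full((n + 1, m + 1), NEG)
    V = np.full((n + 1, m + 1), NEG)
    H = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    H[0, 1:] = -(go + ge * j)
    i = np.arange(1, n + 1)
    V[1:, 0] = -(go + ge * i)
    sub = S[np.ix_(a, b)]  # n x m substitution scores
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], V[i - 1]), H[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        V[i, 1:] = np.maximum(M[i - 1, 1:] - first, V[i - 1, 1:] - ge)
        # H[i,j] = max(M[i,j-1]-first, H[i,j-1]-ge): running max via cummax of
        # candidate openings M[i,k] + k*ge, then shifting by -(go + j*ge).
        cand = np.maximum(M[i, :-1], H[i, 0:1] + go + ge)  # include H[i,0] seed
        opens = np.maximum.accumulate(cand + ge * np.arange(m))
        H[i, 1:] = opens - go - ge * np.arange(1, m + 1)
    return M, V, H


def _traceback(a, b, M, V, H, go, ge):
    """Count identical aligned pairs; tie-break diagonal > vertical > horizontal."""
    first = go + ge
    i, j = len(a), len(b)
    state = int(np.argmax([M[i, j], V[i, j], H[i, j]]))  # 0=M,1=V,2=H
    matches = 0
    cols = 0
    eps = 1e-6
    while i > 0 or j > 0:
        cols += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
            scores = (M[i, j], V[i, j], H[i, j])
            state = int(np.argmax(scores)) if (i or j) else 0
            # deterministic preference on ties: M, then V, then H
            best = max(scores)
            for s, val in enumerate(scores):
                if val >= best - eps:
                    state = s
                    break
        elif state == 1:  # vertical: consumes a_i
            came_open = M[i - 1, j] - first
            came_ext = V[i - 1, j] - ge
            state = 0 if came_open >= came_ext - eps else 1
            i -= 1
        else:  # horizontal: consumes b_j
            came_open = M[i, j - 1] - first
            came_ext = H[i, j - 1] - ge
            state = 0 if came_open >= came_ext - eps else 2
            j -= 1
    return matches, cols


def global_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> PairwiseIdentity:
    """Global (NW/Gotoh) alignment identity between two peptides.

    identity = identical aligned residue pairs / min(len(a), len(b)).
    """
    index, S = _submat(scoring.matrix)
    ea, eb = _encode(a.seq, index), _encode(b.seq, index)
    M, V, H = _forward(ea, eb, S, scoring.gap_open, scoring.gap_extend)
    n, m = len(ea), len(eb)
    score = float(max(M[n, m], V[n, m], H[n, m]))
    matches, cols = _traceback(ea, eb, M, V, H, scoring.gap_open, scoring.gap_extend)
    identity = matches / min(a.length, b.length)
    return PairwiseIdentity(
        id_a=a.id, id_b=b.id, identity=identity,
        aligned_length=cols, matches=matches, score=score,
    )


@dataclass
class Cluster:
    representative: str
    members: list[str]
    cutoff: float
    identities: dict[str, float]  # member -> identity to representative

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its cluster")


def greedy_cluster(
    records: Sequence[ProteinRecord],
    cutoff: float,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity cutoff in (0, 1].

    Records are processed longest-first (ties by id ascending); each record
    joins the first existing representative with identity >= cutoff, else
    founds a new cluster.  Representatives are therefore always the longest
    member.  Output clusters are ordered by representative length
    descending (the founding order).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1]")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            ident = global_identity(rec, rep, scoring).identity
            if ident >= cutoff:
                cluster.members.append(rec.id)
                cluster.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=rec.id, members=[rec.id],
                        cutoff=cutoff, identities={rec.id: 1.0})
            )
            reps.append(rec)
    return clusters


def clusters_to_rows(clusters: Sequence[Cluster]) -> list[dict]:
    """Flatten clusters for the cluster TSV report."""
    rows = []
    for c in clusters:
        for member in c.members:
            rows.append(
                {
                    "representative": c.representative,
                    "member": member,
                    "identity_to_representative": round(c.identities[member], 6),
                    "cutoff": c.cutoff,
                }
            )
    return rows
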