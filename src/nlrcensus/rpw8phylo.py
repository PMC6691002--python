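"""RPW8-domain extraction, distances, neighbor joining and group assignment.

The RNL subfamily is delimited by its N-terminal RPW8 domain.  Full-length
RPW8 domains (strictly more than 100 residues) are extracted from annotated
hits, pairwise distances are taken as 1 - global identity (clusterseq
scoring), and an unrooted Saitou-Nei neighbor-joining tree places each
query relative to labelled anchor sequences: ADR1 (group 2), NRG1 with
RPW8.1/RPW8.2 (group 4) and packaged conifer exemplars for the two
Gymnosperm-specific groups (1 and 3).  Neighbor joining substitutes for
maximum-likelihood tree search here; the downstream quantity is the
nearest-anchor group, which is robust to that substitution, and the
substitution is recorded in output metadata.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import clusterseq
from .seqio import DomainHit, ProteinRecord, read_fasta

log = logging.getLogger(__name__)

MIN_RPW8_LENGTH = 100  # domains must be strictly longer than this

#: Anchor label -> RNL group for the packaged fixture.
DEFAULT_ANCHOR_GROUPS = {
    "CONIFER_G1_A": 1,
    "CONIFER_G1_B": 1,
    "ADR1": 2,
    "CONIFER_G3_A": 3,
    "CONIFER_G3_B": 3,
    "NRG1": 4,
    "RPW8_1": 4,
    "RPW8_2": 4,
}

GROUP_LABELS = {1: "1", 2: "2 (ADR1-like)", 3: "3", 4: "4 (NRG1-like)"}


@dataclass(frozen=True)
class Rpw8Domain:
    seq_id: str
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_record(self) -> ProteinRecord:
        return ProteinRecord(id=self.seq_id, seq=self.seq)


def extract_rpw8(
    records: Sequence[ProteinRecord],
    domain_hits: Iterable[DomainHit],
    min_length: int = MIN_RPW8_LENGTH,
) -> list[Rpw8Domain]:
    """Extract full-length RPW8 domains (> ``min_length`` residues)."""
    by_id = {r.id: r for r in records}
    out: list[Rpw8Domain] = []
    dropped = 0
    for hit in domain_hits:
        if hit.domain != "RPW8" or hit.seq_id not in by_id:
            continue
        if hit.span <= min_length:
            dropped += 1
            continue
        rec = by_id[hit.seq_id]
        out.append(Rpw8Domain(seq_id=rec.id, start=hit.start, end=hit.end,
                              seq=rec.subseq(hit.start, hit.end)))
    if dropped:
        log.info("extract_rpw8: dropped %d sub-threshold RPW8 hits (<= %d aa)",
                 dropped, min_length)
    return out


def pairwise_distances(
    domains: Sequence[Rpw8Domain | ProteinRecord],
    scoring: clusterseq.AlignScoring = clusterseq.DEFAULT_SCORING,
) -> DistanceMatrix:
    """Distance matrix with d = 1 - global identity."""
    records = [d.as_record() if isinstance(d, Rpw8Domain) else d for d in domains]
    labels = [r.id for r in records]
    n = len(records)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = clusterseq.global_identity(records[i], records[j], scoring).identity
            d = 1.0 - min(ident, 1.0)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on a distance matrix (>= 3 labels).

    Ties in the Q-matrix minimization are broken by the smallest (i, j)
    index pair in current matrix order, so the result is deterministic.
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch, preserving the pair's patristic sum.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = D.sum(axis=1)
        # Q[i,j] = (n-2) d_ij - r_i - r_j
        Q = (n - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair on ties: argmin of flattened row-major scan
        flat = np.argmin(Q)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (row_sums[i] - row_sums[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        # distances from the new node to the others
        keep = [k for k in range(n) if k not in (i, j)]
        new_d = 0.5 * (D[i, keep] + D[j, keep] - d_ij)
        new_d = np.maximum(new_d, 0.0)
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal 3-star: closed-form branch lengths
    (a, b, c) = nodes
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    root = TreeNode()
    for child, length in ((a, la), (b, lb), (c, lc)):
        child.length = float(max(length, 0.0))
        root.append(child)
    return root


@dataclass(frozen=True)
class GroupAssignment:
    seq_id: str
    group: int | None         # 1..4, or None for unassigned
    nearest_anchor: str | None
    margin: float             # distance margin to the second-best group

    @property
    def group_label(self) -> str:
        return GROUP_LABELS.get(self.group, "unassigned") if self.group else "unassigned"


def load_anchor_fixture() -> tuple[list[ProteinRecord], dict[str, int]]:
    """Packaged anchor RPW8 sequences and their group map.

    The anchors are deterministic synthetic stand-ins for the Angiosperm
    references ADR1, NRG1, RPW8.1 and RPW8.2 plus one exemplar pair for
    each Gymnosperm-specific group (1 and 3); see the fixture FASTA header
    for provenance.
    """
    source = importlib.resources.files("nlrcensus.data") / "anchors_rpw8_synthetic.fasta"
    with importlib.resources.as_file(source) as path:
        records = read_fasta(path)
    return records, dict(DEFAULT_ANCHOR_GROUPS)


def assign_groups(
    domains: Sequence[Rpw8Domain | ProteinRecord],
    anchors: Sequence[ProteinRecord] | None = None,
    anchor_groups: Mapping[str, int] | None = None,
    mode: str = "patristic",
    tie_tolerance: float = 1e-12,
    scoring: clusterseq.AlignScoring = clusterseq.DEFAULT_SCORING,
) -> list[GroupAssignment]:
    """Assign each query RPW8 domain to the RNL group of its nearest anchor.

    ``patristic`` mode builds one NJ tree over queries plus anchors and uses
    path-length distances; ``nearest_reference`` uses raw alignment
    distances.  A query equidistant (within ``tie_tolerance``) from two
    groups is left unassigned.  The margin is the distance gap between the
    best and second-best group.
    """
    if mode not in ("patristic", "nearest_reference"):
        raise ValueError(f"unknown mode {mode!r}")
    if anchors is None:
        anchors, anchor_groups = load_anchor_fixture()
    if anchor_groups is None:
        raise ValueError("anchor_groups required when anchors are supplied")
    present = {anchor_groups[a.id] for a in anchors if a.id in anchor_groups}
    missing = {1, 2, 3, 4} - present
    if missing:
        raise ValueError(f"anchor set missing groups {sorted(missing)}")

    queries = [d.as_record() if isinstance(d, Rpw8Domain) else d for d in domains]
    query_ids = [q.id for q in queries]
    everything = queries + [a for a in anchors]
    dm = pairwise_distances(everything, scoring)

    if mode == "patristic":
        tree = nj_tree(dm)
        dm = tree.tip_tip_distances()

    assignments: list[GroupAssignment] = []
    for qid in query_ids:
        per_group: dict[int, tuple[float, str]] = {}
        for anchor in anchors:
            g = anchor_groups[anchor.id]
            d = float(dm[qid, anchor.id])
            if g not in per_group or d < per_group[g][0]:
                per_group[g] = (d, anchor.id)
        ranked = sorted(per_group.items(), key=lambda kv: (kv[1][0], kv[0]))
        (g1, (d1, a1)), (_, (d2, _)) = ranked[0], ranked[1]
        margin = d2 - d1
        if margin <= tie_tolerance:
            assignments.append(GroupAssignment(qid, None, None, margin))
        else:
            assignments.append(GroupAssignment(qid, g1, a1, margin))
    return assignments
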