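"""Subfamily classification from domain architecture plus NB-ARC signature.

Each peptide is assigned to one of CNL, CNL2, RNL, TNL, ATYPICAL,
UNDETERMINED or EXCLUDED.  The decision procedure, in order:

1. no TIR, no RPW8, no NB-ARC evidence -> EXCLUDED (CC-only and LRR-only
   sequences are not accepted as NLRs);
2. NB-ARC absent: TIR-only / TIR-LRR -> truncated TNL; RPW8-only ->
   truncated RNL; TIR and RPW8 together without NB-ARC -> ATYPICAL;
3. NB-ARC present with a non-canonical extra domain (e.g. a kinase) ->
   ATYPICAL;
4. NB-ARC present: majority vote (at least 2 of 3) over the RNBS-A, RNBS-D
   and MHD signature calls; an N-terminal domain contradicting the vote
   (e.g. TIR over an RNL signature) -> ATYPICAL; no majority -> UNDETERMINED.

CNL is defined negatively (neither TIR nor RPW8 at the N-terminus): the
coiled-coil region is too polymorphic for reliable consensus detection, so
no CC detector exists here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .motifs import NbArcSignature
from .seqio import DomainHit, ProteinRecord

CATEGORIES = ("CNL", "CNL2", "RNL", "TNL", "ATYPICAL", "UNDETERMINED", "EXCLUDED")
RELATED_GROUPS = ("TNL_related", "RNL_related", "non_TIR", "none")


def merge_domain_hits(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Merge overlapping hits of the same domain on the same sequence.

    Repeat domains (LRR) produce tiled hits; architecture calling wants
    their union interval.  The merged hit keeps the best (smallest)
    e-value.
    """
    grouped: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault((h.seq_id, h.domain), []).append(h)
    merged: list[DomainHit] = []
    for (seq_id, domain), group in sorted(grouped.items()):
        group.sort(key=lambda h: (h.start, h.end))
        cur_start, cur_end = group[0].start, group[0].end
        cur_eval, cur_src = group[0].evalue, group[0].source
        for h in group[1:]:
            if h.start <= cur_end + 1:
                cur_end = max(cur_end, h.end)
                cur_eval = min(cur_eval, h.evalue)
            else:
                merged.append(DomainHit(seq_id, domain, cur_start, cur_end, cur_eval, cur_src))
                cur_start, cur_end, cur_eval, cur_src = h.start, h.end, h.evalue, h.source
        merged.append(DomainHit(seq_id, domain, cur_start, cur_end, cur_eval, cur_src))
    return merged


@dataclass(frozen=True)
class SubfamilyCall:
    seq_id: str
    species: str
    category: str
    related_group: str
    domains: tuple[str, ...]          # canonical + OTHER labels present
    architecture: str                 # rendered architecture string
    signature: NbArcSignature | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.related_group not in RELATED_GROUPS:
            raise ValueError(f"unknown related group {self.related_group!r}")


def _render_architecture(domains: set[str], nbarc: bool, category: str) -> str:
    """Table-style architecture string, e.g. 'TIR-NB_TNL-(LRR)'."""
    parts = []
    if "TIR" in domains:
        parts.append("TIR")
    if "RPW8" in domains:
        parts.append("RPW8")
    if nbarc:
        suffix = f"_{category}" if category in ("CNL", "CNL2", "RNL", "TNL") else ""
        parts.append(f"NB{suffix}")
    if "LRR" in domains:
        parts.append("(LRR)")
    others = sorted(d for d in domains if d.startswith("OTHER("))
    parts.extend(others)
    return "-".join(parts) if parts else "none"


def call_category(
    record: ProteinRecord,
    domain_hits: Sequence[DomainHit],
    signature: NbArcSignature | None,
) -> SubfamilyCall:
    """Classify one peptide; see the module docstring for the procedure."""
    merged = merge_domain_hits(h for h in domain_hits if h.seq_id == record.id)
    domains = {h.domain for h in merged}
    has_tir = "TIR" in domains
    has_rpw8 = "RPW8" in domains
    has_nbarc = "NBARC" in domains or signature is not None
    has_other = any(d.startswith("OTHER(") for d in domains)

    def make(category: str, related: str) -> SubfamilyCall:
        return SubfamilyCall(
            seq_id=record.id,
            species=record.species,
            category=category,
            related_group=related,
            domains=tuple(sorted(domains)),
            architecture=_render_architecture(domains, has_nbarc, category),
            signature=signature,
        )

    # (1) nothing canonical but CC/LRR evidence
    if not (has_tir or has_rpw8 or has_nbarc):
        return make("EXCLUDED", "none")

    # (2) truncated forms without an NB-ARC
    if not has_nbarc:
        if has_tir and has_rpw8:
            return make("ATYPICAL", "none")
        if has_tir:
            return make("TNL", "TNL_related")
        return make("RNL", "RNL_related")

    # (3) NB-ARC plus a non-canonical extra domain
    if has_other:
        return make("ATYPICAL", "none")

    # (4) majority vote over the three signature calls
    votes: dict[str, int] = {}
    if signature is not None:
        for call in signature.calls():
            if call in ("CNL", "CNL2", "RNL", "TNL"):
                votes[call] = votes.get(call, 0) + 1
    winner = None
    if votes:
        top = max(votes.values())
        leaders = [fam for fam, v in votes.items() if v == top]
        if top >= 2 and len(leaders) == 1:
            winner = leaders[0]
    if winner is None:
        return make("UNDETERMINED", "none")

    # N-terminal domain consistency
    if winner in ("CNL", "CNL2"):
        if has_tir or has_rpw8:
            return make("ATYPICAL", "none")
        return make(winner, "non_TIR")
    if winner == "TNL":
        if has_rpw8:
            return make("ATYPICAL", "none")
        return make("TNL", "TNL_related")
    # winner == RNL
    if has_tir:
        return make("ATYPICAL", "none")
    return make("RNL", "RNL_related")


def classify_all(
    records: Sequence[ProteinRecord],
    domain_hits: Sequence[DomainHit],
    signatures: Mapping[str, NbArcSignature],
) -> list[SubfamilyCall]:
    by_id: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        by_id.setdefault(h.seq_id, []).append(h)
    return [
        call_category(rec, by_id.get(rec.id, []), signatures.get(rec.id))
        for rec in records
    ]


def architecture_row(call: SubfamilyCall) -> str | None:
    """Census row label for a call (None for EXCLUDED sequences)."""
    has_tir = "TIR" in call.domains
    has_rpw8 = "RPW8" in call.domains
    has_nbarc = "NBARC" in call.domains or call.signature is not None
    if call.category == "EXCLUDED":
        return None
    if call.category == "ATYPICAL":
        return "Atypical"
    if call.category == "UNDETERMINED":
        return "Undetermined"
    if call.category == "TNL":
        if has_tir and has_nbarc:
            return "TIR-NB_TNL-(LRR)"
        if has_tir:
            return "TIR-LRR" if "LRR" in call.domains else "TIR"
        return "NB_TNL-(LRR)"
    if call.category == "RNL":
        if has_rpw8 and has_nbarc:
            return "RPW8-NB_RNL-(LRR)"
        if has_rpw8:
            return "RPW8"
        return "NB_RNL-(LRR)"
    if call.category == "CNL":
        return "NB_CNL-(LRR)"
    return "NB_CNL2-(LRR)"


def deduplicate(
    records: Sequence[ProteinRecord],
    calls: Sequence[SubfamilyCall] | None = None,
    identity_cutoff: float = 0.97,
):
    """Collapse near-redundant peptides (alleles / alternative transcripts).

    Greedy clustering at ``identity_cutoff`` keeps one representative per
    cluster: the longest member, ties broken by lexicographically smallest
    id (the greedy processing order guarantees the representative has that
    property).  Returns (records, calls) restricted to representatives;
    ``calls`` may be None.
    """
    from . import clusterseq  # local import: clusterseq has no classify dependency

    clusters = clusterseq.greedy_cluster(records, identity_cutoff)
    keep = {c.representative for c in clusters}
    kept_records = [r for r in records if r.id in keep]
    kept_calls = None
    if calls is not None:
        kept_calls = [c for c in calls if c.seq_id in keep]
    return kept_records, kept_calls, clusters
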