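"""Degenerate-consensus motif model and NB-ARC signature extraction.

The classifier's evidence comes from three NB-ARC motifs whose residue
variants track the N-terminal domain identity: RNBS-A, RNBS-D and the MHD
motif.  A motif is an ordered pattern of positions, each either an exact
residue, 'h' (hydrophobic) or 'x' (any); a subset of *discriminant*
positions must always match exactly — they carry the classification signal
and are never relaxed by the mismatch tolerance.  :func:`locate_nbarc`
anchors the NB-ARC region by chaining the universally conserved P-loop,
Kinase-2, GLPL and MHD motifs in sequence order, then reads out which
subfamily variant occupies each discriminative slot.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .seqio import AMINO_ACIDS, ProteinRecord

#: Kyte-Doolittle-positive residues accepted at 'h' pattern positions.
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWY")

SUBFAMILY_TAGS = ("CNL", "CNL2", "RNL", "TNL", "SHARED")
MOTIF_NAMES = (
    "PLOOP", "KIN2", "KIN3", "RNBS_A", "RNBS_C", "RNBS_D", "GLPL", "MHD",
    "TIR1", "TIR2", "TIR3", "TIR4", "TIR5",
)

#: NB-ARC chain in sequence order; adjacent gaps must fall inside the
#: spacing window (defaults 20-180 residues, about an NB-ARC domain span).
CHAIN = ("PLOOP", "KIN2", "GLPL", "MHD")
DEFAULT_SPACING = (20, 180)


class MotifConfigError(ValueError):
    """Invalid motif configuration entry."""


@dataclass(frozen=True)
class MotifDef:
    """A degenerate consensus pattern with discriminant positions."""

    name: str
    pattern: tuple[str, ...]          # tokens: residue letter, 'h' or 'x'
    discriminant: frozenset[int]      # 1-based positions, must match exactly
    tag: str = "SHARED"               # subfamily the variant diagnoses

    def __post_init__(self) -> None:
        if self.name not in MOTIF_NAMES:
            raise MotifConfigError(f"unknown motif name {self.name!r}")
        if self.tag not in SUBFAMILY_TAGS:
            raise MotifConfigError(f"unknown subfamily tag {self.tag!r}")
        if len(self.pattern) < 3:
            raise MotifConfigError(f"{self.name}: pattern shorter than 3 positions")
        for tok in self.pattern:
            if tok not in AMINO_ACIDS and tok not in ("h", "x"):
                raise MotifConfigError(f"{self.name}: illegal pattern symbol {tok!r}")
        if not self.discriminant:
            raise MotifConfigError(f"{self.name}: no discriminant positions")
        if not all(1 <= p <= len(self.pattern) for p in self.discriminant):
            raise MotifConfigError(f"{self.name}: discriminant position out of range")
        for p in self.discriminant:
            if self.pattern[p - 1] in ("h", "x"):
                raise MotifConfigError(
                    f"{self.name}: discriminant position {p} is not an exact residue"
                )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def key(self) -> str:
        return f"{self.name}[{self.tag}]"


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: 1-based start, mismatches at non-discriminant sites."""

    seq_id: str
    motif: str          # MotifDef.key
    name: str
    tag: str
    start: int
    mismatches: int


def _parse_pattern(raw: str) -> tuple[str, ...]:
    tokens = raw.split() if " " in raw.strip() else list(raw.strip())
    return tuple(tokens)


def load_motif_config(path: str | Path | None = None) -> list[MotifDef]:
    """Load motif definitions; with ``path=None`` the packaged defaults.

    The defaults include the fixed RNL RNBS-D (CFLDLGxFP), the RNL QHD and
    the CNL2 VHD MHD-variants.
    """
    if path is None:
        source = importlib.resources.files("nlrcensus.data") / "motifs_default.yaml"
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "motifs" not in raw:
        raise MotifConfigError("motif config must be a mapping with a 'motifs' list")
    defs = []
    for entry in raw["motifs"]:
        try:
            defs.append(
                MotifDef(
                    name=str(entry["name"]),
                    pattern=_parse_pattern(str(entry["pattern"])),
                    discriminant=frozenset(int(p) for p in entry.get("discriminant", [])),
                    tag=str(entry.get("tag", "SHARED")),
                )
            )
        except (KeyError, TypeError) as exc:
            raise MotifConfigError(f"bad motif entry {entry!r}: {exc}") from exc
    return defs


def hydrophobic_set(config_path: str | Path | None = None) -> frozenset[str]:
    if config_path is None:
        return DEFAULT_HYDROPHOBIC
    raw = yaml.safe_load(Path(config_path).read_text())
    return frozenset(raw.get("hydrophobic", "AVLIMFWY"))


def scan_motif(
    record: ProteinRecord,
    motif: MotifDef,
    window: tuple[int, int] | None = None,
    max_mismatch: int = 1,
    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> list[MotifHit]:
    """Scan for a motif; hits sorted by (mismatches, start).

    A start position is a hit when every discriminant position matches
    exactly and the total number of mismatches at non-discriminant positions
    is at most ``max_mismatch``.  'h' matches the hydrophobic set, 'x'
    matches everything, and 'X' in the sequence matches nothing (conservative
    treatment of masked residues).  ``window`` restricts starts so the whole
    match lies inside the 1-based inclusive interval.
    """
    seq = record.seq
    m = len(motif)
    lo, hi = (1, record.length) if window is None else window
    if not 1 <= lo <= hi <= record.length:
        raise ValueError(f"window {lo}..{hi} outside sequence {record.id!r}")
    hits: list[MotifHit] = []
    for start in range(lo, hi - m + 2):
        mismatches = 0
        ok = True
        for offset, tok in enumerate(motif.pattern):
            res = seq[start - 1 + offset]
            if res == "X":
                matched = False
            elif tok == "x":
                matched = True
            elif tok == "h":
                matched = res in hydrophobic
            else:
                matched = res == tok
            if matched:
                continue
            if (offset + 1) in motif.discriminant:
                ok = False
                break
            mismatches += 1
            if mismatches > max_mismatch:
                ok = False
                break
        if ok:
            hits.append(
                MotifHit(
                    seq_id=record.id,
                    motif=motif.key,
                    name=motif.name,
                    tag=motif.tag,
                    start=start,
                    mismatches=mismatches,
                )
            )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


@dataclass(frozen=True)
class NbArcSignature:
    """Subfamily evidence read off an anchored NB-ARC region."""

    seq_id: str
    rnbs_a_call: str      # CNL / CNL2 / RNL / TNL / ambiguous / absent
    rnbs_d_call: str
    mhd_call: str
    anchor_start: int     # P-loop start, 1-based
    anchor_end: int       # MHD end, 1-based

    def calls(self) -> tuple[str, str, str]:
        return (self.rnbs_a_call, self.rnbs_d_call, self.mhd_call)


def _variant_call(
    record: ProteinRecord,
    variants: Sequence[MotifDef],
    window: tuple[int, int],
    max_mismatch: int,
    hydrophobic: frozenset[str],
) -> str:
    """Best subfamily tag among variant motifs inside a window.

    Ties between distinct tags at the minimal mismatch count give
    'ambiguous'; no hit at all gives 'absent'.
    """
    if window[0] > window[1]:
        return "absent"
    best: dict[str, int] = {}
    for motif in variants:
        hits = scan_motif(record, motif, window, max_mismatch, hydrophobic)
        if hits:
            mm = hits[0].mismatches
            if motif.tag not in best or mm < best[motif.tag]:
                best[motif.tag] = mm
    if not best:
        return "absent"
    lowest = min(best.values())
    winners = sorted(tag for tag, mm in best.items() if mm == lowest)
    return winners[0] if len(winners) == 1 else "ambiguous"


def locate_nbarc(
    record: ProteinRecord,
    motifs: Sequence[MotifDef],
    spacing: tuple[int, int] = DEFAULT_SPACING,
    max_mismatch: int = 1,
    hydrophobic: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> NbArcSignature | None:
    """Anchor the NB-ARC region and extract its subfamily signature.

    Finds the best chain P-loop < Kinase-2 < GLPL < MHD-variant with
    inter-motif gaps inside ``spacing``; among competing chains the one
    with the fewest total mismatches wins, ties broken by leftmost P-loop
    (then leftmost downstream motifs).  Returns ``None`` when no chain
    exists.
    """
    by_name: dict[str, list[MotifDef]] = {}
    for m in motifs:
        by_name.setdefault(m.name, []).append(m)

    slot_hits: list[list[MotifHit]] = []
    slot_len: list[int] = []
    for name in CHAIN:
        variants = by_name.get(name, [])
        hits: list[MotifHit] = []
        for v in variants:
            hits.extend(scan_motif(record, v, None, max_mismatch, hydrophobic))
        if not hits:
            return None
        # Collapse co-located hits of sibling variants to the best mismatch
        # count per start position; chain choice only needs position + cost.
        best_at: dict[int, MotifHit] = {}
        for h in sorted(hits, key=lambda h: (h.start, h.mismatches)):
            best_at.setdefault(h.start, h)
        hits = sorted(best_at.values(), key=lambda h: h.start)
        slot_hits.append(hits)
        slot_len.append(len(variants[0]))

    gap_lo, gap_hi = spacing
    best_chain: tuple[int, tuple[int, ...]] | None = None  # (cost, starts)
    # Exhaustive search over hit combinations; hit lists are short because
    # the chain motifs carry several discriminant positions.
    for h0 in slot_hits[0]:
        for h1 in slot_hits[1]:
            g = h1.start - (h0.start + slot_len[0])
            if not gap_lo <= g <= gap_hi:
                continue
            for h2 in slot_hits[2]:
                g = h2.start - (h1.start + slot_len[1])
                if not gap_lo <= g <= gap_hi:
                    continue
                for h3 in slot_hits[3]:
                    g = h3.start - (h2.start + slot_len[2])
                    if not gap_lo <= g <= gap_hi:
                        continue
                    cost = h0.mismatches + h1.mismatches + h2.mismatches + h3.mismatches
                    starts = (h0.start, h1.start, h2.start, h3.start)
                    cand = (cost, starts)
                    if best_chain is None or cand < best_chain:
                        best_chain = cand
    if best_chain is None:
        return None
    _, (ploop_s, kin2_s, glpl_s, mhd_s) = best_chain
    mhd_len = slot_len[3]

    rnbs_a_window = (ploop_s + slot_len[0], kin2_s - 1)
    rnbs_d_window = (glpl_s + slot_len[2], mhd_s - 1)
    rnbs_a = _variant_call(
        record, [m for m in by_name.get("RNBS_A", []) if m.tag != "SHARED"],
        rnbs_a_window, max_mismatch, hydrophobic,
    )
    rnbs_d = _variant_call(
        record, [m for m in by_name.get("RNBS_D", []) if m.tag != "SHARED"],
        rnbs_d_window, max_mismatch, hydrophobic,
    )
    # The MHD call is read at the chain's MHD position itself.
    mhd = _variant_call(
        record, [m for m in by_name.get("MHD", []) if m.tag != "SHARED"],
        (mhd_s, mhd_s + mhd_len - 1), max_mismatch, hydrophobic,
    )
    return NbArcSignature(
        seq_id=record.id,
        rnbs_a_call=rnbs_a,
        rnbs_d_call=rnbs_d,
        mhd_call=mhd,
        anchor_start=ploop_s,
        anchor_end=mhd_s + mhd_len - 1,
    )
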