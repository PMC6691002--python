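"""Readers/writers for the external formats the pipeline touches.

Protein FASTA in/out (Biopython-backed), hmmscan-style per-domain tabular
hit files, TSV/JSON reports and Newick trees (scikit-bio backed).  Also the
core sequence/domain data model: :class:`ProteinRecord`, :class:`DomainHit`
and :class:`SampleSheet`.

All residue coordinates are 1-based inclusive throughout the package; the
conversion to Python slices happens only at slicing boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}
_NUCLEOTIDE = set("ACGTUN")

#: Pfam accession -> canonical domain label.  The nine LRR families plus the
#: N-terminal, TIR, RPW8 and NB-ARC entries used for NLR annotation.
PFAM_TO_DOMAIN = {
    "PF00931": "NBARC",
    "PF01582": "TIR",
    "PF05659": "RPW8",
    # LRR_1..6, LRR_8, LRR_9 and LRRNT
    "PF00560": "LRR",
    "PF07723": "LRR",
    "PF07725": "LRR",
    "PF12799": "LRR",
    "PF13306": "LRR",
    "PF13516": "LRR",
    "PF13855": "LRR",
    "PF14580": "LRR",
    "PF01462": "LRR",
}

CANONICAL_DOMAINS = ("TIR", "RPW8", "NBARC", "LRR")


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted peptide with an id, a species tag and its sequence."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty record id")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-amino-acid symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Return residues ``start..end`` (1-based inclusive)."""
        if not 1 <= start <= end <= self.length:
            raise ValueError(f"bad interval {start}..{end} for {self.id!r}")
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class DomainHit:
    """One annotated domain interval on a peptide (1-based inclusive)."""

    seq_id: str
    domain: str
    start: int
    end: int
    evalue: float = 0.0
    source: str = "external_table"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad domain interval {self.start}..{self.end}")
        if self.evalue < 0:
            raise ValueError("negative e-value")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _looks_like_nucleotide(seq: str) -> bool:
    residues = [c for c in seq if c != "*"]
    if not residues:
        return False
    frac = sum(c in _NUCLEOTIDE for c in residues) / len(residues)
    return frac >= 0.95 and len(residues) >= 30


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and terminal ``*`` stop symbols stripped.
    Duplicate ids, empty sequences, text before the first header and
    nucleotide input are rejected.
    """
    path = Path(path)
    # Pre-scan for structural problems so errors can name a line number,
    # which Biopython's parser does not report.
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            elif not seen_header:
                raise FastaFormatError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().strip("*")
        if not seq:
            raise FastaFormatError(f"{path}: record {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {entry.id!r}")
        if _looks_like_nucleotide(seq):
            raise FastaFormatError(
                f"{path}: record {entry.id!r} looks like nucleotide sequence; "
                "this pipeline takes predicted peptides (ORF prediction is out of scope)"
            )
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, seq=seq, species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_domain_table(path: str | Path, evalue_max: float = 0.03) -> list[DomainHit]:
    """Parse a whitespace-delimited per-domain hit table.

    Two dialects are accepted per row: the 23+-column hmmscan ``--domtblout``
    layout (target name, Pfam accession in column 2, query in column 4,
    i-Evalue in column 13, ali coords in columns 18-19) and a compact 5-column
    layout ``seq_id  accession_or_label  start  end  evalue`` used by the
    planted synthetic tables.  Hits above ``evalue_max`` are dropped; Pfam
    accessions map to canonical labels and unknown accessions to
    ``OTHER(name)``.  Unparseable rows are skipped with a warning.
    """
    hits: list[DomainHit] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 23:  # hmmscan --domtblout dialect
                    name, acc = fields[0], fields[1]
                    seq_id = fields[3]
                    evalue = float(fields[12])
                    start, end = int(fields[17]), int(fields[18])
                else:
                    seq_id, acc, start, end, evalue = (
                        fields[0],
                        fields[1],
                        int(fields[2]),
                        int(fields[3]),
                        float(fields[4]),
                    )
                    name = acc
                accession = acc.split(".")[0]
                domain = PFAM_TO_DOMAIN.get(accession)
                if domain is None:
                    domain = accession if accession in CANONICAL_DOMAINS else f"OTHER({name})"
                hit = DomainHit(seq_id=seq_id, domain=domain, start=start, end=end, evalue=evalue)
            except (ValueError, IndexError) as exc:
                log.warning("%s:%d: skipping unparseable row (%s)", path, lineno, exc)
                skipped += 1
                continue
            if hit.evalue <= evalue_max:
                hits.append(hit)
    if skipped:
        log.warning("%s: skipped %d unparseable rows", path, skipped)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the compact 5-column dialect read by read_domain_table."""
    inverse = {"NBARC": "PF00931", "TIR": "PF01582", "RPW8": "PF05659", "LRR": "PF13855"}
    with open(path, "w") as fh:
        fh.write("# seq_id accession start end evalue\n")
        for h in hits:
            label = inverse.get(h.domain, h.domain.removeprefix("OTHER(").removesuffix(")"))
            fh.write(f"{h.seq_id}\t{label}\t{h.start}\t{h.end}\t{h.evalue:g}\n")


@dataclass
class SampleSheet:
    """Library metadata for the drought RNA-seq design.

    One row per library: genotype (clonally propagated genotypes, default
    labels 8/11/95), treatment (control or drought), sampling day
    (0/7/14/18/22) and replicate index.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("library_id", "genotype", "treatment", "day", "replicate")
    TREATMENTS = ("control", "drought")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        if self.table["library_id"].duplicated().any():
            dups = self.table.loc[self.table["library_id"].duplicated(), "library_id"]
            raise ValueError(f"duplicate library ids: {sorted(set(dups))}")
        bad = set(self.table["treatment"]) - set(self.TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)
        self.table["day"] = self.table["day"].astype(int)

    @property
    def library_ids(self) -> list[str]:
        return list(self.table["library_id"])

    @property
    def days(self) -> list[int]:
        return sorted(self.table["day"].unique())

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"genotype": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports and trees

def write_tsv_report(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a DataFrame as TSV with a deterministic column order."""
    df.to_csv(path, sep="\t", index=index)


def write_json_report(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths, ';'-terminated."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
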