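"""Synthetic-data generators with machine-readable truth tables.

Every downstream stage is exercised against data whose ground truth is
known by construction:

* :func:`synth_proteome` — peptides assembled from N-terminal templates
  (TIR / RPW8 / neutral), an NB-ARC region carrying the subfamily-correct
  motif chain, and optional LRR repeats, plus planted domain-hit rows.
  Point mutations at a configurable rate spare discriminant positions
  unless asked not to; truncated, atypical and decoy forms are emitted at
  configured counts.
* :func:`synth_species_panel` — per-species RNL/TNL/CNL counts with a
  controlled linear RNL-on-TNL relationship (default slope 0.1 over 49
  species, mirroring the cross-species panel size) and independent CNL
  counts as a planted null.
* :func:`synth_counts` — negative-binomial count matrices over the
  5-timepoint, 3-genotype, 2-condition drought design, with treatment
  effects that ramp in from day 14.
* :func:`synth_rpw8_set` / :func:`synth_rpw8_queries` — RPW8 domain sets
  derived from known parents (for identity clustering) or from the
  packaged group anchors (for group-assignment recovery).
* :func:`random_additive_matrix` — patristic distance matrices of random
  binary trees, for exact neighbor-joining recovery checks.

All generators are deterministic in their seed.  Mutations use one
per-sequence uniform draw per position, so the mutated position sets are
nested across increasing mutation rates under a fixed seed (common random
numbers); classifier recall is therefore monotone in the rate by
construction rather than only in expectation.

Spacer and linker residues are drawn from a hydrophilic alphabet that
excludes every residue the motif discriminants and hydrophobic positions
require (no A/C/F/H/I/L/M/V/W/Y), so unmutated sequences cannot contain
accidental motif chains.  Templates are synthetic scaffolds, not real
conifer sequences; the only "real-like" fixtures are the anchor stand-ins
shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import DEFAULT_HYDROPHOBIC, MotifDef, load_motif_config
from .seqio import DomainHit, ProteinRecord, SampleSheet

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Hydrophilic spacer alphabet; cannot satisfy 'h' positions or any
#: discriminant residue of the default motif set's chain motifs.
SPACER_ALPHABET = "EKSTNQRDGP"
#: One leucine-rich-repeat unit (no A/C/H/M/Q/V/W/Y, no GG pair).
LRR_UNIT = "PSLKELDLSGNKLT"

DEFAULT_SEED = 20190812

CATEGORY_ORDER = ("CNL", "CNL2", "RNL", "TNL")


def _spacer(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SPACER_ALPHABET), size=n))


def _instantiate(
    motif: MotifDef,
    rng: np.random.Generator,
    avoid: Mapping[int, set[str]] | None = None,
) -> tuple[str, list[int]]:
    """Instantiate a motif pattern; returns (sequence, discriminant offsets).

    'h' positions draw from the hydrophobic set, 'x' positions from the
    spacer alphabet; both avoid any residue a sibling variant requires at
    that position, so an instance can never satisfy a sibling's
    discriminants.
    """
    avoid = avoid or {}
    out = []
    for pos, tok in enumerate(motif.pattern, start=1):
        banned = avoid.get(pos, set())
        if tok == "h":
            pool = sorted(DEFAULT_HYDROPHOBIC - banned)
        elif tok == "x":
            pool = sorted(set(SPACER_ALPHABET) - banned)
        else:
            out.append(tok)
            continue
        out.append(pool[int(rng.integers(len(pool)))])
    disc = sorted(p - 1 for p in motif.discriminant)
    return "".join(out), disc


def _sibling_avoid(variants: Sequence[MotifDef]) -> dict[str, dict[int, set[str]]]:
    """For each variant tag: position -> residues any sibling requires there."""
    out: dict[str, dict[int, set[str]]] = {}
    for v in variants:
        banned: dict[int, set[str]] = {}
        for sib in variants:
            if sib.tag == v.tag:
                continue
            for pos in sib.discriminant:
                banned.setdefault(pos, set()).add(sib.pattern[pos - 1])
        out[v.tag] = banned
    return out


@dataclass
class NbArcTemplate:
    seq: str
    positions: dict[str, int]        # motif slot -> 1-based start within template
    protected: list[int]             # 0-based offsets of discriminant residues


def _build_nbarc_template(tag: str, motifs: Sequence[MotifDef], rng: np.random.Generator) -> NbArcTemplate:
    by_name: dict[str, list[MotifDef]] = {}
    for m in motifs:
        by_name.setdefault(m.name, []).append(m)

    def variant(name: str, want_tag: str) -> MotifDef | None:
        for m in by_name.get(name, []):
            if m.tag == want_tag:
                return m
        return None

    avoid_a = _sibling_avoid([m for m in by_name.get("RNBS_A", []) if m.tag != "SHARED"])
    avoid_d = _sibling_avoid([m for m in by_name.get("RNBS_D", []) if m.tag != "SHARED"])

    layout = [
        ("PLOOP", variant("PLOOP", "SHARED"), {}),
        ("spacer", 10, None),
        ("RNBS_A", variant("RNBS_A", tag), avoid_a.get(tag, {})),
        ("spacer", 10, None),
        ("KIN2", variant("KIN2", "SHARED"), {}),
        ("spacer", 8, None),
        ("KIN3", variant("KIN3", "SHARED"), {}),
        ("spacer", 8, None),
        ("RNBS_C", variant("RNBS_C", "SHARED"), {}),
        ("spacer", 8, None),
        ("GLPL", variant("GLPL", "SHARED"), {}),
        ("spacer", 10, None),
        ("RNBS_D", variant("RNBS_D", tag), avoid_d.get(tag, {})),
        ("spacer", 10, None),
        ("MHD", variant("MHD", tag), {}),
    ]
    parts: list[str] = []
    positions: dict[str, int] = {}
    protected: list[int] = []
    cursor = 0
    for entry in layout:
        if entry[0] == "spacer":
            parts.append(_spacer(rng, entry[1]))
            cursor += entry[1]
            continue
        slot, motif, avoid = entry
        if motif is None:  # e.g. the polymorphic CNL2 RNBS-A: spacer instead
            filler = 8
            parts.append(_spacer(rng, filler))
            cursor += filler
            continue
        inst, disc = _instantiate(motif, rng, avoid)
        positions[slot] = cursor + 1
        protected.extend(cursor + off for off in disc)
        parts.append(inst)
        cursor += len(inst)
    return NbArcTemplate(seq="".join(parts), positions=positions, protected=protected)


@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    domain_hits: list[DomainHit]
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if sorted(ids) != sorted(self.truth["seq_id"]):
            raise AssertionError("truth table does not cover emitted records exactly once")
        lengths = {r.id: r.length for r in self.records}
        for h in self.domain_hits:
            if not 1 <= h.start <= h.end <= lengths[h.seq_id]:
                raise AssertionError(f"planted hit outside sequence: {h}")


#: (form, has_nterm, has_nbarc, has_lrr) templates per category's truncation menu.
_TRUNCATED_FORMS = {
    "TNL": ("tir_only", "tir_lrr", "nb_only"),
    "RNL": ("rpw8_only", "nb_only"),
}

_NTERM_LEN = {"TIR": 90, "RPW8": 130, "CC": 60}


def synth_proteome(
    n_per_category: int = 50,
    mutation_rate: float = 0.0,
    seed: int = DEFAULT_SEED,
    truncated_fraction: float = 0.3,
    n_atypical: int = 10,
    n_decoys: int = 10,
    corrupt_discriminants: bool = False,
    species: str = "synthetic",
    motifs: Sequence[MotifDef] | None = None,
) -> SyntheticProteome:
    """Generate a proteome with planted architectures and NB-ARC motifs.

    ``n_per_category`` peptides per subfamily (CNL, CNL2, RNL, TNL); within
    RNL and TNL a ``truncated_fraction`` is emitted as truncated forms
    (TIR-only, TIR-LRR, RPW8-only, NB-only).  ``n_atypical`` sequences
    alternate two atypical flavours (TIR N-terminus over an RNL NB-ARC;
    a kinase-like extra domain) and ``n_decoys`` LRR-only sequences are
    planted as EXCLUDED decoys.  Matching domain-hit rows are emitted with
    source='planted'.
    """
    if motifs is None:
        motifs = load_motif_config()
    rng = np.random.default_rng([seed, 101])
    templates = {tag: _build_nbarc_template(tag, motifs, rng) for tag in CATEGORY_ORDER}
    nterm_templates = {dom: _spacer(rng, n) for dom, n in _NTERM_LEN.items()}
    lrr_block = LRR_UNIT * 3
    alpha = np.array(list(ALPHABET))

    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    rows: list[dict] = []
    index = 0

    def emit(category: str, form: str) -> None:
        nonlocal index
        seq_id = f"SYN_{category}_{index:04d}"
        parts: list[str] = []
        planted: list[DomainHit] = []
        positions: dict[str, int] = {}
        protected: set[int] = set()
        cursor = 0

        def add_nterm(dom: str) -> None:
            nonlocal cursor
            tpl = nterm_templates[dom]
            if dom in ("TIR", "RPW8"):
                planted.append(DomainHit(seq_id, dom, cursor + 1, cursor + len(tpl),
                                         1e-12, "planted"))
            parts.append(tpl)
            cursor += len(tpl)

        def add_linker(n: int = 20) -> None:
            nonlocal cursor
            parts.append(_spacer(rng, n))
            cursor += n

        def add_nbarc(tag: str) -> None:
            nonlocal cursor
            tpl = templates[tag]
            planted.append(DomainHit(seq_id, "NBARC", cursor + 1, cursor + len(tpl.seq),
                                     1e-12, "planted"))
            for slot, start in tpl.positions.items():
                positions[slot] = cursor + start
            protected.update(cursor + off + 1 for off in tpl.protected)
            parts.append(tpl.seq)
            cursor += len(tpl.seq)

        def add_lrr() -> None:
            nonlocal cursor
            planted.append(DomainHit(seq_id, "LRR", cursor + 1, cursor + len(lrr_block),
                                     1e-12, "planted"))
            parts.append(lrr_block)
            cursor += len(lrr_block)

        nterm_of = {"TNL": "TIR", "RNL": "RPW8", "CNL": "CC", "CNL2": "CC"}
        if form == "full":
            add_nterm(nterm_of[category])
            add_linker()
            add_nbarc(category)
            add_linker(10)
            add_lrr()
        elif form == "tir_only":
            add_nterm("TIR")
        elif form == "tir_lrr":
            add_nterm("TIR")
            add_linker(10)
            add_lrr()
        elif form == "rpw8_only":
            add_nterm("RPW8")
        elif form == "nb_only":
            add_nbarc(category)
            add_linker(10)
            add_lrr()
        elif form == "atypical_tir_rnl":
            add_nterm("TIR")
            add_linker()
            add_nbarc("RNL")
        elif form == "atypical_kinase":
            add_nterm("CC")
            add_linker()
            add_nbarc(category)
            add_linker(10)
            kin = _spacer(rng, 60)
            planted.append(DomainHit(seq_id, "OTHER(PKinase)", cursor + 1,
                                     cursor + len(kin), 1e-12, "planted"))
            parts.append(kin)
            cursor += len(kin)
        elif form == "decoy_lrr":
            add_lrr()
            add_linker(10)
            add_lrr()
        else:  # pragma: no cover
            raise ValueError(form)

        seq = "".join(parts)
        # Coupled (common-random-numbers) point mutations: one uniform and
        # one replacement draw per position, independent of the rate, so
        # mutated sets are nested across rates under one seed.
        mut_rng = np.random.default_rng([seed, 7919, index])
        u = mut_rng.random(len(seq))
        repl = mut_rng.integers(0, len(ALPHABET) - 1, size=len(seq))
        if mutation_rate > 0:
            chars = list(seq)
            for i in np.flatnonzero(u < mutation_rate):
                if (i + 1) in protected and not corrupt_discriminants:
                    continue
                pool = [c for c in alpha if c != chars[i]]
                chars[i] = pool[repl[i]]
            seq = "".join(chars)

        records.append(ProteinRecord(id=seq_id, seq=seq, species=species))
        hits.extend(planted)
        true_cat = {"atypical_tir_rnl": "ATYPICAL", "atypical_kinase": "ATYPICAL",
                    "decoy_lrr": "EXCLUDED"}.get(form, category)
        rows.append(
            {
                "seq_id": seq_id,
                "species": species,
                "category": true_cat,
                "form": form,
                "length": len(seq),
                **{f"{slot.lower()}_start": positions.get(slot, np.nan)
                   for slot in ("PLOOP", "RNBS_A", "KIN2", "KIN3", "RNBS_C",
                                "GLPL", "RNBS_D", "MHD")},
            }
        )
        index += 1

    for category in CATEGORY_ORDER:
        n_trunc = int(round(truncated_fraction * n_per_category)) if category in _TRUNCATED_FORMS else 0
        forms = _TRUNCATED_FORMS.get(category, ())
        for i in range(n_per_category):
            if i < n_trunc:
                emit(category, forms[i % len(forms)])
            else:
                emit(category, "full")
    for i in range(n_atypical):
        emit("CNL" if i % 2 else "RNL", "atypical_kinase" if i % 2 else "atypical_tir_rnl")
    for _ in range(n_decoys):
        emit("NA", "decoy_lrr")

    truth = pd.DataFrame(rows)
    return SyntheticProteome(records=records, domain_hits=hits, truth=truth)


# ---------------------------------------------------------------------------
# Species panel

def synth_species_panel(
    n_species: int = 49,
    slope: float = 0.1,
    noise_sd: float = 5.0,
    seed: int = DEFAULT_SEED,
    intercept: float = 0.0,
    tnl_range: tuple[int, int] = (20, 400),
    cnl_range: tuple[int, int] = (30, 300),
) -> pd.DataFrame:
    """Per-species RNL/TNL/CNL counts with a planted linear RNL~TNL law.

    RNL = max(0, round(slope*TNL + intercept + Gaussian noise)); CNL counts
    are drawn independently, so the RNL~CNL regression is a planted null.
    Truth parameters are attached as DataFrame attrs.
    """
    rng = np.random.default_rng([seed, 211])
    tnl = rng.integers(tnl_range[0], tnl_range[1] + 1, size=n_species)
    noise = rng.normal(0.0, noise_sd, size=n_species)
    rnl = np.maximum(0, np.round(slope * tnl + intercept + noise)).astype(int)
    cnl = rng.integers(cnl_range[0], cnl_range[1] + 1, size=n_species)
    panel = pd.DataFrame(
        {
            "species": [f"sp{i:02d}" for i in range(n_species)],
            "tnl": tnl,
            "rnl": rnl,
            "cnl": cnl,
        }
    )
    panel.attrs.update(slope=slope, intercept=intercept, noise_sd=noise_sd, seed=seed)
    return panel


# ---------------------------------------------------------------------------
# Drought count matrices

def default_sample_sheet(
    genotypes: Sequence[str] = ("8", "11", "95"),
    days: Sequence[int] = (0, 7, 14, 18, 22),
    replicates: int = 2,
) -> SampleSheet:
    """Balanced drought design: genotypes x treatments x days x replicates."""
    rows = []
    for g in genotypes:
        for trt in ("control", "drought"):
            for day in days:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "library_id": f"g{g}_{trt}_d{day:02d}_r{rep}",
                            "genotype": g,
                            "treatment": trt,
                            "day": day,
                            "replicate": rep,
                        }
                    )
    return SampleSheet(pd.DataFrame(rows))


#: Fraction of the planted log2FC applied per sampling day; effects ramp in
#: from day 14, matching a progressive water-stress response.
DEFAULT_RAMP = {0: 0.0, 7: 0.0, 14: 0.5, 18: 1.0, 22: 1.0}

from .expression import CountMatrix  # noqa: E402  (CountMatrix has no synthetic dependency)


def synth_counts(
    n_genes: int = 1000,
    sheet: SampleSheet | None = None,
    size_factors: Sequence[float] | None = None,
    de_fraction: float = 0.1,
    log2fc: float = 2.0,
    up_fraction: float = 0.5,
    dispersion: float = 0.05,
    seed: int = DEFAULT_SEED,
    mean_log: float = np.log(100.0),
    mean_log_sd: float = 1.0,
    ramp: Mapping[int, float] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted drought effects.

    DE genes receive a signed log2 fold change (|log2fc|, sign up with
    probability ``up_fraction``) on drought libraries, scaled per day by
    ``ramp``.  With ``de_fraction=0`` the matrix is a pure null for
    type-I-error checks.
    """
    if sheet is None:
        sheet = default_sample_sheet()
    if ramp is None:
        ramp = DEFAULT_RAMP
    t = sheet.table
    n_lib = len(t)
    if size_factors is None:
        sf = np.ones(n_lib)
    else:
        sf = np.asarray(size_factors, dtype=float)
        if len(sf) != n_lib:
            raise ValueError("size_factors length mismatch")
    rng = np.random.default_rng([seed, 307])
    base = rng.lognormal(mean_log, mean_log_sd, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[:n_de] = True
    sign = np.where(rng.random(n_genes) < up_fraction, 1.0, -1.0)
    lfc = np.where(is_de, sign * abs(log2fc), 0.0)

    drought = (t["treatment"] == "drought").to_numpy()
    day_ramp = t["day"].map(ramp).to_numpy(dtype=float)
    effect = np.where(drought, day_ramp, 0.0)  # per library
    log2_mu = np.log2(base)[:, None] + lfc[:, None] * effect[None, :]
    mu = (2.0 ** log2_mu) * sf[None, :]

    if dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / dispersion
        p = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=t["library_id"]), sheet
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": is_de, "log2fc": lfc, "baseline_mean": base}
    ).set_index("gene_id")
    return cm, truth


# ---------------------------------------------------------------------------
# RPW8 domain sets

def synth_rpw8_set(
    n_parents: int = 45,
    n_domains: int = 300,
    max_divergence: float = 0.2,
    length_range: tuple[int, int] = (110, 140),
    seed: int = DEFAULT_SEED,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """RPW8-like domains derived from known parents by point substitution.

    Each emitted domain diverges from its parent by at most
    ``max_divergence`` of its positions (substitutions only, no indels),
    so two siblings are always >= 1 - 2*max_divergence identical while
    unrelated parents are far below any realistic clustering cutoff.
    """
    rng = np.random.default_rng([seed, 401])
    alpha = np.array(list(ALPHABET))
    parents = []
    for p in range(n_parents):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        parents.append(_spacer(rng, L))
    records: list[ProteinRecord] = []
    rows = []
    for i in range(n_domains):
        parent_idx = i % n_parents
        parent = parents[parent_idx]
        L = len(parent)
        n_mut = int(rng.uniform(0.0, max_divergence) * L)
        sites = rng.choice(L, size=n_mut, replace=False)
        chars = list(parent)
        for s in sites:
            pool = [c for c in alpha if c != chars[s]]
            chars[s] = pool[int(rng.integers(len(pool)))]
        seq_id = f"RPW8_{i:04d}"
        records.append(ProteinRecord(id=seq_id, seq="".join(chars)))
        rows.append({"seq_id": seq_id, "parent": parent_idx, "n_mutations": n_mut})
    return records, pd.DataFrame(rows)


def synth_rpw8_queries(
    anchors: Sequence[ProteinRecord],
    anchor_groups: Mapping[str, int],
    n_per_anchor: int = 3,
    max_divergence: float = 0.15,
    seed: int = DEFAULT_SEED,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Query domains obtained by mutating each anchor by <= max_divergence."""
    rng = np.random.default_rng([seed, 503])
    alpha = np.array(list(ALPHABET))
    records = []
    rows = []
    for anchor in anchors:
        for j in range(n_per_anchor):
            L = anchor.length
            n_mut = int(rng.uniform(0.0, max_divergence) * L)
            sites = rng.choice(L, size=n_mut, replace=False)
            chars = list(anchor.seq)
            for s in sites:
                pool = [c for c in alpha if c != chars[s]]
                chars[s] = pool[int(rng.integers(len(pool)))]
            qid = f"Q_{anchor.id}_{j}"
            records.append(ProteinRecord(id=qid, seq="".join(chars)))
            rows.append({"seq_id": qid, "anchor": anchor.id,
                         "group": anchor_groups[anchor.id]})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Random additive trees (for neighbor-joining recovery checks)

def random_additive_matrix(
    n_leaves: int, rng: np.random.Generator,
    branch_range: tuple[float, float] = (0.1, 1.0),
) -> tuple[list[str], np.ndarray]:
    """Patristic matrix of a random binary tree with positive branch lengths.

    Built by sequential leaf insertion on random edges; distances computed
    by breadth-first traversal of the explicit edge list, independently of
    any tree library.
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    lo, hi = branch_range
    # adjacency: node -> {neighbor: length}; leaves are 0..n_leaves-1
    adj: dict[int, dict[int, float]] = {}
    nxt = n_leaves  # internal node ids

    def connect(a: int, b: int, w: float) -> None:
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def disconnect(a: int, b: int) -> None:
        del adj[a][b]
        del adj[b][a]

    center = nxt
    nxt += 1
    for leaf in range(3):
        connect(center, leaf, float(rng.uniform(lo, hi)))
    for leaf in range(3, n_leaves):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[int(rng.integers(len(edges)))]
        w = adj[a][b]
        split = float(rng.uniform(0.25, 0.75))
        mid = nxt
        nxt += 1
        disconnect(a, b)
        connect(a, mid, w * split)
        connect(mid, b, w * (1.0 - split))
        connect(mid, leaf, float(rng.uniform(lo, hi)))

    labels = [f"L{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        frontier = [src]
        while frontier:
            nxt_frontier = []
            for node in frontier:
                for nb, w in adj[node].items():
                    if nb not in dist:
                        dist[nb] = dist[node] + w
                        nxt_frontier.append(nb)
            frontier = nxt_frontier
        for dst in range(n_leaves):
            D[src, dst] = dist[dst]
    D = 0.5 * (D + D.T)  # path sums accumulate in opposite orders; symmetrize exactly
    np.fill_diagonal(D, 0.0)
    return labels, D
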