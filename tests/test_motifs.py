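import numpy as np
import pytest

from nlrcensus import motifs, synthetic
from nlrcensus.motifs import MotifConfigError, MotifDef
from nlrcensus.seqio import ProteinRecord

from oracles import exhaustive_motif_scan


def _get(defs, name, tag):
    return next(m for m in defs if m.name == name and m.tag == tag)


class TestConfig:
    def test_packaged_defaults_fix_the_diagnostic_motifs(self, motif_defs):
        rnl_d = _get(motif_defs, "RNBS_D", "RNL")
        assert "".join(t if t != "x" else "x" for t in rnl_d.pattern) == "CFLDLGxFP"
        assert rnl_d.pattern[0] == "C" and 1 in rnl_d.discriminant
        assert rnl_d.pattern[3] == "D" and 4 in rnl_d.discriminant
        assert rnl_d.pattern[5] == "G" and 6 in rnl_d.discriminant
        qhd = _get(motif_defs, "MHD", "RNL")
        assert qhd.pattern == ("Q", "H", "D")
        assert qhd.discriminant == frozenset({1, 2, 3})
        vhd = _get(motif_defs, "MHD", "CNL2")
        assert vhd.pattern == ("V", "H", "D")
        # the polymorphic CNL2 RNBS-A has no consensus entry
        assert not any(m.name == "RNBS_A" and m.tag == "CNL2" for m in motif_defs)

    def test_illegal_symbols_rejected(self):
        with pytest.raises(MotifConfigError, match="illegal"):
            MotifDef(name="MHD", pattern=("Q", "?", "D"), discriminant=frozenset({1}))
        with pytest.raises(MotifConfigError):
            MotifDef(name="MHD", pattern=("Q", "H", "D"), discriminant=frozenset())
        with pytest.raises(MotifConfigError):
            MotifDef(name="MHD", pattern=("Q", "H", "D"), discriminant=frozenset({9}))

    def test_custom_config_file(self, tmp_path):
        path = tmp_path / "m.yaml"
        path.write_text(
            "motifs:\n  - {name: MHD, tag: RNL, pattern: Q H D, discriminant: [1,2,3]}\n"
        )
        defs = motifs.load_motif_config(path)
        assert len(defs) == 1 and defs[0].tag == "RNL"
        bad = tmp_path / "bad.yaml"
        bad.write_text("motifs:\n  - {name: MHD, tag: RNL, pattern: 'Q ?', discriminant: [1]}\n")
        with pytest.raises(MotifConfigError):
            motifs.load_motif_config(bad)


class TestScan:
    def test_rnl_rnbs_d_exact_hit(self, motif_defs):
        rnl_d = _get(motif_defs, "RNBS_D", "RNL")
        rec = ProteinRecord(id="t", seq="AACFLDLGAFPKK")
        hits = motifs.scan_motif(rec, rnl_d, max_mismatch=0)
        assert [(h.start, h.mismatches) for h in hits] == [(3, 0)]

    def test_discriminant_violation_never_tolerated(self, motif_defs):
        rnl_d = _get(motif_defs, "RNBS_D", "RNL")
        with_p9_disc = MotifDef(
            name="RNBS_D", tag="RNL", pattern=rnl_d.pattern,
            discriminant=frozenset(rnl_d.discriminant | {9}),
        )
        rec = ProteinRecord(id="t", seq="AACFLDLGAFAKK")  # P9 -> A
        assert motifs.scan_motif(rec, with_p9_disc, max_mismatch=10) == []

    def test_masked_residues_match_nothing(self, motif_defs):
        qhd = _get(motif_defs, "MHD", "RNL")
        rec = ProteinRecord(id="t", seq="AAQXDAA")
        assert motifs.scan_motif(rec, qhd, max_mismatch=3) == []

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        residues = list("ACDEFGHIKLMNPQRSTVWYX")
        hset = motifs.DEFAULT_HYDROPHOBIC
        for _ in range(300):
            seq = "".join(rng.choice(residues, size=60, p=[0.0475] * 20 + [0.05]))
            tokens = []
            for _ in range(6):
                r = rng.random()
                tokens.append("x" if r < 0.2 else "h" if r < 0.4
                              else str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))))
            exact = [i + 1 for i, t in enumerate(tokens) if t not in ("x", "h")]
            if not exact:
                tokens[0] = "A"
                exact = [1]
            disc = frozenset(
                rng.choice(exact, size=int(rng.integers(1, len(exact) + 1)), replace=False).tolist()
            )
            motif = MotifDef(name="RNBS_D", tag="SHARED", pattern=tuple(tokens), discriminant=disc)
            mm = int(rng.integers(0, 3))
            rec = ProteinRecord(id="r", seq=seq)
            got = [(h.start, h.mismatches) for h in motifs.scan_motif(rec, motif, max_mismatch=mm)]
            want = exhaustive_motif_scan(seq, tokens, disc, mm, hset)
            assert got == want

    def test_raising_tolerance_never_removes_hits(self, motif_defs):
        rng = np.random.default_rng(3)
        rnl_d = _get(motif_defs, "RNBS_D", "RNL")
        for _ in range(50):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            rec = ProteinRecord(id="r", seq=seq)
            prev: set[int] = set()
            for mm in range(0, 4):
                starts = {h.start for h in motifs.scan_motif(rec, rnl_d, max_mismatch=mm)}
                assert prev <= starts
                prev = starts

    def test_determinism(self, motif_defs):
        rec = ProteinRecord(id="r", seq="AACFLDLGAFPKKCFLDLGSFP")
        rnl_d = _get(motif_defs, "RNBS_D", "RNL")
        a = motifs.scan_motif(rec, rnl_d)
        b = motifs.scan_motif(rec, rnl_d)
        assert a == b


class TestLocateNbarc:
    def test_planted_sequences_yield_unanimous_calls(self, clean_proteome, motif_defs,
                                                     clean_signatures):
        truth = clean_proteome.truth.set_index("seq_id")
        by_id = {r.id: r for r in clean_proteome.records}
        for seq_id, row in truth.iterrows():
            if row["form"] != "full":
                continue
            sig = clean_signatures[seq_id]
            cat = row["category"]
            assert sig.rnbs_d_call == cat, seq_id
            if cat == "RNL":
                assert sig.calls() == ("RNL", "RNL", "RNL")
            if cat == "CNL2":
                assert sig.rnbs_a_call == "absent" and sig.mhd_call == "CNL2"
            if cat in ("CNL", "TNL"):
                # the MHD consensus is shared between CNL and TNL
                assert sig.mhd_call == "ambiguous"
            assert sig.anchor_start == int(truth.loc[seq_id, "ploop_start"])
            rec = by_id[seq_id]
            assert sig.anchor_end <= rec.length

    def test_featureless_sequence_has_no_anchor(self, motif_defs):
        rec = ProteinRecord(id="poly_a", seq="A" * 50)
        assert motifs.locate_nbarc(rec, motif_defs) is None

    def test_qhd_to_mhd_swap_breaks_the_rnl_call(self, clean_proteome, motif_defs):
        truth = clean_proteome.truth.set_index("seq_id")
        by_id = {r.id: r for r in clean_proteome.records}
        rnl_full = truth[(truth["category"] == "RNL") & (truth["form"] == "full")]
        checked = 0
        for seq_id, row in rnl_full.iterrows():
            rec = by_id[seq_id]
            pos = int(row["mhd_start"])  # 1-based Q of the QHD motif
            assert rec.seq[pos - 1] == "Q"
            mutated = ProteinRecord(
                id=rec.id, seq=rec.seq[: pos - 1] + "M" + rec.seq[pos:]
            )
            sig = motifs.locate_nbarc(mutated, motif_defs)
            assert sig is not None and sig.mhd_call != "RNL"
            checked += 1
        assert checked > 0
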