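import numpy as np
import pandas as pd
import pytest

from nlrcensus import classify, motifs, synthetic
from nlrcensus.seqio import write_fasta

SEED = synthetic.DEFAULT_SEED


class TestProteome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = synthetic.synth_proteome(n_per_category=5, mutation_rate=0.05, seed=SEED)
        b = synthetic.synth_proteome(n_per_category=5, mutation_rate=0.05, seed=SEED)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(a.records, pa)
        write_fasta(b.records, pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = synthetic.synth_proteome(n_per_category=5, mutation_rate=0.05, seed=SEED + 1)
        assert any(x.seq != y.seq for x, y in zip(a.records, c.records))

    def test_truth_covers_records_exactly_once(self, clean_proteome):
        ids = sorted(r.id for r in clean_proteome.records)
        assert sorted(clean_proteome.truth["seq_id"]) == ids
        assert clean_proteome.truth["seq_id"].is_unique

    def test_category_composition(self, clean_proteome):
        counts = clean_proteome.truth["category"].value_counts()
        assert counts["CNL"] == 12 and counts["CNL2"] == 12
        assert counts["RNL"] == 12 and counts["TNL"] == 12
        assert counts["ATYPICAL"] == 6 and counts["EXCLUDED"] == 6

    def test_mutations_nested_across_rates(self):
        base = synthetic.synth_proteome(n_per_category=4, mutation_rate=0.0, seed=SEED)
        prev_diffs: list[set] = None
        for eps in (0.02, 0.05, 0.1):
            mut = synthetic.synth_proteome(n_per_category=4, mutation_rate=eps, seed=SEED)
            diffs = []
            for r0, r1 in zip(base.records, mut.records):
                assert r0.id == r1.id and len(r0.seq) == len(r1.seq)
                diffs.append({i for i, (x, y) in enumerate(zip(r0.seq, r1.seq)) if x != y})
            if prev_diffs is not None:
                assert all(p <= d for p, d in zip(prev_diffs, diffs))
            prev_diffs = diffs

    def test_discriminants_spared_unless_corrupted(self, motif_defs):
        eps = 0.5
        spared = synthetic.synth_proteome(n_per_category=6, mutation_rate=eps, seed=SEED)
        truth = spared.truth.set_index("seq_id")
        by_id = {r.id: r for r in spared.records}
        rnl = truth[(truth["category"] == "RNL") & (truth["form"] == "full")]
        for seq_id, row in rnl.iterrows():
            pos = int(row["mhd_start"])
            assert by_id[seq_id].seq[pos - 1 : pos + 2] == "QHD"
        corrupted = synthetic.synth_proteome(
            n_per_category=6, mutation_rate=eps, seed=SEED, corrupt_discriminants=True
        )
        by_id_c = {r.id: r for r in corrupted.records}
        damaged = sum(
            by_id_c[seq_id].seq[int(row["mhd_start"]) - 1] != "Q"
            for seq_id, row in rnl.iterrows()
        )
        assert damaged > 0

    def test_corrupted_qhd_drops_rnl_calls(self, motif_defs):
        prot = synthetic.synth_proteome(
            n_per_category=6, mutation_rate=0.9, seed=SEED, corrupt_discriminants=True
        )
        truth = prot.truth.set_index("seq_id")
        by_id = {r.id: r for r in prot.records}
        rnl_ids = truth[(truth["category"] == "RNL") & (truth["form"] == "full")].index
        rnl_calls = 0
        for seq_id in rnl_ids:
            sig = motifs.locate_nbarc(by_id[seq_id], motif_defs)
            if sig is not None and sig.mhd_call == "RNL":
                rnl_calls += 1
        assert rnl_calls == 0


class TestPanel:
    def test_zero_noise_exact_recovery(self):
        from nlrcensus.census_stats import ols_regression

        panel = synthetic.synth_species_panel(n_species=20, slope=0.2, noise_sd=0.0,
                                              seed=SEED, tnl_range=(100, 400))
        res = ols_regression(panel["tnl"], panel["rnl"])
        # counts are rounded, so recovery is exact up to rounding error
        assert abs(res.slope - 0.2) < 0.01
        assert res.r_squared > 0.99

    def test_determinism_and_shape(self):
        a = synthetic.synth_species_panel(seed=SEED)
        b = synthetic.synth_species_panel(seed=SEED)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 49
        assert (a[["tnl", "rnl", "cnl"]] >= 0).all().all()


class TestCounts:
    def test_determinism(self):
        a, ta = synthetic.synth_counts(n_genes=50, seed=SEED)
        b, tb = synthetic.synth_counts(n_genes=50, seed=SEED)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta, tb)

    def test_null_matrix_has_no_planted_effects(self):
        cm, truth = synthetic.synth_counts(n_genes=100, de_fraction=0.0, seed=SEED)
        assert not truth["is_de"].any()
        assert (truth["log2fc"] == 0).all()

    def test_effects_ramp_from_day_14(self):
        cm, truth = synthetic.synth_counts(
            n_genes=400, de_fraction=1.0, log2fc=2.0, up_fraction=1.0,
            dispersion=0.01, seed=SEED,
        )
        t = cm.sheet.table
        means = {}
        for day in (0, 7, 14, 22):
            d_libs = t[(t["day"] == day) & (t["treatment"] == "drought")]["library_id"]
            c_libs = t[(t["day"] == day) & (t["treatment"] == "control")]["library_id"]
            ratio = cm.counts[d_libs].mean(axis=1) / cm.counts[c_libs].mean(axis=1).clip(lower=1)
            means[day] = np.log2(ratio.clip(lower=1e-3)).median()
        assert abs(means[0]) < 0.3 and abs(means[7]) < 0.3
        assert means[14] == pytest.approx(1.0, abs=0.35)
        assert means[22] == pytest.approx(2.0, abs=0.35)

    def test_small_dispersion_approaches_poisson(self):
        cm, _ = synthetic.synth_counts(
            n_genes=3000, de_fraction=0.0, dispersion=1e-9, seed=SEED,
        )
        arr = cm.counts.to_numpy(float)
        mean = arr.mean(axis=1)
        var = arr.var(axis=1, ddof=1)
        big = mean > 50
        ratio = np.median(var[big] / mean[big])
        assert abs(ratio - 1.0) < 0.1


class TestRpw8Sets:
    def test_divergence_bounds_hold(self):
        recs, truth = synthetic.synth_rpw8_set(n_parents=10, n_domains=40,
                                               max_divergence=0.2, seed=SEED)
        assert len(recs) == 40
        assert truth["parent"].nunique() == 10
        frac = truth["n_mutations"] / [len(r.seq) for r in recs]
        assert (frac <= 0.2).all()

    def test_every_parent_represented(self):
        _, truth = synthetic.synth_rpw8_set(n_parents=45, n_domains=300, seed=SEED)
        assert truth["parent"].nunique() == 45


def test_additive_matrix_satisfies_four_point_condition():
    rng = np.random.default_rng(13)
    for _ in range(20):
        labels, D = synthetic.random_additive_matrix(6, rng)
        n = len(labels)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        # four-point condition: the two largest of the three pair sums tie
        idx = range(n)
        import itertools

        for (i, j, k, l) in itertools.combinations(idx, 4):
            sums = sorted(
                [D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]]
            )
            assert sums[2] - sums[1] < 1e-9
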