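import warnings

import numpy as np
import pandas as pd
import pytest

from nlrcensus import expression, synthetic
from nlrcensus.expression import (CountMatrix, bh_adjust, expression_groups,
                                  filter_low_counts, nb_lrt, size_factors,
                                  subfamily_de_summary)
from nlrcensus.seqio import SampleSheet

from oracles import stepup_bh

SEED = synthetic.DEFAULT_SEED

warnings.filterwarnings("ignore", module="statsmodels")


def mini_sheet(n, treatment="control"):
    return SampleSheet(
        pd.DataFrame(
            {
                "library_id": [f"lib{i}" for i in range(n)],
                "genotype": ["8"] * n,
                "treatment": [treatment] * n,
                "day": [0] * n,
                "replicate": list(range(1, n + 1)),
            }
        )
    )


class TestFilter:
    def _cm(self, rows):
        df = pd.DataFrame(rows, columns=[f"lib{i}" for i in range(len(rows[0]))])
        df.index = [f"g{i}" for i in range(len(rows))]
        return CountMatrix(df, mini_sheet(len(rows[0])))

    def test_strict_threshold(self):
        cm = self._cm([[6, 6, 0, 0], [5, 5, 5, 5], [6, 0, 0, 0], [7, 8, 9, 10]])
        kept = filter_low_counts(cm)
        assert list(kept.counts.index) == ["g0", "g3"]

    def test_all_zero_matrix_empties(self):
        cm = self._cm([[0, 0, 0], [0, 0, 0]])
        assert filter_low_counts(cm).n_genes == 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            self._cm([[1, -1, 0]])


class TestSizeFactors:
    def test_doubled_library_analytic(self):
        cm = CountMatrix(
            pd.DataFrame({"lib0": [10, 20, 30], "lib1": [20, 40, 60]}), mini_sheet(2)
        )
        sf = size_factors(cm)
        assert sf.to_numpy() == pytest.approx([2 ** -0.5, 2 ** 0.5])

    def test_identical_libraries_unit_factors(self):
        cm = CountMatrix(
            pd.DataFrame({"lib0": [5, 9, 14], "lib1": [5, 9, 14], "lib2": [5, 9, 14]}),
            mini_sheet(3),
        )
        assert size_factors(cm).to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_planted_factors_recovered_within_5pct(self):
        cm, _ = synthetic.synth_counts(
            n_genes=2000, sheet=mini_sheet(3), size_factors=[0.5, 1.0, 2.0],
            de_fraction=0.0, seed=SEED,
        )
        sf = size_factors(cm).to_numpy()
        assert np.all(np.abs(sf / np.array([0.5, 1.0, 2.0]) - 1) < 0.05)

    def test_log_mean_zero_when_zero_free(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(50, size=(200, 4)) + 1, columns=[f"lib{i}" for i in range(4)]
        )
        cm = CountMatrix(counts, mini_sheet(4))
        # median-of-ratios factors are centred: log geometric mean ~ 0
        assert abs(np.log(size_factors(cm)).mean()) < 0.05


class TestBH:
    def test_closed_form_triple(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_independent_stepup_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(stepup_bh(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestNbLrt:
    def test_flat_gene_not_significant(self):
        sheet = synthetic.default_sample_sheet(genotypes=("8",), replicates=1)
        n = len(sheet.library_ids)
        counts = pd.DataFrame(
            {lib: [100, 40] for lib in sheet.library_ids}, index=["flat", "flat2"]
        )
        cm = CountMatrix(counts, sheet)
        res = nb_lrt(cm, sf=pd.Series(1.0, index=sheet.library_ids))
        assert res.loc["flat", "log2_fold_change"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["flat", "pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_null_type_I_error_calibrated(self):
        cm, _ = synthetic.synth_counts(n_genes=400, de_fraction=0.0, seed=SEED)
        cm = filter_low_counts(cm)
        res = nb_lrt(cm)
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08  # acceptance checks the tighter band at n=1000

    def test_planted_effects_recovered(self):
        cm, truth = synthetic.synth_counts(
            n_genes=300, de_fraction=0.2, log2fc=2.0, seed=SEED + 1
        )
        cm = filter_low_counts(cm)
        res = nb_lrt(cm)
        tr = truth.loc[res.index]
        de = tr["is_de"]
        recall = ((res["padj"] < 0.05) & de).sum() / de.sum()
        assert recall >= 0.9
        signs = np.sign(res.loc[de, "log2_fold_change"])
        assert (signs == np.sign(tr.loc[de, "log2fc"])).mean() > 0.95
        assert np.all(res["lrt_statistic"].dropna() >= 0)
        assert np.all(res["padj"].dropna() >= res.loc[res["padj"].notna(), "pvalue"] - 1e-12)

    def test_status_consistent_with_padj_and_sign(self):
        cm, _ = synthetic.synth_counts(n_genes=200, de_fraction=0.3, seed=SEED + 2)
        cm = filter_low_counts(cm)
        res = nb_lrt(cm)
        up = res["status"] == "up"
        assert ((res.loc[up, "padj"] < 0.05) & (res.loc[up, "log2_fold_change"] > 0)).all()


class TestGroups:
    def test_k_equals_n_gives_singletons(self):
        cm, _ = synthetic.synth_counts(n_genes=8, de_fraction=0.5, seed=SEED)
        groups = expression_groups(list(cm.counts.index), cm, k=8)
        assert sorted(len(g.gene_ids) for g in groups) == [1] * 8

    def test_two_archetypes_split_perfectly(self):
        cm, truth = synthetic.synth_counts(
            n_genes=40, de_fraction=0.5, log2fc=3.0, up_fraction=1.0, seed=SEED
        )
        groups = expression_groups(list(cm.counts.index), cm, k=2)
        de_ids = set(truth[truth["is_de"]].index)
        assert any(set(g.gene_ids) == de_ids for g in groups)

    def test_gene_order_permutation_invariant(self):
        cm, _ = synthetic.synth_counts(n_genes=30, de_fraction=0.4, seed=SEED + 3)
        ids = list(cm.counts.index)
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(ids))
        g1 = expression_groups(ids, cm, k=5)
        g2 = expression_groups(shuffled, cm, k=5)
        parts1 = sorted(tuple(sorted(g.gene_ids)) for g in g1)
        parts2 = sorted(tuple(sorted(g.gene_ids)) for g in g2)
        assert parts1 == parts2

    def test_groups_partition_de_set(self):
        cm, _ = synthetic.synth_counts(n_genes=50, de_fraction=0.5, seed=SEED + 4)
        ids = list(cm.counts.index)[:25]
        groups = expression_groups(ids, cm, k=6)
        members = sorted(g for grp in groups for g in grp.gene_ids)
        assert members == sorted(ids)


class TestSubfamilySummary:
    def _de_frame(self):
        return pd.DataFrame(
            {
                "log2_fold_change": [2.0, 1.5, -1.0, -3.0, 0.5, -0.2],
                "status": ["up", "up", "down", "down", "up", "ns"],
            },
            index=[f"g{i}" for i in range(6)],
        )

    def test_up_fraction_and_conservation(self):
        de = self._de_frame()
        cats = pd.Series(
            ["RNL", "RNL", "RNL", "TNL", "CNL", "CNL"], index=de.index
        )
        summary = subfamily_de_summary(de, cats)
        assert summary.loc["RNL", "n_de"] == 3
        assert summary.loc["RNL", "up_fraction"] == pytest.approx(2 / 3)
        assert summary["n_de"].sum() == (de["status"] != "ns").sum()

    def test_no_de_genes_empty(self):
        de = self._de_frame()
        de["status"] = "ns"
        assert subfamily_de_summary(de, pd.Series(dtype=object)).empty
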