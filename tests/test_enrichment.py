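import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from mztkin import enrichment, synth
from mztkin.datatypes import CellTable


class TestZygoticFractionBins:
    def _table(self, fractions, n_cells=30, seed=0):
        rng = np.random.default_rng(seed)
        n_genes = len(fractions)
        counts = rng.integers(3, 20, size=(n_genes, n_cells))
        ntr = np.empty((n_genes, n_cells))
        for i, f in enumerate(fractions):
            ntr[i] = np.clip(f + rng.normal(0, 0.005, n_cells), 0, 1)
        meta = pd.DataFrame({
            "stage": ["s"] * n_cells, "cluster": ["a"] * n_cells,
            "pseudotime_au": np.linspace(0.1, 1, n_cells), "replicate": ["A"] * n_cells,
        }, index=[f"c{i}" for i in range(n_cells)])
        return CellTable(genes=pd.Index([f"g{i}" for i in range(n_genes)]),
                         counts=sparse.csr_matrix(counts), ntr=ntr, meta=meta)

    def test_class_thresholds(self):
        table = self._table([0.03, 0.40, 0.70])
        df = enrichment.gene_zygotic_fraction_bins(table, n_bins=3)
        assert df.loc["g0", "gene_class"] == "maternal"
        assert df.loc["g1", "gene_class"] == "maternal_zygotic"
        assert df.loc["g2", "gene_class"] == "zygotic"

    def test_quantile_bins_equal_count(self):
        rng = np.random.default_rng(1)
        table = self._table(list(rng.uniform(0, 1, 50)))
        df = enrichment.gene_zygotic_fraction_bins(table, n_bins=10)
        counts = df["quantile_bin"].value_counts()
        assert len(counts) == 10
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == len(df)

    def test_gene_without_qualifying_cells_excluded(self):
        table = self._table([0.1, 0.9])
        table.counts = sparse.csr_matrix(
            np.vstack([np.zeros(30, dtype=int), np.full(30, 10)]))
        df = enrichment.gene_zygotic_fraction_bins(table, n_bins=2)
        assert "g0" not in df.index and "g1" in df.index


class TestCellTypeRestriction:
    def _marker_table(self, seed=0, n_cells=200):
        rng = np.random.default_rng(seed)
        clusters = np.array(["target"] * (n_cells // 2) + ["other"] * (n_cells // 2))
        counts = np.vstack([
            np.where(clusters == "target", rng.poisson(20, n_cells), rng.poisson(2, n_cells)),
            rng.poisson(10, n_cells),
            rng.poisson(60, n_cells),
        ])
        ntr = np.full(counts.shape, 0.9)
        meta = pd.DataFrame({
            "stage": ["s"] * n_cells, "cluster": clusters,
            "pseudotime_au": rng.uniform(0.1, 1.0, n_cells), "replicate": ["A"] * n_cells,
        }, index=[f"c{i}" for i in range(n_cells)])
        return CellTable(genes=pd.Index(["marker", "flat", "high"]),
                         counts=sparse.csr_matrix(counts), ntr=ntr, meta=meta)

    def test_planted_marker_recovered_as_top_hit(self):
        df = enrichment.celltype_restriction_test(self._marker_table())
        row = df[df["gene"] == "marker"].iloc[0]
        assert row["cell_type"] == "target"
        assert row["significant"]

    def test_flat_gene_not_significant(self):
        df = enrichment.celltype_restriction_test(self._marker_table())
        assert not df[df["gene"] == "flat"]["significant"].any()

    def test_bonferroni_family_arithmetic(self):
        df = enrichment.celltype_restriction_test(self._marker_table(), family_size=100)
        row = df[df["gene"] == "flat"].iloc[0]
        assert row["p_adjusted"] == pytest.approx(min(row["p_raw"] * 100, 1.0))


class TestKmerExtraction:
    def test_sliding_window_example(self):
        sets = enrichment.extract_utr_kmers([("g", "GCACUUAAAA")], k_range=(3, 3))
        assert {"GCA", "CAC", "ACU", "CUU", "UUA", "UAA", "AAA"} == sets["g"]

    def test_short_utr_removed(self):
        sets = enrichment.extract_utr_kmers([("g", "ACGUACGU")])  # 8 nt < 10
        assert "g" not in sets

    def test_longest_utr_kept(self):
        short = "A" * 50
        long = "C" * 120
        sets = enrichment.extract_utr_kmers([("g", short), ("g", long)])
        assert "AAA" not in sets["g"] and "CCC" in sets["g"]

    def test_presence_sets_agree_with_naive_oracle(self):
        records, _ = synth.plant_kmer_sequences(100, "GCACUU", 0.5,
                                                length_range=(20, 60), rng_seed=3)
        sets = enrichment.extract_utr_kmers(records)
        rng = np.random.default_rng(4)
        for gene, seq in records:
            L = len(seq)
            assert len(sets[gene]) <= sum(L - k + 1 for k in range(3, 9))
            for _ in range(20):
                k = int(rng.integers(3, 9))
                probe = "".join(rng.choice(list("ACGU"), size=k))
                assert (probe in sets[gene]) == (probe in seq)

    def test_non_nucleotide_sequence_skipped(self):
        sets = enrichment.extract_utr_kmers([("bad", "ACGTNNACGTACGT"), ("ok", "ACGU" * 5)])
        assert "bad" not in sets and "ok" in sets


class TestKmerEnrichment:
    def test_theta_definition_one_sd_shift(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 400)
        x = y[:200] + 1.0
        theta = enrichment.standardized_mean_difference(x, y[200:])
        assert theta == pytest.approx(1.0, abs=0.25)

    def test_theta_affine_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(1, 1, 50), rng.normal(0, 1, 70)
        t0 = enrichment.standardized_mean_difference(x, y)
        t1 = enrichment.standardized_mean_difference(3 * x + 7, 3 * y + 7)
        assert t1 == pytest.approx(t0)

    def test_planted_kmer_recovered_with_sign(self):
        records, labels = synth.plant_kmer_sequences(300, "GCACUU", 0.3, rng_seed=7)
        sets = enrichment.extract_utr_kmers(records)
        rng = np.random.default_rng(8)
        vals = pd.Series(rng.normal(5, 0.8, 300), index=[g for g, _ in records])
        vals[labels] -= 0.8  # carriers destabilized: shorter half-life
        df = enrichment.kmer_parameter_enrichment(sets, vals, k_filter=6)
        hit = df[df["kmer"] == "GCACUU"].iloc[0]
        assert hit["significant"]
        assert hit["theta"] < -0.13
        assert hit["direction"] == "down"

    def test_permuted_values_not_significant(self):
        records, labels = synth.plant_kmer_sequences(300, "GCACUU", 0.3, rng_seed=7)
        sets = enrichment.extract_utr_kmers(records)
        rng = np.random.default_rng(9)
        vals = pd.Series(rng.normal(5, 0.8, 300), index=[g for g, _ in records])
        vals[labels] -= 0.8
        hits = 0
        for i in range(10):
            perm = pd.Series(rng.permutation(vals.to_numpy()), index=vals.index)
            df = enrichment.kmer_parameter_enrichment(sets, perm, k_filter=6)
            sub = df[df["kmer"] == "GCACUU"]
            if len(sub) and sub.iloc[0]["significant"]:
                hits += 1
        assert hits == 0

    def test_degenerate_kmers_skipped(self):
        sets = {"g0": {"AAA"}, "g1": {"AAA"}, "g2": {"AAA"}, "g3": {"AAA"}}
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=list(sets))
        df = enrichment.kmer_parameter_enrichment(sets, vals)
        assert len(df) == 0  # all genes carry it: no contrast


class TestFeatureAssociation:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(10)
        feature = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        group = pd.Series([True, False] * 50, index=feature.index)
        df = enrichment.feature_association_test(feature, group)
        assert not df["significant"].any()

    def test_monotone_relation_detected(self):
        rng = np.random.default_rng(11)
        param = pd.Series(np.linspace(0, 10, 200), index=[f"g{i}" for i in range(200)])
        feature = param + rng.normal(0, 0.5, 200)
        df = enrichment.feature_association_test(feature, param)
        up = df[df["direction"] == "up"].iloc[0]
        assert up["significant"] and up["q"] < 1e-10

    def test_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        fp = 0
        n_sim = 200
        for _ in range(n_sim):
            feature = pd.Series(rng.normal(size=60), index=genes)
            group = pd.Series(rng.permutation([True] * 30 + [False] * 30), index=genes)
            df = enrichment.feature_association_test(feature, group, fdr=0.05)
            fp += int(df["significant"].any())
        assert fp / n_sim <= 0.10  # nominal 5% family rate, wilson slack

    def test_constant_feature_p_one(self):
        feature = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        group = pd.Series([True] * 10 + [False] * 10, index=feature.index)
        df = enrichment.feature_association_test(feature, group)
        assert (df["p_raw"] == 1.0).all()

    def test_wilcoxon_variant(self):
        rng = np.random.default_rng(13)
        feature = pd.Series(np.r_[rng.normal(2, 1, 50), rng.normal(0, 1, 50)],
                            index=[f"g{i}" for i in range(100)])
        group = pd.Series([True] * 50 + [False] * 50, index=feature.index)
        df = enrichment.feature_association_test(feature, group, test="wilcoxon")
        assert df[df["direction"] == "up"].iloc[0]["significant"]
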