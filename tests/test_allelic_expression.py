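"""%mus metric and the gene-classification cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from xi_origami import (call_reactivated, class_enrichment, classify_genes,
                        cluster_samples, compare_cdp, percent_mus)
from xi_origami.synthetic import make_expression_truth, simulate_allelic_counts
from conftest import toy_allelic_tables

WT_REF = ["WT_DMSO_c1", "WT_DMSO_c2"]


class TestPercentMus:
    @pytest.mark.parametrize("mus,cas,expected", [
        (0, 10, 0.0),
        (7, 7, 50.0),
        (10, 0, 100.0),
    ])
    def test_simple_ratios(self, mus, cas, expected):
        assert percent_mus(mus, cas) == pytest.approx(expected)

    def test_one_in_eleven_is_the_miscalled_snp_threshold(self):
        # 1 mus of 11 allele reads = 9.0909...%, the cutoff used to flag
        # incorrectly annotated SNPs in pure-cas cells
        assert percent_mus(1, 10) == pytest.approx(9.0909, abs=1e-3)

    def test_no_allelic_reads_is_na(self):
        assert np.isnan(percent_mus(0, 0))

    def test_vectorized_bounds(self):
        rng = np.random.default_rng(0)
        mus = rng.integers(0, 100, 50)
        cas = rng.integers(1, 100, 50)
        p = percent_mus(mus, cas)
        assert ((p >= 0) & (p <= 100)).all()


class TestClassificationCascade:
    @pytest.fixture(scope="class")
    def cls(self):
        table, control = toy_allelic_tables()
        return classify_genes(table, control, WT_REF)

    def test_hand_applied_cascade_matches(self, cls):
        status = cls.genes["status"]
        assert status["g01"] == "excluded"
        assert cls.genes.loc["g01", "first_failed"] == "active"
        assert status["g02"] == "excluded"
        assert cls.genes.loc["g02", "first_failed"] == "assessable"
        assert status["g03"] == "subject_to_XCI"      # 13 reads inclusive
        assert status["g04"] == "excluded"            # miscalled SNP
        assert cls.genes.loc["g04", "is_miscalled_snp"]
        assert status["g05"] == "subject_to_XCI"      # 9.0% control, kept
        assert status["g06"] == "escapee"             # 11% > 10%, strict
        assert status["g07"] == "subject_to_XCI"      # exactly 10% is not enough
        assert set(status[status == "subject_to_XCI"].index) == {
            "g03", "g05", "g07", "g08", "g09", "g10"}

    def test_statuses_partition_and_counts_conserve(self, cls):
        s = cls.summary()
        assert s["n_escapee"] + s["n_subject_to_XCI"] + s["n_miscalled_snp"] == s["n_assessable"]
        assert s["n_active"] == 9 and s["n_assessable"] == 8

    def test_cascade_idempotent(self):
        table, control = toy_allelic_tables()
        a = classify_genes(table, control, WT_REF)
        b = classify_genes(table, control, WT_REF)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_missing_gene_fatal(self):
        table, control = toy_allelic_tables()
        broken = table[~((table.gene_id == "g03") & (table.sample_id == "WT_DMSO_c1"))]
        with pytest.raises(ValueError, match="missing"):
            classify_genes(broken, control, WT_REF)

    def test_missing_control_skips_miscalled_filter_with_warning(self):
        table, control = toy_allelic_tables()
        with pytest.warns(UserWarning, match="miscalled"):
            cls = classify_genes(table, None, WT_REF)
        assert not cls.genes["is_miscalled_snp"].any()
        assert cls.genes.loc["g04", "status"] == "subject_to_XCI"

    def test_noiseless_synthetic_truth_agreement(self):
        truth = make_expression_truth(n_genes=200, noiseless=True, seed=3)
        table, control = simulate_allelic_counts(truth)
        cls = classify_genes(table, control, WT_REF)
        status = cls.genes["status"]
        for gene, tstat, mis in zip(truth.gene_ids, truth.xci_status,
                                    truth.is_miscalled):
            if tstat in ("inactive", "low"):
                assert status[gene] == "excluded", gene
            elif mis:
                assert cls.genes.loc[gene, "is_miscalled_snp"], gene
            elif tstat == "escapee":
                assert status[gene] == "escapee", gene
            else:
                assert status[gene] == "subject_to_XCI", gene

    def test_noiseless_reactivation_recovers_truth_exactly(self):
        truth = make_expression_truth(n_genes=200, noiseless=True, seed=4)
        table, control = simulate_allelic_counts(truth)
        cls = classify_genes(table, control, WT_REF)
        react = call_reactivated(cls)
        called = set(react.index[react["is_reactivated"]])
        planted = {g for g, r in zip(truth.gene_ids, truth.is_reactivated) if r}
        assert called == planted


class TestReactivation:
    @pytest.fixture(scope="class")
    def cls(self):
        table, control = toy_allelic_tables()
        return classify_genes(table, control, WT_REF)

    def test_fold_and_p_thresholds(self, cls):
        react = call_reactivated(cls)
        assert react.loc["g08", "is_reactivated"]        # 3.5-fold, p < 0.1
        assert not react.loc["g09", "is_reactivated"]    # 2.9-fold fails
        assert react.loc["g09", "fold_ok"] == False

    def test_reactivated_subset_of_subject(self, cls):
        react = call_reactivated(cls)
        assert set(react.index) <= set(cls.subject_genes)


class TestCompareCdp:
    @pytest.fixture(scope="class")
    def cls(self):
        truth = make_expression_truth(n_genes=120, seed=5)
        table, control = simulate_allelic_counts(truth)
        return classify_genes(table, control, WT_REF)

    def test_identical_groups_paired_na_by_convention(self, cls):
        res = compare_cdp(cls, WT_REF, WT_REF, paired=True)
        assert np.isnan(res["p_value"])

    def test_shifted_group_matches_manual_ranks_and_shifts_right(self):
        # unpaired comparison with a known +5 point shift
        truth = make_expression_truth(n_genes=80, seed=6)
        table, control = simulate_allelic_counts(truth)
        cls = classify_genes(table, control, WT_REF)
        a = cls.pmus.loc[cls.subject_genes, WT_REF].mean(axis=1).dropna()
        b = a + 5.0
        ranks = stats.rankdata(np.concatenate([b, a]))
        u_manual = ranks[:len(b)].sum() - len(b) * (len(b) + 1) / 2
        u, _ = stats.mannwhitneyu(b, a, alternative="greater")
        assert u == pytest.approx(u_manual)
        assert np.median(b) > np.median(a)

    def test_planted_reactivation_shift_detected(self, cls):
        res = compare_cdp(cls, ["WT_DMSO_c1", "WT_DMSO_c2"],
                          ["KO_Aza_c1", "KO_Aza_c2"], paired=True,
                          alternative="greater")
        assert res["p_value"] < 0.05
        # CDP of the treated group sits to the right
        assert res["median_b"] >= res["median_a"]

    def test_cdp_coordinates_are_valid_ecdf(self, cls):
        res = compare_cdp(cls, WT_REF, ["KO_Aza_c1", "KO_Aza_c2"])
        xs, ys = res["cdp_b"]
        assert (np.diff(xs) >= 0).all()
        assert ys[0] > 0 and ys[-1] == pytest.approx(1.0)


class TestClassEnrichment:
    def test_disjoint_annotation_skipped_with_warning(self):
        table, control = toy_allelic_tables()
        cls = classify_genes(table, control, WT_REF)
        with pytest.warns(UserWarning):
            res = class_enrichment(cls, {"absent_gene": "I"}, WT_REF)
        assert np.isnan(res["p_value"]) and res["n_intersection"] == 0

    def test_intersection_counts_on_constructed_fixture(self):
        # a fixture built to the published set sizes: 126 annotated Class I
        # genes, 216 subject genes, 79 in the intersection
        truth = make_expression_truth(n_genes=400, noiseless=True, seed=7,
                                      escapee_fraction=0.0, inactive_fraction=0.0,
                                      low_count_fraction=0.0, miscalled_fraction=0.0)
        table, control = simulate_allelic_counts(truth)
        cls = classify_genes(table, control, WT_REF)
        subject = cls.subject_genes[:216]
        labels = {g: "I" for g in subject[:79]}
        labels.update({f"off_chromosome_{k}": "I" for k in range(126 - 79)})
        res = class_enrichment(cls, labels, ["KO_Aza_c1", "KO_Aza_c2"])
        assert res["n_annotated"] == 126
        assert res["n_intersection"] == 79

    def test_planted_class_bias_detected(self):
        truth = make_expression_truth(n_genes=200, seed=8)
        table, control = simulate_allelic_counts(truth)
        cls = classify_genes(table, control, WT_REF)
        labels = {g: c for g, c in zip(truth.gene_ids, truth.class_label)}
        # Class I genes carry the planted reactivation effect in KO_Aza
        res = class_enrichment(cls, labels, ["KO_Aza_c1", "KO_Aza_c2"])
        assert res["p_value"] < 0.05


class TestClusterSamples:
    def test_condition_effects_recover_four_groups(self):
        truth = make_expression_truth(n_genes=300, seed=9)
        table, control = simulate_allelic_counts(truth)
        # add distinct condition-level shifts so conditions dominate clone noise
        cls = classify_genes(table, control, WT_REF)
        shifts = {"WT_DMSO": 0.0, "WT_Aza": 30.0, "KO_DMSO": 60.0, "KO_Aza": 90.0}
        for s in cls.pmus.columns:
            cls.pmus[s] = cls.pmus[s] + shifts[cls.sample_conditions[s]]
        Z, samples = cluster_samples(cls)
        clusters = fcluster(Z, 4, criterion="maxclust")
        by_cond = {}
        for s, c in zip(samples, clusters):
            by_cond.setdefault(cls.sample_conditions[s], set()).add(c)
        assert all(len(v) == 1 for v in by_cond.values())
        assert len({next(iter(v)) for v in by_cond.values()}) == 4

    def test_order_invariance_and_duplicate_merge(self):
        truth = make_expression_truth(n_genes=100, seed=10)
        table, control = simulate_allelic_counts(truth)
        cls = classify_genes(table, control, WT_REF)
        Z1, _ = cluster_samples(cls)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        cls2 = classify_genes(shuffled, control, WT_REF)
        Z2, _ = cluster_samples(cls2)
        np.testing.assert_allclose(Z1, Z2)
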