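"""Burden sums, Metabolic Index Scores, subsetting, genotype combinations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from miscore import (
    DataValidationError,
    PathwayModel,
    burden_sum,
    distinct_genotype_combinations,
    metabolic_index_score,
    subset_variants,
)

from conftest import make_matrix, make_samples, make_variants


class TestSubsetVariants:
    def test_boundary_maf_is_common(self):
        # 1 het among 20 individuals -> MAF exactly 1/40 = 0.025 -> common
        values = np.zeros((20, 1))
        values[0, 0] = 1
        matrix = make_matrix(values, ["MTHFD1_1"])
        variants = make_variants(["MTHFD1_1"])
        samples = make_samples(10, 10)
        subset = subset_variants(
            variants, matrix, samples,
            class_filter="nonsynonymous", maf_bin="common",
        )
        assert subset.members == ("MTHFD1_1",)
        rare = subset_variants(
            variants, matrix, samples,
            class_filter="nonsynonymous", maf_bin="rare",
        )
        assert rare.is_empty

    def test_class_filter_excludes_other_classes(self):
        matrix = make_matrix([[1, 1]], ["G_1", "G_2"], sample_ids=["S000"])
        variants = make_variants(
            ["G_1", "G_2"], classes=["synonymous", "nonsynonymous"]
        )
        samples = pd.DataFrame(
            {"status": ["case"], "stratum": ["Hispanic"]}, index=["S000"]
        )
        subset = subset_variants(
            variants, matrix, samples, class_filter="nonsynonymous"
        )
        assert subset.members == ("G_2",)

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(17)
        m = 30
        ids = [f"G{j}_1" for j in range(m)]
        values = rng.binomial(2, rng.uniform(0.005, 0.2, m), size=(60, m)).astype(float)
        classes = rng.choice(["nonsynonymous", "non_coding"], m).tolist()
        matrix = make_matrix(values, ids)
        variants = make_variants(ids, classes=classes)
        samples = make_samples(30, 30)
        subset = subset_variants(
            variants, matrix, samples, class_filter="nonsynonymous", maf_bin="rare"
        )
        expected = []
        for j, vid in enumerate(ids):
            maf = values[:, j].sum() / (2 * 60)
            if classes[j] == "nonsynonymous" and maf < 0.025:
                expected.append(vid)
        assert list(subset.members) == expected


class TestBurdenSum:
    def test_heterozygote_counts_one(self, toy_cohort):
        matrix, variants, samples = toy_cohort
        subset = subset_variants(variants, matrix, samples)
        burden = burden_sum(matrix, subset)
        assert burden["S001"] == 1.0  # single het
        assert burden["S007"] == 0.0  # all major homozygote

    def test_homozygote_counts_two(self, toy_cohort):
        matrix, variants, samples = toy_cohort
        burden = burden_sum(matrix, ["GOODGENE_1"])
        assert burden["S000"] == 2.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(23)
        values = rng.integers(0, 3, size=(50, 200)).astype(float)
        matrix = make_matrix(values, [f"G{j}_1" for j in range(200)])
        burden = burden_sum(matrix, list(matrix.columns))
        for i in range(0, 50, 7):
            total = 0.0
            for j in range(200):
                total += values[i, j]
            assert burden.iloc[i] == total

    def test_missing_requires_explicit_policy(self):
        matrix = make_matrix([[1, np.nan]], ["G_1", "G_2"], sample_ids=["S000"])
        with pytest.raises(DataValidationError, match="complete_case"):
            burden_sum(matrix, ["G_1", "G_2"])
        assert burden_sum(matrix, ["G_1", "G_2"], complete_case=True)["S000"] == 1.0

    def test_additive_over_disjoint_subsets(self, toy_cohort):
        matrix, variants, samples = toy_cohort
        left = burden_sum(matrix, ["GOODGENE_1", "GOODGENE_2"])
        right = burden_sum(matrix, ["BADGENE_1", "BADGENE_2"])
        both = burden_sum(matrix, list(matrix.columns))
        pd.testing.assert_series_equal(left + right, both, check_names=False)


class TestMetabolicIndexScore:
    def test_homozygote_in_beneficial_gene_scores_plus_two(
        self, one_gene_model, toy_cohort
    ):
        matrix, variants, _ = toy_cohort
        mis = metabolic_index_score(
            matrix, list(matrix.columns), variants, one_gene_model, "purine"
        )
        assert mis["S000"] == 2.0

    def test_heterozygote_in_competing_gene_scores_minus_one(
        self, one_gene_model, toy_cohort
    ):
        matrix, variants, _ = toy_cohort
        mis = metabolic_index_score(
            matrix, list(matrix.columns), variants, one_gene_model, "purine"
        )
        assert mis["S002"] == -1.0

    def test_mixed_genotypes_sum_signed(self, one_gene_model, toy_cohort):
        # het in + gene (+1) and minor homozygote in - gene (-2) -> -1
        matrix, variants, _ = toy_cohort
        mis = metabolic_index_score(
            matrix, list(matrix.columns), variants, one_gene_model, "purine"
        )
        assert mis["S006"] == -1.0

    def test_unsigned_gene_contributes_zero(self, one_gene_model):
        ids = ["GOODGENE_1", "FOLH1_1"]
        matrix = make_matrix([[1, 2]], ids, sample_ids=["S000"])
        variants = make_variants(ids)
        mis = metabolic_index_score(
            matrix, ids, variants, one_gene_model, "purine"
        )
        assert mis["S000"] == 1.0

    def test_unknown_metabolite_rejected(self, one_gene_model, toy_cohort):
        matrix, variants, _ = toy_cohort
        with pytest.raises(KeyError):
            metabolic_index_score(
                matrix, list(matrix.columns), variants, one_gene_model, "lipids"
            )

    def test_compartment_filter_restricts_genes(self):
        # the cytoplasmic purine module: ALDH1L1(-), MTHFD1(+), ATIC(+), GART(+)
        model = PathwayModel(
            signs={"purine": {
                "ALDH1L1": -1, "MTHFD1": 1, "ATIC": 1, "GART": 1, "MTHFD2": 1,
            }},
            compartments={
                "ALDH1L1": "cytoplasmic", "MTHFD1": "cytoplasmic",
                "ATIC": "cytoplasmic", "GART": "cytoplasmic",
                "MTHFD2": "mitochondrial",
            },
        )
        ids = ["ALDH1L1_1", "MTHFD1_1", "ATIC_1", "GART_1", "MTHFD2_1"]
        matrix = make_matrix([[1, 1, 0, 2, 2]], ids, sample_ids=["S000"])
        variants = make_variants(ids)
        full = metabolic_index_score(matrix, ids, variants, model, "purine")
        cyto = metabolic_index_score(
            matrix, ids, variants, model, "purine",
            compartment_filter="cytoplasmic",
        )
        assert full["S000"] == -1 + 1 + 0 + 2 + 2
        assert cyto["S000"] == -1 + 1 + 0 + 2

    def test_sign_antisymmetry_and_decomposition(self, one_gene_model, toy_cohort):
        matrix, variants, _ = toy_cohort
        ids = list(matrix.columns)
        mis = metabolic_index_score(matrix, ids, variants, one_gene_model, "purine")
        negated = metabolic_index_score(
            matrix, ids, variants, one_gene_model.negated(), "purine"
        )
        pd.testing.assert_series_equal(mis, -negated, check_names=False)
        plus = burden_sum(matrix, ["GOODGENE_1", "GOODGENE_2"])
        minus = burden_sum(matrix, ["BADGENE_1", "BADGENE_2"])
        pd.testing.assert_series_equal(mis, plus - minus, check_names=False)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.data(),
        n=st.integers(2, 12),
        m=st.integers(1, 8),
    )
    def test_signed_sum_properties_hold_generally(self, data, n, m):
        """Antisymmetry, decomposition, bound, and the all-positive case."""
        dosages = data.draw(
            st.lists(
                st.lists(st.integers(0, 2), min_size=m, max_size=m),
                min_size=n, max_size=n,
            )
        )
        signs = data.draw(st.lists(st.sampled_from([1, -1]), min_size=m, max_size=m))
        ids = [f"GENE{j}_1" for j in range(m)]
        matrix = make_matrix(np.array(dosages, float), ids)
        variants = make_variants(ids)
        model = PathwayModel(
            signs={"x": {f"GENE{j}": signs[j] for j in range(m)}},
            compartments={f"GENE{j}": "cytoplasmic" for j in range(m)},
        )
        mis = metabolic_index_score(matrix, ids, variants, model, "x")
        neg = metabolic_index_score(matrix, ids, variants, model.negated(), "x")
        assert (mis == -neg).all()
        plus_ids = [ids[j] for j in range(m) if signs[j] > 0]
        minus_ids = [ids[j] for j in range(m) if signs[j] < 0]
        expected = burden_sum(matrix, plus_ids) - burden_sum(matrix, minus_ids)
        assert (mis == expected).all()
        assert (mis.abs() <= 2 * m).all()
        assert (mis == mis.round()).all()
        all_plus = PathwayModel(
            signs={"x": {f"GENE{j}": 1 for j in range(m)}},
            compartments={f"GENE{j}": "cytoplasmic" for j in range(m)},
        )
        assert (
            metabolic_index_score(matrix, ids, variants, all_plus, "x")
            == burden_sum(matrix, ids)
        ).all()


class TestDistinctCombinations:
    def test_identical_rows_count_once(self):
        matrix = make_matrix(np.ones((6, 3)))
        assert distinct_genotype_combinations(matrix, list(matrix.columns)) == 1

    def test_distinct_rows_count_fully(self):
        values = np.array([[0, 0], [0, 1], [1, 0], [2, 2]], float)
        matrix = make_matrix(values)
        assert distinct_genotype_combinations(matrix, list(matrix.columns)) == 4

    def test_matches_set_oracle(self):
        rng = np.random.default_rng(31)
        values = rng.integers(0, 3, size=(40, 9)).astype(float)
        matrix = make_matrix(values, [f"G{j}_1" for j in range(9)])
        expected = len({tuple(row) for row in values})
        assert distinct_genotype_combinations(matrix, list(matrix.columns)) == expected

    def test_sample_filter_restricts_rows(self):
        values = np.array([[0, 0], [0, 0], [1, 1]], float)
        matrix = make_matrix(values)
        count = distinct_genotype_combinations(
            matrix, list(matrix.columns), sample_filter=["S000", "S001"]
        )
        assert count == 1
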