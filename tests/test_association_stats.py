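"""Two-sample statistics, permutation p-values, max(T), logistic and 2x2 ORs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from miscore import (
    DataValidationError,
    dichotomized_or,
    maxt_adjust,
    permutation_pvalue,
    single_variant_assoc,
    two_sample_stat,
)


class TestTwoSampleStat:
    def test_equal_distributions_give_zero_ks(self):
        scores = np.array([1, 2, 3, 1, 2, 3], float)
        labels = ["case"] * 3 + ["control"] * 3
        assert two_sample_stat(scores, labels, "ks") == 0.0

    def test_complete_separation_gives_zero_u(self):
        scores = np.array([0, 1, 2, 10, 11, 12], float)
        labels = ["case"] * 3 + ["control"] * 3
        assert two_sample_stat(scores, labels, "mannwhitney") == 0.0

    def test_welch_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0])
        scores = np.concatenate([x, y])
        labels = ["case"] * 4 + ["control"] * 3
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        expected = (mx - my) / math.sqrt(vx / 4 + vy / 3)
        assert two_sample_stat(scores, labels, "t") == pytest.approx(expected)

    def test_zero_variance_t_directs_to_alternatives(self):
        scores = np.array([1, 1, 1, 1], float)
        labels = ["case", "case", "control", "control"]
        with pytest.raises(DataValidationError, match="mannwhitney"):
            two_sample_stat(scores, labels, "t")


class TestPermutationPvalue:
    def test_exhaustive_enumeration_exact(self):
        scores = np.array([10, 11, 12, 0, 1, 2], float)
        labels = ["case"] * 3 + ["control"] * 3
        result = permutation_pvalue(scores, labels, method="t")
        assert result.exhaustive
        assert result.n_permutations == 20
        assert result.p_value == pytest.approx(2 / 20)

    def test_degenerate_scores_give_p_one(self):
        result = permutation_pvalue(
            np.ones(8), ["case"] * 4 + ["control"] * 4, method="t"
        )
        assert result.p_value == 1.0
        assert result.degenerate

    def test_montecarlo_agrees_with_exhaustive(self):
        scores = np.array([3, 9, 7, 1, 4, 2], float)
        labels = ["case"] * 3 + ["control"] * 3
        exact = permutation_pvalue(scores, labels, method="t", mode="exhaustive")
        mc = permutation_pvalue(
            scores, labels, method="t", mode="montecarlo",
            n_permutations=4000, seed=7,
        )
        sd = math.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(mc.p_value - exact.p_value) < 2 * sd + 1 / 4000

    def test_joint_relabeling_leaves_exact_p_unchanged(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=10)
        labels = np.array(["case"] * 4 + ["control"] * 6)
        base = permutation_pvalue(scores, labels, method="t", mode="exhaustive")
        perm = rng.permutation(10)
        shuffled = permutation_pvalue(
            scores[perm], labels[perm], method="t", mode="exhaustive"
        )
        assert shuffled.p_value == pytest.approx(base.p_value)

    def test_stratified_permutation_preserves_ratios(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        strata = np.array(["A"] * 30 + ["B"] * 10)
        labels = np.array(
            ["case"] * 10 + ["control"] * 20 + ["case"] * 8 + ["control"] * 2
        )
        result = permutation_pvalue(
            scores, labels, method="t", strata=strata,
            n_permutations=500, seed=2, mode="montecarlo",
        )
        assert 0 < result.p_value <= 1

    def test_add_one_estimator_never_zero(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(5, 1, 20), rng.normal(0, 1, 20)])
        labels = ["case"] * 20 + ["control"] * 20
        result = permutation_pvalue(
            scores, labels, method="t", n_permutations=200, seed=1,
            mode="montecarlo",
        )
        assert result.p_value == pytest.approx(1 / 201)


def brute_force_maxt(X, case):
    """Enumeration oracle: Welch t per hypothesis over all label placements."""
    n = X.shape[1]
    k = int(case.sum())
    obs = np.array([
        abs(sps.ttest_ind(row[case], row[~case], equal_var=False).statistic)
        for row in X
    ])
    maxima, per_hyp = [], []
    for combo in itertools.combinations(range(n), k):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        stats = np.array([
            abs(sps.ttest_ind(row[mask], row[~mask], equal_var=False).statistic)
            for row in X
        ])
        maxima.append(stats.max())
        per_hyp.append(stats)
    maxima = np.array(maxima)
    per_hyp = np.array(per_hyp)
    B = len(maxima)
    raw = [(per_hyp[:, h] >= obs[h] - 1e-12).sum() / B for h in range(X.shape[0])]
    adj = [(maxima >= obs[h] - 1e-12).sum() / B for h in range(X.shape[0])]
    return np.array(raw), np.array(adj)


class TestMaxT:
    def test_single_hypothesis_adjusted_equals_raw(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame([rng.normal(size=12)], index=["h1"])
        labels = ["case"] * 6 + ["control"] * 6
        result = maxt_adjust(X, labels, method="t", mode="exhaustive")
        assert result.adjusted_p["h1"] == pytest.approx(result.raw_p["h1"])

    def test_duplicate_hypotheses_share_p(self):
        rng = np.random.default_rng(17)
        row = rng.normal(size=12)
        X = pd.DataFrame([row, row], index=["h1", "h2"])
        labels = ["case"] * 6 + ["control"] * 6
        result = maxt_adjust(X, labels, method="t", mode="exhaustive")
        assert result.adjusted_p["h1"] == result.adjusted_p["h2"]
        assert result.adjusted_p["h1"] == pytest.approx(result.raw_p["h1"])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(3, 10))
        case = np.array([True] * 5 + [False] * 5)
        labels = np.where(case, "case", "control")
        result = maxt_adjust(
            pd.DataFrame(X, index=["h1", "h2", "h3"]), labels,
            method="t", mode="exhaustive",
        )
        raw, adj = brute_force_maxt(X, case)
        np.testing.assert_allclose(result.raw_p.to_numpy(), raw)
        np.testing.assert_allclose(result.adjusted_p.to_numpy(), adj)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.normal(size=(6, 30)))
        labels = ["case"] * 15 + ["control"] * 15
        result = maxt_adjust(
            X, labels, method="t", n_permutations=300, seed=3, mode="montecarlo"
        )
        assert (result.adjusted_p >= result.raw_p - 1e-12).all()

    def test_degenerate_row_scores_zero(self):
        rng = np.random.default_rng(29)
        X = pd.DataFrame(
            [np.ones(10), rng.normal(size=10)], index=["flat", "noise"]
        )
        labels = ["case"] * 5 + ["control"] * 5
        result = maxt_adjust(X, labels, method="t", mode="exhaustive")
        assert result.table.loc["flat", "observed"] == 0.0
        assert result.adjusted_p["flat"] == 1.0


class TestSingleVariantAssoc:
    def test_null_dosage_or_near_one(self):
        rng = np.random.default_rng(31)
        dosage = rng.binomial(2, 0.3, size=2000)
        labels = np.where(rng.random(2000) < 0.5, "case", "control")
        result = single_variant_assoc(dosage, labels)
        assert result.fit == "ml"
        assert abs(math.log(result.odds_ratio)) < 0.3

    def test_recovers_simulated_log_or(self):
        # per-allele log-OR 0.5; Wald CI should cover in ~95% of replicates
        rng = np.random.default_rng(37)
        covered = 0
        for _ in range(30):
            dosage = rng.binomial(2, 0.3, size=5000)
            p = 1 / (1 + np.exp(-(-0.5 + 0.5 * dosage)))
            labels = np.where(rng.random(5000) < p, "case", "control")
            result = single_variant_assoc(dosage, labels)
            if result.ci_low <= math.exp(0.5) <= result.ci_high:
                covered += 1
        assert covered >= 24

    def test_stratum_adjustment_accepted(self):
        rng = np.random.default_rng(41)
        dosage = rng.binomial(2, 0.2, 400)
        strata = rng.choice(["Hispanic", "White"], 400)
        labels = np.where(rng.random(400) < 0.5, "case", "control")
        result = single_variant_assoc(dosage, labels, stratum_covariate=strata)
        assert np.isfinite(result.odds_ratio)

    def test_separation_falls_back_to_firth(self):
        dosage = np.zeros(60)
        dosage[0] = 1.0  # the lone carrier is a case -> ML separates
        labels = np.array(["control"] * 60)
        labels[[0, 1, 2, 3, 4]] = "case"
        result = single_variant_assoc(dosage, labels)
        assert result.fit == "firth"
        assert np.isfinite(result.odds_ratio)
        assert result.ci_low < result.odds_ratio < result.ci_high

    def test_monomorphic_flagged(self):
        result = single_variant_assoc(
            np.zeros(10), ["case"] * 5 + ["control"] * 5
        )
        assert result.fit == "monomorphic"
        assert not result.estimable


class TestDichotomizedOr:
    def test_null_table(self):
        scores = np.array([1] * 20 + [0] * 20, float)
        labels = (["case"] * 10 + ["control"] * 10) * 2
        result = dichotomized_or(scores, labels, rule=("fixed_cut", 0.5))
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.ci_low < 1.0 < result.ci_high

    def test_closed_form_or_and_woolf_ci(self):
        # cases: 5 above / 20 below; controls: 20 above / 5 below
        scores = np.array([1.0] * 5 + [0.0] * 20 + [1.0] * 20 + [0.0] * 5)
        labels = ["case"] * 25 + ["control"] * 25
        result = dichotomized_or(scores, labels, rule=("fixed_cut", 0.5))
        assert result.odds_ratio == pytest.approx((5 * 5) / (20 * 20))
        se = math.sqrt(1 / 5 + 1 / 20 + 1 / 20 + 1 / 5)
        assert result.ci_low == pytest.approx(0.0625 * math.exp(-1.96 * se), rel=1e-3)
        assert result.ci_high == pytest.approx(0.0625 * math.exp(1.96 * se), rel=1e-3)
        assert not result.haldane_corrected

    def test_control_median_rule_ties_below(self):
        scores = np.array([0, 1, 3, 3, 1, 2, 2, 3], float)
        labels = ["case"] * 4 + ["control"] * 4
        result = dichotomized_or(scores, labels, rule="median_of_controls")
        assert result.cutpoint == 2.0
        # above arm is strictly > 2: cases {3,3}, controls {3}
        assert result.table.tolist() == [[2, 1], [2, 3]]

    def test_fixed_cut_zero_excludes_ties_by_default(self):
        scores = np.array([-1, 0, 1, 2, -2, 0, 1, -1], float)
        labels = ["case"] * 4 + ["control"] * 4
        result = dichotomized_or(scores, labels, rule=("fixed_cut", 0))
        assert result.n_excluded == 2

    def test_extremes_rule_drops_middle(self):
        scores = np.array([-2, 0, 5, 6, -1, 1, 4, -3], float)
        labels = ["case"] * 4 + ["control"] * 4
        result = dichotomized_or(scores, labels, rule=("extremes", -1, 4))
        # kept: -2, 5, 6, -1 (cases), 4, -3 (controls); 0 and 1 dropped
        assert result.n_excluded == 2
        assert result.table.sum() == 6

    def test_zero_cell_triggers_haldane(self):
        # cases: 2 above / 2 below; controls: 0 above / 4 below
        scores = np.array([1, 1, 0, 0, 0, 0, 0, 0], float)
        labels = ["case"] * 4 + ["control"] * 4
        result = dichotomized_or(scores, labels, rule=("fixed_cut", 0.5))
        assert result.haldane_corrected
        assert np.isfinite(result.odds_ratio) and result.odds_ratio > 0
        expected = (2.5 * 4.5) / (0.5 * 2.5)
        assert result.odds_ratio == pytest.approx(expected)

    def test_empty_arm_is_error(self):
        scores = np.ones(8)
        labels = ["case"] * 4 + ["control"] * 4
        with pytest.raises(DataValidationError):
            dichotomized_or(scores, labels, rule=("fixed_cut", 0.5))
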