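"""Clinical statistics: QC, ROC/Youden, proportions, stepwise logistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from stempcr.diagnostics import (
    cluster_samples,
    combine_or_rule,
    group_difference_test,
    logistic_forward_conditional,
    marker_correlation,
    qc_filter,
    relative_level,
    roc_auc,
    sens_spec,
    youden_cutoff,
)


def _cohort(ct_pos, ct_neg, marker="M"):
    rows = [{"sample_id": f"p{i}", "class": "CRC", marker: v} for i, v in enumerate(ct_pos)]
    rows += [{"sample_id": f"n{i}", "class": "normal", marker: v} for i, v in enumerate(ct_neg)]
    df = pd.DataFrame(rows)
    df["ACTB_Ct"] = 20.0
    return df


class TestQc:
    def test_boundary_retained_above_excluded(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "class": "normal",
                           "ACTB_Ct": [24.5, 24.6]})
        kept, dropped = qc_filter(df)
        assert list(kept["sample_id"]) == ["a"]
        assert list(dropped["sample_id"]) == ["b"]
        assert dropped["reason"].iloc[0] == "insufficient_dna"

    def test_toy_table_counts_and_missing_reason(self):
        df = pd.DataFrame({"sample_id": list("abcde"), "class": "normal",
                           "ACTB_Ct": [20.0, 24.5, 24.6, 30.0, np.nan]})
        kept, dropped = qc_filter(df)
        assert len(kept) == 2 and len(dropped) == 3
        assert dropped.set_index("sample_id").loc["e", "reason"] == "missing_reference"


class TestRelativeLevel:
    @pytest.mark.parametrize("marker,actb,expected", [
        (24.0, 24.0, 1.0),
        (25.0, 24.0, 0.5),
        (30.0, 24.0, 0.015625),
    ])
    def test_two_power_minus_delta_ct(self, marker, actb, expected):
        assert relative_level(marker, actb) == pytest.approx(expected)


class TestGroupDifference:
    def test_identical_groups_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = group_difference_test({"a": vals, "b": list(vals)})
        assert out["test"] == "mann-whitney" or out["p_value"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_shifted_normals_use_t_branch(self):
        rng = np.random.default_rng(0)
        out = group_difference_test(
            {"a": rng.normal(0, 1, 30), "b": rng.normal(3, 1, 30)}
        )
        assert out["test"] == "t-test" and out["p_value"] < 1e-3

    def test_heavy_tailed_data_use_mann_whitney(self):
        rng = np.random.default_rng(1)
        a = np.exp(rng.normal(0, 1.5, 100))
        b = np.exp(rng.normal(0.5, 1.5, 100))
        assert group_difference_test({"a": a, "b": b})["test"] == "mann-whitney"

    def test_constant_group_falls_to_mann_whitney(self):
        out = group_difference_test({"a": [2.0] * 5, "b": [1.0, 2.0, 3.0, 2.5, 1.5]})
        assert out["test"] == "mann-whitney"


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc(_cohort([30, 32], [35, 38]), "M")
        assert roc.auc == 1.0
        assert youden_cutoff(roc)["youden_j"] == 1.0

    def test_three_of_four_pairs_concordant(self):
        roc = roc_auc(_cohort([30, 36], [32, 38]), "M")
        assert roc.auc == pytest.approx(0.75)

    def test_youden_tie_breaks_toward_sensitivity(self):
        roc = roc_auc(_cohort([30, 36], [32, 38]), "M")
        yj = youden_cutoff(roc)
        assert yj["youden_j"] == pytest.approx(0.5)
        assert yj["sensitivity"] == 1.0 and yj["specificity"] == 0.5
        assert yj["cutoff"] == pytest.approx(36.0)

    def test_identical_scores_zero_j(self):
        roc = roc_auc(_cohort([30, 30], [30, 30]), "M")
        assert youden_cutoff(roc)["youden_j"] == pytest.approx(0.0)

    def test_empty_class_raises(self):
        df = _cohort([30.0], [])
        with pytest.raises(ValueError, match="empty class"):
            roc_auc(df, "M")

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos = rng.normal(30, 3, rng.integers(3, 20))
            neg = rng.normal(33, 3, rng.integers(3, 20))
            roc = roc_auc(_cohort(pos, neg), "M")
            conc = np.mean([
                1.0 if p < n else 0.5 if p == n else 0.0 for p in pos for n in neg
            ])
            assert roc.auc == pytest.approx(conc, abs=1e-12)

    def test_permutation_null_centers_on_half(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(30, 3, 40)
        aucs = []
        for _ in range(1000):
            lab = rng.permutation([True] * 20 + [False] * 20)
            aucs.append(roc_auc(_cohort(vals[lab], vals[~lab]), "M").auc)
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se


class TestSensSpec:
    def test_all_correct(self):
        out = sens_spec(["CRC", "normal"], ["CRC", "normal"], "CRC")
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_printed_worked_ratios(self):
        out = sens_spec(["CRC"] * 107 + ["normal"] * 8, ["CRC"] * 115, "CRC")
        assert out["sensitivity"] == pytest.approx(107 / 115)
        assert round(100 * out["sensitivity"], 1) == 93.0
        out = sens_spec(["CRC"] * 8 + ["normal"], ["CRC"] * 9, "CRC")
        assert out["sensitivity"] == pytest.approx(8 / 9)

    def test_zero_positives_not_applicable(self):
        out = sens_spec(["normal"] * 5, ["normal"] * 5, "CRC")
        assert out["sensitivity"] is None and out["specificity"] == 1.0

    def test_clopper_pearson_interval_matches_beta_quantiles(self):
        out = sens_spec(["CRC"] * 107 + ["normal"] * 8, ["CRC"] * 115, "CRC")
        lo, hi = out["sensitivity_ci"]
        assert lo == pytest.approx(stats.beta.ppf(0.025, 107, 9))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 108, 8))


class TestOrRule:
    def test_any_positive_member_positive_union(self):
        calls = {"a": [True, False, False], "b": [False, False, True]}
        assert list(combine_or_rule(calls, ["a", "b"])) == [True, False, True]

    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                    min_size=4, max_size=40))
    def test_union_monotonicity(self, rows):
        labels = np.array([r[0] for r in rows])
        if labels.all() or not labels.any():
            return
        calls = {"a": np.array([r[1] for r in rows]), "b": np.array([r[2] for r in rows])}
        union = combine_or_rule(calls, ["a", "b"])

        def rates(c):
            sens = (c & labels).sum() / labels.sum()
            spec = (~c & ~labels).sum() / (~labels).sum()
            return sens, spec

        su, pu = rates(union)
        for m in ("a", "b"):
            sm, pm = rates(calls[m])
            assert su >= sm and pu <= pm


class TestCorrelationAndClustering:
    def test_self_and_monotone_transform_are_unity(self):
        rng = np.random.default_rng(3)
        ct = rng.normal(30, 2, 20)
        df = pd.DataFrame({"a": ct, "b": np.exp(ct / 10)})
        corr = marker_correlation(df, ["a", "b"])
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_table_matches_rank_formula(self):
        # one discordant pair among 5 samples
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.0, 2.0, 3.0, 5.0, 4.0]
        corr = marker_correlation(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        d2 = sum((ra - rb) ** 2 for ra, rb in zip([1, 2, 3, 4, 5], [1, 2, 3, 5, 4]))
        expected = 1 - 6 * d2 / (5 * 24)
        assert corr.loc["a", "b"] == pytest.approx(expected)

    def test_constant_marker_flagged_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr = marker_correlation(df, ["a", "b"])
        assert corr.loc["a", "b"] == 0.0
        assert corr.attrs["constant_markers"] == ["b"]

    def test_duplicated_samples_merge_first_at_zero(self):
        df = pd.DataFrame({"m1": [1.0, 1.0, 9.0], "m2": [2.0, 2.0, 8.0]})
        out = cluster_samples(df, ["m1", "m2"])
        assert out["linkage"][0, 2] == 0.0
        assert set(out["linkage"][0, :2]) == {0, 1}

    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "m1": np.r_[rng.normal(30, 0.5, 10), rng.normal(40, 0.5, 10)],
            "m2": np.r_[rng.normal(28, 0.5, 10), rng.normal(44, 0.5, 10)],
        })
        out = cluster_samples(df, ["m1", "m2"])
        two = out["two_group"]
        assert len(set(two[:10])) == 1 and len(set(two[10:])) == 1
        assert two[0] != two[-1]

    def test_row_permutation_preserves_partition(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"m1": rng.normal(30, 3, 12), "m2": rng.normal(30, 3, 12)})
        out1 = cluster_samples(df, ["m1", "m2"])
        perm = rng.permutation(12)
        out2 = cluster_samples(df.iloc[perm].reset_index(drop=True), ["m1", "m2"])
        assert np.allclose(sorted(out1["linkage"][:, 2]), sorted(out2["linkage"][:, 2]))
        part1 = out1["two_group"]
        part2_back = np.empty(12, dtype=int)
        part2_back[perm] = out2["two_group"]
        same = (part1 == part2_back).all() or (part1 == 3 - part2_back).all()
        assert same


class TestForwardConditional:
    def _cohort_with(self, informative_shift, n=60, n_null=4, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(2 * n)],
                           "class": ["CRC"] * n + ["normal"] * n})
        df["good"] = np.r_[rng.normal(30 - informative_shift, 2, n), rng.normal(30, 2, n)]
        for i in range(n_null):
            df[f"null{i}"] = rng.normal(32, 2, 2 * n)
        df["ACTB_Ct"] = 20.0
        return df

    def test_informative_marker_selected_alone(self):
        df = self._cohort_with(3.0, seed=2)
        model = logistic_forward_conditional(df, ["good"] + [f"null{i}" for i in range(4)])
        assert model.markers == ["good"]
        assert model.entry_pvalues["good"] < 0.05

    def test_all_null_mostly_intercept_only(self):
        # two null candidates at p_enter 0.05: P(no entry) ~ 0.95^2 ~ 0.90
        empty = 0
        for seed in range(100):
            df = self._cohort_with(0.0, n=30, n_null=1, seed=seed)
            model = logistic_forward_conditional(df, ["good", "null0"])
            empty += not model.markers
        assert empty >= 90

    def test_frozen_refit_reproduces_coefficients(self):
        df = self._cohort_with(2.0, seed=5)
        m1 = logistic_forward_conditional(df, ["good", "null0"])
        m2 = logistic_forward_conditional(df, ["good", "null0"])
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-8)

    def test_perfect_separation_flagged_not_fatal(self):
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(20)],
                           "class": ["CRC"] * 10 + ["normal"] * 10,
                           "sep": list(np.linspace(20, 25, 10)) + list(np.linspace(35, 40, 10)),
                           "ACTB_Ct": 20.0})
        model = logistic_forward_conditional(df, ["sep"])
        assert model.markers == ["sep"]
        assert model.separation_flag
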