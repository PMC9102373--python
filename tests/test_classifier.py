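import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ocumir.classifier import (
    INDETERMINATE,
    MarkerRule,
    apply_rule,
    classify_cohort,
    combined_and_classify,
    evaluate,
    roc_curve,
    threshold_at_sensitivity,
)
from ocumir.simulate import MarkerSimConfig, simulate_marker_expression

from oracles import best_rule_threshold

# The two published decision rules.
RULE_196B = MarkerRule("miR-196b-5p", 1172.258, "low", "OSC")
RULE_107 = MarkerRule("miR-107", 365.4, "high", "OSC")


class TestRocCurve:
    def test_perfect_separation(self):
        values = [1.0, 2.0, 3.0, 4.0]
        labels = ["OSC", "OSC", "SCCC", "SCCC"]
        roc = roc_curve(values, labels, "OSC", "low")
        assert roc.auc == 1.0
        assert roc.sensitivity.max() == 1.0 and roc.specificity.max() == 1.0

    def test_interleaved_pairs_enumerate_to_three_quarters(self):
        # Positives {1, 3}, negatives {2, 4}: of the 4 (pos, neg) pairs,
        # 3 are ordered correctly under positive-class-low.
        roc = roc_curve([1.0, 3.0, 2.0, 4.0],
                        ["OSC", "OSC", "SCCC", "SCCC"], "OSC", "low")
        assert roc.auc == pytest.approx(0.75)

    def test_complete_ties_give_half(self):
        roc = roc_curve([5.0] * 6, ["OSC"] * 3 + ["SCCC"] * 3, "OSC", "high")
        assert roc.auc == pytest.approx(0.5)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], ["OSC", "OSC"], "OSC", "low")

    @pytest.mark.parametrize("direction", ["low", "high"])
    def test_auc_matches_sklearn(self, direction):
        rng = np.random.default_rng(3)
        values = rng.lognormal(6, 1, 40)
        labels = np.where(rng.random(40) < 0.4, "OSC", "SCCC")
        roc = roc_curve(values, labels, "OSC", direction)
        score = -values if direction == "low" else values
        expected = roc_auc_score(labels == "OSC", score)
        assert roc.auc == pytest.approx(expected)

    def test_auc_consistent_with_mann_whitney_u(self):
        """AUC equals U/(n1*n2) from the rank-sum statistic on the same data."""
        from ocumir.diffexpr import mann_whitney

        rng = np.random.default_rng(8)
        pos = rng.lognormal(7, 0.8, 14)
        neg = rng.lognormal(6, 0.8, 18)
        values = np.concatenate([pos, neg])
        labels = np.array(["OSC"] * 14 + ["SCCC"] * 18)
        roc = roc_curve(values, labels, "OSC", "high")
        u, _ = mann_whitney(pos, neg)
        assert roc.auc == pytest.approx(u / (14 * 18))


class TestThresholdSelection:
    def test_separable_fixture_attains_perfect_rule(self):
        values = np.array([100.0, 120.0, 900.0, 950.0])
        labels = np.array(["OSC", "OSC", "SCCC", "SCCC"])
        rule = threshold_at_sensitivity(
            roc_curve(values, labels, "OSC", "low"), 0.9, marker="m")
        calls = [apply_rule(rule, v, "SCCC") for v in values]
        assert calls == list(labels)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        pos = rng.lognormal(6.0, 0.7, 10)
        neg = rng.lognormal(7.0, 0.7, 10)
        values = np.concatenate([pos, neg])
        labels = np.array(["OSC"] * 10 + ["SCCC"] * 10)
        roc = roc_curve(values, labels, "OSC", "low")
        rule = threshold_at_sensitivity(roc, 0.9, marker="m")
        expected = best_rule_threshold(pos, neg, "low", 0.9, roc.thresholds)
        assert rule.threshold == pytest.approx(expected)

    def test_full_sensitivity_bound_attained(self):
        rng = np.random.default_rng(5)
        pos = rng.lognormal(6, 1, 12)
        neg = rng.lognormal(6.5, 1, 12)
        values = np.concatenate([pos, neg])
        labels = np.array(["OSC"] * 12 + ["SCCC"] * 12)
        rule = threshold_at_sensitivity(
            roc_curve(values, labels, "OSC", "low"), 1.0, marker="m")
        assert all(apply_rule(rule, v, "SCCC") == "OSC" for v in pos)

    def test_bad_min_sensitivity_rejected(self):
        roc = roc_curve([1.0, 2.0], ["OSC", "SCCC"], "OSC", "low")
        with pytest.raises(ValueError):
            threshold_at_sensitivity(roc, 0.0)


class TestRuleSemantics:
    def test_published_directions(self):
        assert apply_rule(RULE_196B, 1000.0, "SCCC") == "OSC"
        assert apply_rule(RULE_196B, 2000.0, "SCCC") == "SCCC"
        assert apply_rule(RULE_107, 500.0, "SCCC") == "OSC"
        assert apply_rule(RULE_107, 100.0, "SCCC") == "SCCC"

    def test_boundaries_are_inclusive_toward_positive(self):
        assert apply_rule(RULE_196B, 1172.258, "SCCC") == "OSC"
        assert apply_rule(RULE_107, 365.4, "SCCC") == "OSC"

    def test_missing_value_is_indeterminate(self):
        assert apply_rule(RULE_196B, float("nan")) == INDETERMINATE

    def test_conjunction_truth_table(self):
        cases = {
            (True, True): "OSC",
            (True, False): "SCCC",
            (False, True): "SCCC",
            (False, False): "SCCC",
        }
        for (call_196b, call_107), expected in cases.items():
            values = {
                "miR-196b-5p": 1000.0 if call_196b else 2000.0,
                "miR-107": 500.0 if call_107 else 100.0,
            }
            assert combined_and_classify([RULE_196B, RULE_107], values,
                                         "SCCC") == expected

    def test_indeterminate_propagates_through_conjunction(self):
        values = {"miR-196b-5p": 1000.0, "miR-107": float("nan")}
        assert combined_and_classify([RULE_196B, RULE_107], values,
                                     "SCCC") == INDETERMINATE

    def test_single_rule_conjunction_equals_apply_rule(self):
        for v in (100.0, 1172.258, 5000.0):
            assert combined_and_classify([RULE_196B], {"miR-196b-5p": v},
                                         "SCCC") == \
                apply_rule(RULE_196B, v, "SCCC")

    def test_absent_marker_rejected(self):
        with pytest.raises(ValueError, match="miR-107"):
            combined_and_classify([RULE_196B, RULE_107],
                                  {"miR-196b-5p": 1000.0})

    def test_invalid_rule_construction_rejected(self):
        with pytest.raises(ValueError):
            MarkerRule("m", -1.0, "low", "OSC")
        with pytest.raises(ValueError):
            MarkerRule("m", 10.0, "sideways", "OSC")


class TestEvaluate:
    def test_published_validation_outcome(self):
        """9/10 positives and 10/12 negatives correct give the reported
        90.0% sensitivity and 83.3% specificity."""
        calls = ["OSC"] * 9 + ["SCCC"] + ["SCCC"] * 10 + ["OSC"] * 2
        truth = ["OSC"] * 10 + ["SCCC"] * 12
        report = evaluate(calls, truth, "OSC")
        assert (report.tp, report.fn, report.tn, report.fp) == (9, 1, 10, 2)
        assert report.sensitivity_pct == 90.0
        assert report.specificity_pct == 83.3

    def test_degenerate_classifiers(self):
        truth = ["OSC"] * 3 + ["SCCC"] * 3
        perfect = evaluate(truth, truth, "OSC")
        assert (perfect.sensitivity_pct, perfect.specificity_pct) == (100.0, 100.0)
        all_pos = evaluate(["OSC"] * 6, truth, "OSC")
        assert (all_pos.sensitivity_pct, all_pos.specificity_pct) == (100.0, 0.0)

    def test_indeterminate_counted_and_excluded(self):
        calls = ["OSC", INDETERMINATE, "SCCC"]
        truth = ["OSC", "OSC", "SCCC"]
        report = evaluate(calls, truth, "OSC")
        assert report.n_indeterminate == 1
        assert (report.tp, report.fn) == (1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["OSC"], ["OSC", "SCCC"], "OSC")


class TestCohortRecovery:
    def test_large_cohort_threshold_generalizes(self):
        """On a large planted cohort, the trained rule meets the requested
        sensitivity in training and transfers to held-out data within a few
        points."""
        train, train_annot = simulate_marker_expression(
            MarkerSimConfig(seed=31, n_per_class={"OSC": 500, "SCCC": 500}))
        test, test_annot = simulate_marker_expression(
            MarkerSimConfig(seed=32, n_per_class={"OSC": 500, "SCCC": 500}))
        labels = train_annot.set_index("sample_id").loc[train.index, "group"]
        test_labels = test_annot.set_index("sample_id").loc[test.index, "group"]
        for marker, direction in (("miR-196b-5p", "low"), ("miR-107", "high")):
            roc = roc_curve(train[marker], labels, "OSC", direction)
            rule = threshold_at_sensitivity(roc, 0.9, marker=marker)
            calls_tr = classify_cohort([rule], train[[marker]], "SCCC")
            calls_te = classify_cohort([rule], test[[marker]], "SCCC")
            sens_tr = evaluate(calls_tr, labels, "OSC").sensitivity
            sens_te = evaluate(calls_te, test_labels, "OSC").sensitivity
            assert sens_tr >= 0.9
            assert abs(sens_tr - sens_te) <= 0.05

    def test_conjunction_monotone_vs_single_rules(self, marker_cohorts):
        (disc, disc_annot), (val, val_annot) = marker_cohorts
        labels = disc_annot.set_index("sample_id").loc[disc.index, "group"]
        rules = []
        for marker, direction in (("miR-196b-5p", "low"), ("miR-107", "high")):
            roc = roc_curve(disc[marker], labels, "OSC", direction)
            rules.append(threshold_at_sensitivity(roc, 0.9, marker=marker))
        val_labels = val_annot.set_index("sample_id").loc[val.index, "group"]
        combined = evaluate(classify_cohort(rules, val, "SCCC"), val_labels,
                            "OSC")
        for rule in rules:
            single = evaluate(classify_cohort([rule], val[[rule.marker]],
                                              "SCCC"), val_labels, "OSC")
            assert combined.specificity >= single.specificity
            assert combined.sensitivity <= single.sensitivity
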