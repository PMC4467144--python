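"""Percentile thresholds, k-of-n flagging and 2x2 evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from etstargets import TumorCohort, ValidationError, gen_tumor_cohort
from etstargets.panel import (
    PanelRule,
    chi2_2x2,
    classify,
    cutoff_scan,
    evaluate,
    evaluate_rule,
    flag_matrix,
    percentile_threshold,
)
from etstargets.synthetic import PlantedTruth

from _oracles import chi2_from_expected


class TestPercentileThreshold:
    def test_hand_computed_linear_interpolation(self):
        values = list(range(1, 9))  # 1..8
        assert percentile_threshold(values, 25) == pytest.approx(2.75)
        assert percentile_threshold(values, 50) == pytest.approx(4.5)

    def test_constant_values(self):
        assert percentile_threshold([3.0, 3.0, 3.0], 25) == 3.0

    def test_needs_two_values(self):
        with pytest.raises(ValidationError):
            percentile_threshold([1.0], 25)


def _cohort_from_values(values_by_gene: dict, stages: list):
    n = len(stages)
    samples = [f"T{i:02d}" for i in range(n)]
    data = pd.DataFrame(values_by_gene, index=samples).T
    data.index.name = "gene_id"
    anno = pd.DataFrame({
        "tissue": ["PCa"] * n,
        "subtype": ["ERG"] * n,
        "pea3_gene": [None] * n,
        "gleason_group": ["low"] * n,
        "stage": stages,
        "age_years": [60.0] * n,
        "psa_ng_ml": [5.0] * n,
    }, index=pd.Index(samples, name="sample_id"))
    from etstargets import ExpressionMatrix
    return TumorCohort(expression=ExpressionMatrix(data), annotations=anno)


class TestFlagMatrix:
    def test_bottom_quarter_flags(self):
        cohort = _cohort_from_values({"G": list(map(float, range(1, 9)))},
                                     ["pT2"] * 4 + ["pT3"] * 4)
        rule = PanelRule(genes=("G",), percentile=25, k=1)
        flags = flag_matrix(cohort, rule)
        flagged = set(flags.index[flags["G"]])
        assert flagged == {"T00", "T01"}  # values 1, 2 < threshold 2.75

    def test_percentile_nesting(self):
        cohort = _cohort_from_values({"G": list(map(float, range(1, 9)))},
                                     ["pT2"] * 4 + ["pT3"] * 4)
        f25 = flag_matrix(cohort, PanelRule(genes=("G",), percentile=25, k=1))
        f50 = flag_matrix(cohort, PanelRule(genes=("G",), percentile=50, k=1))
        assert set(f50.index[f50["G"]]) == {"T00", "T01", "T02", "T03"}
        assert set(f25.index[f25["G"]]) <= set(f50.index[f50["G"]])

    def test_ties_never_overflow_with_strict_inequality(self):
        cohort = _cohort_from_values({"G": [2.0] * 8},
                                     ["pT2"] * 4 + ["pT3"] * 4)
        flags = flag_matrix(cohort, PanelRule(genes=("G",), percentile=25, k=1))
        assert not flags["G"].any()

    def test_missing_panel_gene_named(self, study_cohort):
        with pytest.raises(ValidationError, match="MISSING"):
            flag_matrix(study_cohort,
                        PanelRule(genes=("CCPG1", "MISSING"), percentile=25, k=1))


class TestClassify:
    def test_k_of_n(self):
        flags = pd.DataFrame([[True, True, False], [True, False, False]],
                             index=["a", "b"], columns=["g1", "g2", "g3"])
        assert classify(flags, 2) == {"a"}
        assert classify(flags, 1) == {"a", "b"}

    def test_antitone_in_k(self):
        rng = np.random.default_rng(2)
        flags = pd.DataFrame(rng.random((30, 7)) < 0.4,
                             index=[f"t{i}" for i in range(30)])
        for k in range(1, 7):
            assert classify(flags, k + 1) <= classify(flags, k)

    def test_k_beyond_panel_rejected_at_rule_construction(self):
        with pytest.raises(ValidationError):
            PanelRule(genes=("a", "b"), percentile=25, k=3)


class TestEvaluate:
    def test_closed_form_example(self):
        truth = pd.Series(["pT3"] * 10 + ["pT2"] * 10,
                          index=[f"t{i}" for i in range(20)])
        predicted = frozenset([f"t{i}" for i in range(8)]       # 8 TP
                              + [f"t{i}" for i in range(10, 12)])  # 2 FP
        ev = evaluate(predicted, truth, PanelRule(genes=("g",), k=1))
        assert (ev.tp, ev.fp, ev.fn, ev.tn) == (8, 2, 2, 8)
        assert ev.sensitivity == pytest.approx(0.8)
        assert ev.specificity == pytest.approx(0.8)
        assert ev.ppv == pytest.approx(0.8)
        assert ev.npv == pytest.approx(0.8)
        assert ev.chi2 == pytest.approx(7.2)
        assert ev.p == pytest.approx(stats.chi2.sf(7.2, 1), abs=1e-10)
        assert ev.p == pytest.approx(0.00729, abs=1e-4)

    def test_all_negative_predictions(self):
        truth = pd.Series(["pT3", "pT3", "pT2", "pT2"],
                          index=["a", "b", "c", "d"])
        ev = evaluate(frozenset(), truth, PanelRule(genes=("g",), k=1))
        assert ev.sensitivity == 0.0
        assert ev.ppv is None
        assert ev.npv == pytest.approx(2 / 4)

    def test_chi2_matches_expected_count_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            chi2, p = chi2_2x2(int(tp), int(fp), int(fn), int(tn))
            assert chi2 == pytest.approx(
                chi2_from_expected(tp, fp, fn, tn), rel=1e-10)
            # and against the standard contingency implementation
            ref = stats.chi2_contingency([[tp, fn], [fp, tn]],
                                         correction=False)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_chi2_invariant_under_table_transpositions(self):
        chi2, p = chi2_2x2(8, 3, 5, 11)
        chi2_swapped, p_swapped = chi2_2x2(11, 5, 3, 8)
        assert chi2 == pytest.approx(chi2_swapped)
        assert p == pytest.approx(p_swapped)

    def test_metric_counts_recoverable(self):
        ev = evaluate(
            frozenset(["a"]),
            pd.Series(["pT3", "pT3", "pT2"], index=["a", "b", "c"]),
            PanelRule(genes=("g",), k=1))
        assert round(ev.sensitivity * (ev.tp + ev.fn)) == ev.tp
        assert round(ev.ppv * (ev.tp + ev.fp)) == ev.tp


class TestCutoffScan:
    def test_ranked_by_p_and_study_grid(self, study_cohort):
        evaluations = cutoff_scan(study_cohort)
        assert len(evaluations) == 3
        pvals = [ev.p for ev in evaluations]
        assert pvals == sorted(pvals)
        assert {(ev.rule.percentile, ev.rule.k) for ev in evaluations} == \
            {(10.0, 1), (25.0, 2), (50.0, 4)}

    def test_duplicates_deduplicated_with_warning(self, study_cohort):
        with pytest.warns(UserWarning, match="duplicate"):
            evaluations = cutoff_scan(study_cohort,
                                      grid=((25, 2), (25, 2), (10, 1)))
        assert len(evaluations) == 2

    def test_planted_panel_separates_stages(self, study_cohort):
        ev = [e for e in cutoff_scan(study_cohort)
              if e.rule.percentile == 25.0][0]
        assert ev.p < 0.001
        assert ev.sensitivity >= 0.7 and ev.specificity >= 0.7

    def test_frozen_thresholds_mode(self, study_cohort):
        rule = PanelRule(percentile=25, k=2)
        flags_native = flag_matrix(study_cohort, rule)
        thresholds = {
            g: percentile_threshold(
                study_cohort.expression.data.loc[
                    g, study_cohort.staged_pca_samples()].to_numpy(), 25)
            for g in rule.genes
        }
        flags_frozen = flag_matrix(study_cohort, rule, thresholds=thresholds)
        pd.testing.assert_frame_equal(flags_native, flags_frozen)
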