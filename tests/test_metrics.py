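"""Confusion counting, the metric suite, paired tests and rate helpers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vpptbench import (
    BenchmarkSet,
    ConfusionCounts,
    compute_metrics,
    confusion_counts,
    evaluate_all_tools,
    fold_change,
    mean_row,
    paired_metric_test,
    per_capita_rate,
)
from vpptbench.errors import ConfigError, DataError
from vpptbench.metrics import performance_table
from vpptbench.registry import BENIGN, DELETERIOUS, NO_CALL
from vpptbench.variant_model import VariantKey


def _key(i: int) -> VariantKey:
    return VariantKey("1", i, "A", "G")


def oracle_metrics(tp, fp, tn, fn):
    """Independent loop-free reference implementation of the metric suite."""
    sen = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    fpr = fp / (tn + fp) if tn + fp else None
    fnr = fn / (tp + fn) if tp + fn else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sen, spec, fpr, fnr, mcc


class TestComputeMetrics:
    def test_perfect_classifier(self):
        p = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (p.sensitivity, p.specificity, p.fpr, p.fnr, p.mcc) == (1, 1, 0, 0, 1)
        assert not p.mcc_degenerate

    def test_degenerate_all_positive_predictor(self):
        p = compute_metrics(ConfusionCounts(tp=4, fp=6, tn=0, fn=0))
        assert p.mcc == 0.0 and p.mcc_degenerate
        assert p.specificity == 0.0 and p.sensitivity == 1.0

    def test_hand_evaluated_mcc(self):
        # (3*5 - 1*1) / sqrt(4 * 4 * 6 * 6) = 14/24
        p = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert p.mcc == pytest.approx(14 / math.sqrt(576))
        assert p.mcc == pytest.approx(0.5833, abs=1e-4)

    def test_rates_undefined_when_one_class_absent(self):
        p = compute_metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=1))
        assert p.specificity is None and p.fpr is None
        assert p.sensitivity == 0.75

    def test_agrees_with_oracle_over_all_small_matrices(self):
        """Exhaustive check over all 6^4 confusion matrices with cells <= 5."""
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            p = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            sen, spec, fpr, fnr, mcc = oracle_metrics(tp, fp, tn, fn)
            assert p.sensitivity == sen and p.specificity == spec
            assert p.fpr == fpr and p.fnr == fnr
            assert p.mcc == pytest.approx(mcc)
            # complementarity identities whenever defined
            if sen is not None:
                assert p.sensitivity + p.fnr == pytest.approx(1.0)
            if spec is not None:
                assert p.specificity + p.fpr == pytest.approx(1.0)

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_mcc_symmetries(self, tp, fp, tn, fn):
        """MCC is invariant under TP<->TN,FP<->FN and negates under label swap."""
        base = compute_metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
        swapped = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)).mcc
        inverted = compute_metrics(ConfusionCounts(tp=fp, fp=tp, tn=fn, fn=tn)).mcc
        assert base == pytest.approx(swapped)
        assert base == pytest.approx(-inverted)


class TestConfusionCounts:
    def test_no_call_excluded(self):
        bench = BenchmarkSet("merged", "T", {_key(i) for i in range(5)},
                             {_key(i) for i in range(10, 15)})
        calls = {k: DELETERIOUS for k in bench.positives}
        calls.update({k: BENIGN for k in bench.negatives})
        calls[_key(0)] = NO_CALL
        calls[_key(1)] = NO_CALL
        c = confusion_counts(calls, bench)
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 0, 5, 0)

    def test_missing_benchmark_key_raises(self):
        bench = BenchmarkSet("merged", "T", {_key(1)}, {_key(2)})
        with pytest.raises(DataError, match="absent"):
            confusion_counts({_key(1): DELETERIOUS}, bench)

    def test_random_fixture_matches_brute_force_tally(self):
        rng = np.random.default_rng(42)
        pos = {_key(i) for i in range(10)}
        neg = {_key(i) for i in range(10, 20)}
        bench = BenchmarkSet("merged", "T", pos, neg)
        calls = {k: int(rng.integers(-1, 2)) for k in pos | neg}
        c = confusion_counts(calls, bench)
        # independent loop-and-count oracle
        tp = sum(calls[k] == 1 for k in pos)
        fn = sum(calls[k] == 0 for k in pos)
        fp = sum(calls[k] == 1 for k in neg)
        tn = sum(calls[k] == 0 for k in neg)
        assert (c.tp, c.fn, c.fp, c.tn) == (tp, fn, fp, tn)


class TestEvaluateAllTools:
    def _bench_and_calls(self):
        pos = {_key(i) for i in range(8)}
        neg = {_key(i) for i in range(10, 22)}
        bench = BenchmarkSet("merged", "T", pos, neg)
        keys = sorted(pos | neg)
        rng = np.random.default_rng(0)
        data = rng.integers(-1, 2, size=(len(keys), 3)).astype("int8")
        data[:, 2] = data[:, 1]  # toolC duplicates toolB
        calls = pd.DataFrame(data, index=keys, columns=["toolA", "toolB", "toolC"])
        return bench, calls

    def test_identical_call_columns_identical_rows(self):
        bench, calls = self._bench_and_calls()
        perfs = {p.tool: p for p in evaluate_all_tools(bench, calls)}
        b, c = perfs["toolB"], perfs["toolC"]
        assert (b.counts, b.sensitivity, b.mcc) == (c.counts, c.sensitivity, c.mcc)

    def test_sorted_descending_sensitivity(self):
        bench, calls = self._bench_and_calls()
        perfs = evaluate_all_tools(bench, calls)
        sens = [p.sensitivity for p in perfs if p.sensitivity is not None]
        assert sens == sorted(sens, reverse=True)

    def test_unscored_tool_flagged(self):
        bench, calls = self._bench_and_calls()
        calls["toolD"] = NO_CALL
        perfs = {p.tool: p for p in evaluate_all_tools(bench, calls)}
        d = perfs["toolD"]
        assert d.n_scored_pos == 0 and d.n_scored_neg == 0
        assert d.sensitivity is None and d.specificity is None
        table = performance_table([d])
        assert math.isnan(table.loc[0, "sensitivity"])

    def test_empty_benchmark(self):
        bench = BenchmarkSet("merged", "T", set(), set())
        assert evaluate_all_tools(bench, pd.DataFrame()) == []


class TestMeanRow:
    def test_reference_mean_sensitivities(self, reference_metrics):
        afr = [r.sensitivity for r in reference_metrics["AFR"]]
        eur = [r.sensitivity for r in reference_metrics["EUR"]]
        assert round(mean_row(afr), 2) == 0.66
        assert round(mean_row(eur), 2) == 0.71

    def test_single_row(self):
        assert mean_row([0.42]) == 0.42

    def test_undefined_excluded(self):
        assert mean_row([0.2, None, 0.4, float("nan")]) == pytest.approx(0.3)

    def test_all_undefined_raises(self):
        with pytest.raises(DataError):
            mean_row([None, None])


class TestPairedMetricTest:
    def test_identical_vectors_null(self):
        stat, p = paired_metric_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (stat, p) == (0.0, 1.0)

    def test_paired_t_closed_form(self):
        # diffs (-0.1, -0.05, -0.1): mean -1/12, sd 0.028868 -> t = -5, df = 2
        from scipy.stats import t as tdist

        stat, p = paired_metric_test([0.1, 0.25, 0.3], [0.2, 0.3, 0.4], "paired_t")
        assert stat == pytest.approx(-5.0)
        assert p == pytest.approx(2 * tdist.sf(5.0, df=2))

    def test_reference_sensitivity_gap_significant(self, reference_metrics):
        afr = [r.sensitivity for r in reference_metrics["AFR"]]
        eur = [r.sensitivity for r in reference_metrics["EUR"]]
        for method in ("paired_t", "wilcoxon"):
            _, p = paired_metric_test(afr, eur, method)
            assert p < 1e-3, method

    def test_incomplete_pairs_dropped(self):
        stat, p = paired_metric_test([0.1, None, 0.3, 0.5], [0.2, 0.9, 0.35, 0.65])
        stat2, p2 = paired_metric_test([0.1, 0.3, 0.5], [0.2, 0.35, 0.65])
        assert stat == stat2 and p == p2

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            paired_metric_test([0.1, None], [0.2, 0.3])
        with pytest.raises(ConfigError):
            paired_metric_test([0.1], [0.2, 0.3])


class TestRates:
    @pytest.mark.parametrize(
        "n_var, n_pat, expected",
        [(158, 50, 3.16), (158 + 234, 50, 7.84), (202, 50, 4.04), (0, 50, 0.0)],
    )
    def test_per_capita(self, n_var, n_pat, expected):
        assert round(per_capita_rate(n_var, n_pat), 2) == expected

    def test_zero_patients_rejected(self):
        with pytest.raises(ConfigError):
            per_capita_rate(10, 0)

    def test_count_ratio(self):
        assert round(fold_change(99, 39), 1) == 2.5
        assert round(fold_change(21356, 15272), 1) == 1.4

    def test_rate_ratio(self):
        f = fold_change(13269, 9427, num_denom=4465388, den_denom=3752976, mode="rate_ratio")
        assert round(f, 2) == 1.18

    def test_equal_counts_unity(self):
        assert fold_change(7, 7) == 1.0

    def test_larger_over_smaller_symmetric(self):
        assert fold_change(2, 8, mode="larger_over_smaller") == 4.0
        assert fold_change(8, 2, mode="larger_over_smaller") == 4.0

    def test_zero_denominator_undefined(self):
        assert fold_change(5, 0) is None
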