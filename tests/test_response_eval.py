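"""Odds ratio, Fisher, average precision, coverage and table reconstruction."""

from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slide2rx.response_eval import (
    ResponseTable,
    average_precision,
    build_table,
    coverage_curve,
    evaluate_response,
    fisher_exact,
    odds_ratio_ci,
    permutation_test_ap,
    precision_increase_test,
    reconstruct_table,
)


class TestBuildTable:
    def test_all_matched_responders(self):
        t = build_table([True] * 4, [1] * 4)
        assert (t.a, t.b, t.c, t.d) == (4, 0, 0, 0)

    def test_one_patient_per_cell(self):
        t = build_table([True, True, False, False], [1, 0, 1, 0])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.random(30) > 0.5
        r = rng.random(30) > 0.6
        perm = rng.permutation(30)
        assert build_table(m, r) == build_table(m[perm], r[perm])

    def test_missing_labels_excluded_by_index(self):
        m = pd.Series([True, False, True], index=["a", "b", "c"])
        r = pd.Series([1, 0], index=["a", "b"])
        t = build_table(m, r)
        assert t.n == 2 and t.a == 1


class TestOddsRatio:
    def test_aggregate_worked_example(self):
        or_, lo, hi = odds_ratio_ci(ResponseTable(33, 36, 45, 120))
        assert or_ == pytest.approx(33 * 120 / (36 * 45))
        assert round(lo, 2) == 1.36
        assert round(hi, 2) == 4.38

    def test_balanced_table_symmetric_in_log_space(self):
        or_, lo, hi = odds_ratio_ci(ResponseTable(7, 7, 7, 7))
        assert or_ == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        or_, lo, hi = odds_ratio_ci(ResponseTable(5, 0, 3, 4))
        assert np.isfinite([or_, lo, hi]).all() and or_ > 1

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_ci(ResponseTable(0, 0, 3, 4))

    def test_matches_direct_formula_on_small_tables(self):
        for a, b, c, d in product(range(1, 5), repeat=4):
            or_, lo, hi = odds_ratio_ci(ResponseTable(a, b, c, d))
            assert or_ == pytest.approx(a * d / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert lo == pytest.approx(np.exp(np.log(or_) - 1.96 * se))
            assert hi == pytest.approx(np.exp(np.log(or_) + 1.96 * se))


def _fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher: sum probabilities <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_zero_margin_gives_p_one(self):
        assert fisher_exact(ResponseTable(0, 0, 5, 7)) == pytest.approx(1.0)

    def test_enumerated_three_three_example(self):
        assert fisher_exact(ResponseTable(3, 0, 0, 3)) == pytest.approx(0.1)

    def test_aggregate_table_both_sidedness_conventions(self):
        t = ResponseTable(33, 36, 45, 120)
        assert fisher_exact(t) == pytest.approx(0.00366, abs=5e-5)
        assert round(fisher_exact(t, alternative="greater"), 3) == 0.002

    def test_matches_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            t = ResponseTable(int(a), int(b), int(c), int(d))
            assert fisher_exact(t) == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-9)


def _ap_oracle(scores, labels):
    """Brute-force threshold sweep over descending unique scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        precision = labels[sel].mean()
        recall = labels[sel].sum() / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAveragePrecision:
    def test_perfect_ranking_gives_one(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_tied_scores_collapse_to_prevalence(self):
        assert average_precision([0.5] * 8, [1, 0, 0, 1, 0, 0, 0, 0]) == pytest.approx(0.25)

    def test_hand_computed_interleaved_case(self):
        assert average_precision([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(5 / 6)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.1, 0.2], [0, 0])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.integers(0, 1)),
            min_size=2, max_size=10,
        )
    )
    def test_matches_threshold_sweep_oracle(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if sum(labels) == 0:
            return
        assert average_precision(scores, labels) == pytest.approx(
            _ap_oracle(scores, labels), abs=1e-9
        )

    def test_random_permutation_expectation_near_prevalence(self):
        # the small-sample positive bias of AP under a random ranking decays
        # with n; at n = 400 the Monte-Carlo mean sits at the prevalence
        rng = np.random.default_rng(2)
        scores = rng.random(400)
        labels = (rng.random(400) < 0.3).astype(int)
        aps = [average_precision(scores, rng.permutation(labels)) for _ in range(150)]
        assert np.mean(aps) == pytest.approx(labels.mean(), abs=0.03)


class TestCoverageCurve:
    def test_coverage_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        curve = coverage_curve(scores, labels)
        assert (np.diff(curve.sort_values("threshold")["coverage"]) <= 1e-12).all()
        assert curve["coverage"].between(0.1, 0.9).all()

    def test_random_scores_fluctuate_around_unit_or(self):
        rng = np.random.default_rng(4)
        scores = rng.random(1000)
        labels = (rng.random(1000) < 0.4).astype(int)
        curve = coverage_curve(scores, labels)
        assert 0.8 <= curve["odds_ratio"].median() <= 1.25

    def test_perfect_classifier_flags_degenerate_points(self):
        labels = np.array([1] * 5 + [0] * 15)
        scores = labels * 0.9 + 0.05
        curve = coverage_curve(scores, labels)
        at_prev = curve[np.isclose(curve["coverage"], 0.25)]
        assert at_prev["degenerate"].all() or at_prev["odds_ratio"].isna().all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            coverage_curve([0.1] * 5, [1, 0, 1, 0, 1])


class TestPrecisionIncrease:
    def test_no_increase_when_precision_equals_orr(self):
        inc, _ = precision_increase_test(ResponseTable(2, 2, 2, 2))
        assert inc == pytest.approx(0.0)

    def test_aggregate_worked_example_rounds_to_43_5(self):
        inc, p = precision_increase_test(ResponseTable(33, 36, 45, 120))
        assert round(inc, 1) == 43.5
        assert 0 < p < 0.05

    def test_perfect_precision_doubles_half_orr(self):
        inc, _ = precision_increase_test(ResponseTable(10, 0, 10, 20))
        assert inc == pytest.approx(100.0)

    def test_zero_orr_rejected(self):
        with pytest.raises(ValueError):
            precision_increase_test(ResponseTable(0, 5, 0, 5))


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        scores = np.linspace(0, 1, 12)
        labels = (scores > 0.6).astype(int)
        p = permutation_test_ap(scores, labels, n_permutations=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        scores, labels = rng.random(25), (rng.random(25) < 0.4).astype(int)
        p1 = permutation_test_ap(scores, labels, n_permutations=199, seed=11)
        p2 = permutation_test_ap(scores, labels, n_permutations=199, seed=11)
        assert p1 == p2

    def test_roughly_uniform_under_null(self):
        rng = np.random.default_rng(6)
        ps = []
        for i in range(40):
            scores = rng.random(30)
            labels = (rng.random(30) < 0.5).astype(int)
            if labels.sum() == 0:
                continue
            ps.append(permutation_test_ap(scores, labels, n_permutations=99, seed=i))
        assert 0.25 < np.mean(ps) < 0.75

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_ap([0.1, 0.9], [0, 1], n_permutations=10, seed=0)


class TestReconstruction:
    def test_aggregate_table_is_unique(self):
        tables = reconstruct_table(234, 78, {"or": 2.44, "precision_pct": 47.8})
        assert tables == [ResponseTable(33, 36, 45, 120)]

    def test_balanced_tables_found_at_or_one(self):
        tables = reconstruct_table(4, 2, {"or": 1.0})
        assert ResponseTable(1, 1, 1, 1) in tables

    def test_inconsistent_constraints_give_empty_result(self):
        assert reconstruct_table(20, 10, {"precision_pct": 100.0, "or": 0.5}) == []


def test_evaluate_response_report_fields():
    rng = np.random.default_rng(7)
    idx = [f"p{i}" for i in range(40)]
    scores = pd.Series(rng.random(40), index=idx)
    labels = pd.Series((scores + 0.3 * rng.random(40) > 0.8).astype(int), index=idx)
    rep = evaluate_response(scores, labels, threshold=0.54)
    assert rep["n"] == 40
    assert 0 <= rep["average_precision"] <= 1
    assert rep["table"]["a"] + rep["table"]["b"] + rep["table"]["c"] + rep["table"]["d"] == 40
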