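import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavemap.activity import ActivityMatrix, CallMatrix
from cleavemap.rule import (
    RuleError,
    all_variant_rocs,
    boundary_is_monotone,
    brute_force_best_order,
    build_map,
    fit_boundary,
    order_targets,
    order_variants,
    score_rule_fit,
    variant_roc,
)
from conftest import act_matrix, bool_matrix


def random_call_matrix(rng, nv, nt):
    m = rng.uniform(size=(nv, nt)) < rng.uniform(0.2, 0.8)
    df = pd.DataFrame(
        m, index=[f"V{i}" for i in range(nv)], columns=[f"T{j}" for j in range(nt)]
    ).astype("boolean")
    return CallMatrix(calls=df, theta=0.20)


class TestOrderVariants:
    def test_count_then_mean_activity(self):
        calls = bool_matrix(
            [
                [1, 1, 1, 1, 1, 0],  # A: 5
                [1, 1, 0, 0, 0, 0],  # B: 2
                [1, 1, 1, 1, 1, 0],  # C: 5
            ],
            ["A", "B", "C"],
            [f"t{i}" for i in range(6)],
        )
        acts = act_matrix(
            [[0.9] * 6, [0.5] * 6, [1.1] * 6], ["A", "B", "C"], [f"t{i}" for i in range(6)]
        )
        assert order_variants(calls, acts) == ["C", "A", "B"]

    def test_degenerate_ties_lexicographic(self):
        calls = bool_matrix([[1, 0], [1, 0], [1, 0]], ["c", "a", "b"], ["t1", "t2"])
        acts = act_matrix([[0.8, 0.0]] * 3, ["c", "a", "b"], ["t1", "t2"])
        assert order_variants(calls, acts) == ["a", "b", "c"]

    def test_single_variant_identity(self):
        calls = bool_matrix([[1, 0, 1]], ["only"], ["t1", "t2", "t3"])
        acts = act_matrix([[1.0, 0.0, 0.9]], ["only"], ["t1", "t2", "t3"])
        assert order_variants(calls, acts) == ["only"]

    def test_axis_mismatch_errors(self):
        calls = bool_matrix([[1]], ["A"], ["t1"])
        acts = act_matrix([[1.0]], ["B"], ["t1"])
        with pytest.raises(RuleError):
            order_variants(calls, acts)


class TestOrderTargets:
    def test_staircase_zero_outliers_lexicographic(self, staircase_calls):
        order = order_targets(staircase_calls, ["A", "B", "C", "D"])
        assert order == ["t1", "t2", "t3", "t4", "t5"]

    def test_distinct_counts_sorted_by_count(self):
        calls = bool_matrix(
            [[1, 1, 1], [0, 1, 1], [0, 0, 1]], ["A", "B", "C"], ["x", "y", "z"]
        )
        assert order_targets(calls, ["A", "B", "C"]) == ["z", "y", "x"]

    def test_flipped_cell_matches_brute_force(self):
        # 3 variants x 4 targets staircase with one flipped cell
        calls = bool_matrix(
            [[1, 1, 1, 0], [1, 1, 0, 1], [1, 0, 0, 0]],
            ["A", "B", "C"],
            ["t1", "t2", "t3", "t4"],
        )
        order = order_targets(calls, ["A", "B", "C"])
        ordered = CallMatrix(calls=calls.calls.loc[["A", "B", "C"], order], theta=0.2)
        mine = len(fit_boundary(ordered).outliers)
        _, best = brute_force_best_order(calls)
        assert mine == best == 1

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_never_worse_than_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        calls = random_call_matrix(rng, int(rng.integers(2, 5)), int(rng.integers(2, 7)))
        vorder = list(calls.calls.index)
        order = order_targets(calls, vorder)
        ordered = CallMatrix(calls=calls.calls.loc[vorder, order], theta=0.2)
        mine = len(fit_boundary(ordered).outliers)
        _, best = brute_force_best_order(calls, max_cells=28)
        assert mine == best


class TestFitBoundary:
    def test_perfect_staircase(self, staircase_calls):
        rmap = fit_boundary(staircase_calls)
        assert rmap.n_outliers == 0
        assert list(rmap.boundary) == [5, 4, 2, 1]

    def test_smaller_b_tie_rule(self):
        # ordered calls [1,1,0,1,0]: b=2 and b=4 both misclassify one cell
        calls = bool_matrix([[1, 1, 0, 1, 0]], ["v"], [f"t{i}" for i in range(5)])
        rmap = fit_boundary(calls)
        # independent enumeration of all cutoffs
        row = [1, 1, 0, 1, 0]
        best = min(
            range(6),
            key=lambda b: (sum(1 - x for x in row[:b]) + sum(row[b:]), b),
        )
        assert rmap.boundary[0] == best == 2
        assert rmap.outliers == [("v", "t3", True, False)]

    def test_all_cleaved_variant(self):
        calls = bool_matrix([[1, 1, 1]], ["v"], ["a", "b", "c"])
        rmap = fit_boundary(calls)
        assert rmap.boundary[0] == 3
        assert rmap.n_outliers == 0

    def test_count_matched_mode(self):
        calls = bool_matrix([[1, 1, 0, 1, 0]], ["v"], [f"t{i}" for i in range(5)])
        rmap = fit_boundary(calls, count_matched=True)
        assert rmap.boundary[0] == 3  # observed cleaved count
        assert rmap.n_outliers == 2  # paired FP/FN forced by count matching

    def test_monotone_flag(self):
        calls = bool_matrix([[1, 0, 0], [1, 1, 1]], ["hi", "lo"], ["a", "b", "c"])
        rmap = fit_boundary(calls, monotone=True)
        assert boundary_is_monotone(rmap)

    def test_monotone_validator(self, staircase_calls):
        assert boundary_is_monotone(fit_boundary(staircase_calls))


class TestScoreRuleFit:
    def test_zero_outliers_gmean_one(self, staircase_calls):
        fit = score_rule_fit(fit_boundary(staircase_calls))
        assert fit.gmean == 1.0
        assert fit.n_outliers == 0

    def test_hand_confusion_matrix(self):
        # 10 cleaved / 10 not-cleaved with exactly 1 FN, 0 FP: boundary at 9
        from cleavemap.rule import RankedCleavageMap

        calls = bool_matrix([[1] * 10 + [0] * 10], ["v"], [f"t{i:02d}" for i in range(20)])
        rmap = RankedCleavageMap(
            variant_order=["v"],
            target_order=list(calls.calls.columns),
            boundary=np.array([9]),
            outliers=[("v", "t09", True, False)],
            calls=calls.calls,
            theta=0.2,
        )
        fit = score_rule_fit(rmap)
        assert (fit.tp, fit.fp, fit.tn, fit.fn) == (9, 0, 10, 1)
        assert fit.sensitivity == pytest.approx(0.9)
        assert fit.specificity == pytest.approx(1.0)
        assert fit.gmean == pytest.approx(math.sqrt(0.9))

    def test_single_class_flagged_undefined(self):
        calls = bool_matrix([[1, 1, 1]], ["v"], ["a", "b", "c"])
        fit = score_rule_fit(fit_boundary(calls))
        assert not fit.defined
        assert math.isnan(fit.gmean)

    def test_gmean_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            calls = random_call_matrix(rng, 4, 6)
            rmap = fit_boundary(calls)
            fit = score_rule_fit(rmap)
            assert fit.n_outliers == rmap.n_outliers == fit.fp + fit.fn
            assert fit.n_cells == calls.calls.notna().sum().sum()
            if fit.defined:
                assert fit.gmean == pytest.approx(
                    math.sqrt(fit.sensitivity * fit.specificity)
                )
                assert (fit.gmean == 1.0) == (fit.n_outliers == 0)

    def test_flipping_concordant_cell_never_raises_gmean(self):
        # against a fixed boundary, turning any concordant cell discordant
        # can only push G-mean down
        from cleavemap.rule import RankedCleavageMap

        rng = np.random.default_rng(7)
        for _ in range(20):
            calls = random_call_matrix(rng, 3, 5)
            rmap = fit_boundary(calls)
            base = score_rule_fit(rmap)
            if not base.defined:
                continue
            pred = rmap.predicted()
            for v in rmap.calls.index:
                for t in rmap.calls.columns:
                    if bool(rmap.calls.loc[v, t]) != bool(pred.loc[v, t]):
                        continue
                    df = rmap.calls.copy()
                    df.loc[v, t] = not bool(df.loc[v, t])
                    flipped = RankedCleavageMap(
                        variant_order=rmap.variant_order,
                        target_order=rmap.target_order,
                        boundary=rmap.boundary,
                        outliers=[],
                        calls=df,
                        theta=rmap.theta,
                    )
                    worse = score_rule_fit(flipped)
                    if worse.defined:
                        assert worse.gmean <= base.gmean + 1e-12


class TestVariantROC:
    def test_perfectly_ordered_auc_one(self):
        order = [f"t{i}" for i in range(6)]
        calls = pd.Series([True, True, True, False, False, False], index=order)
        roc = variant_roc(order, calls, "v")
        assert roc.auc == 1.0
        assert roc.points[0] == (0.0, 0.0)
        assert roc.points[-1] == (1.0, 1.0)

    @pytest.mark.parametrize(
        "labels, expect",
        [
            ([True, False, False, True], 0.5),  # rank-symmetric, balanced -> 0.5
            ([True, False] * 5, None),  # alternating; oracle computes the value
        ],
    )
    def test_rank_oracle_agreement(self, labels, expect):
        order = [f"t{i}" for i in range(len(labels))]
        calls = pd.Series(labels, index=order)
        roc = variant_roc(order, calls, "v")
        # closed-form rank oracle: P(pos outranks neg) over all pairs
        scores = {t: len(order) - i for i, t in enumerate(order)}
        pos = [scores[t] for t, y in zip(order, labels) if y]
        neg = [scores[t] for t, y in zip(order, labels) if not y]
        oracle = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert roc.auc == pytest.approx(oracle)
        if expect is not None:
            assert roc.auc == pytest.approx(expect)

    def test_single_class_undefined(self):
        order = ["a", "b", "c"]
        roc = variant_roc(order, pd.Series([True, True, True], index=order), "v")
        assert not roc.defined

    def test_missing_call_errors(self):
        order = ["a", "b"]
        with pytest.raises(RuleError):
            variant_roc(order, pd.Series([True], index=["a"]), "v")

    def test_relabel_invariance(self):
        rng = np.random.default_rng(11)
        order = [f"t{i}" for i in range(8)]
        labels = rng.uniform(size=8) < 0.5
        calls = pd.Series(labels, index=order)
        roc1 = variant_roc(order, calls, "v")
        renamed = {t: f"x{i}" for i, t in enumerate(order)}
        order2 = [renamed[t] for t in order]
        calls2 = pd.Series(labels, index=order2)
        roc2 = variant_roc(order2, calls2, "v")
        assert roc1.points == roc2.points
        assert (roc1.auc == roc2.auc) or (math.isnan(roc1.auc) and math.isnan(roc2.auc))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        order = [f"t{i}" for i in range(12)]
        labels = rng.uniform(size=12) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        calls = pd.Series(labels, index=order)
        roc = variant_roc(order, calls, "v")
        scores = np.arange(12, 0, -1)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestBruteForce:
    def test_staircase_zero(self, staircase_calls):
        _, best = brute_force_best_order(staircase_calls)
        assert best == 0

    def test_flipped_cell_one(self):
        calls = bool_matrix(
            [[1, 1, 1, 0], [1, 1, 0, 1], [1, 0, 0, 0]],
            ["A", "B", "C"],
            ["t1", "t2", "t3", "t4"],
        )
        _, best = brute_force_best_order(calls)
        assert best == 1

    def test_all_zero_matrix(self):
        calls = bool_matrix([[0, 0], [0, 0]], ["A", "B"], ["x", "y"])
        _, best = brute_force_best_order(calls)
        assert best == 0

    def test_too_large_rejected(self):
        calls = bool_matrix(np.ones((5, 6), dtype=bool), [f"v{i}" for i in range(5)], [f"t{j}" for j in range(6)])
        with pytest.raises(RuleError, match="max_cells"):
            brute_force_best_order(calls)


class TestBuildMap:
    def test_end_to_end_on_staircase_activities(self):
        vals = [
            [1.00, 0.95, 0.88, 0.80, 1.10],
            [0.90, 1.05, 0.75, 0.85, 0.00],
            [0.72, 0.91, 0.05, 0.00, 0.00],
            [1.10, 0.00, 0.00, 0.00, 0.00],
        ]
        acts = act_matrix(vals, ["w", "x", "y", "z"], [f"t{i}" for i in range(5)])
        rmap = build_map(acts, 0.20)
        fit = score_rule_fit(rmap)
        assert fit.gmean == 1.0
        assert rmap.variant_order == ["w", "x", "y", "z"]
        assert rmap.target_order[0] == "t0"
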