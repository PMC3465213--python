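"""Ranking metrics against brute-force oracles, exact Wilcoxon, folds, ladder.

The AUC iP/R and TAP-k oracles below are deliberately naive, literal
transcriptions of the metric definitions, independent of the package's
implementations; agreement is checked exhaustively over all short binary
relevance lists.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from relrank import ValidationError
from relrank.evaluation import (
    auc_ipr,
    greedy_parameter_ascent,
    macro_average,
    paired_wilcoxon,
    perfect_ranking_bound,
    prf_at_cutoff,
    stratified_folds,
    tap_k,
)


# ---------------------------------------------------------------------------
# Independent metric oracles
# ---------------------------------------------------------------------------

def oracle_auc_ipr(relevance, n_gold, cutoff):
    """Literal interpolated-precision area: for each retrieved gold item,
    take the max precision at any rank with recall >= its recall."""
    rel = relevance[:cutoff]
    points = []  # (recall, precision) at every rank
    tp = 0
    for i, r in enumerate(rel, start=1):
        tp += r
        points.append((tp / n_gold, tp / i))
    total = 0.0
    tp = 0
    for i, r in enumerate(rel, start=1):
        if r:
            tp += 1
            recall_here = tp / n_gold
            total += max(p for rec, p in points if rec >= recall_here)
    return total / n_gold


def oracle_tap_k(relevance, n_gold, k):
    """Literal threshold average precision: sum precision at gold ranks up
    to the k-th false positive (or list end), add the terminal precision,
    divide by n_gold + 1."""
    if not relevance:
        return 0.0
    fp = 0
    threshold = len(relevance)
    for i, r in enumerate(relevance, start=1):
        if not r:
            fp += 1
            if fp == k:
                threshold = i
                break
    total = 0.0
    tp = 0
    for i, r in enumerate(relevance[:threshold], start=1):
        if r:
            tp += 1
            total += tp / i
    terminal = tp / threshold
    return (total + terminal) / (n_gold + 1)


def as_items(relevance, n_gold):
    """Turn a 0/1 relevance pattern into a ranked item list and a gold set."""
    items = []
    gold = set()
    tp_count = sum(relevance)
    for i, r in enumerate(relevance):
        name = f"tp{i}" if r else f"fp{i}"
        items.append(name)
        if r:
            gold.add(name)
    for j in range(n_gold - tp_count):  # unretrieved gold items
        gold.add(f"missed{j}")
    return items, gold


def all_binary_lists(max_len):
    for length in range(max_len + 1):
        yield from itertools.product([0, 1], repeat=length)


class TestMetricOracles:
    def test_exhaustive_agreement_with_brute_force(self):
        for relevance in all_binary_lists(8):
            n_tp = sum(relevance)
            for n_gold in range(max(n_tp, 1), 9):
                items, gold = as_items(relevance, n_gold)
                assert auc_ipr(items, gold, cutoff=8) == pytest.approx(
                    oracle_auc_ipr(relevance, n_gold, 8)
                ), (relevance, n_gold)
                for k in (1, 2, 3):
                    assert tap_k(items, gold, k) == pytest.approx(
                        oracle_tap_k(relevance, n_gold, k)
                    ), (relevance, n_gold, k)

    def test_hand_derived_values(self):
        items, gold = as_items((1, 0, 1), 2)
        assert auc_ipr(items, gold, cutoff=50) == pytest.approx((1 + 2 / 3) / 2)
        items, gold = as_items((1, 0, 0), 1)
        assert tap_k(items, gold, k=1) == pytest.approx(0.75)

    def test_perfect_list_scores_one(self):
        for n in (1, 3, 6):
            items, gold = as_items((1,) * n, n)
            assert auc_ipr(items, gold, cutoff=50) == 1.0
            assert tap_k(items, gold, k=2) == 1.0

    def test_all_false_positives_score_zero(self):
        items, gold = as_items((0, 0, 0), 2)
        assert auc_ipr(items, gold, cutoff=50) == 0.0
        assert tap_k(items, gold, k=3) == 0.0

    def test_empty_list_scores_zero(self):
        assert tap_k([], {"g"}, k=1) == 0.0
        assert auc_ipr([], {"g"}, cutoff=50) == 0.0

    def test_tap_threshold_semantics_at_increasing_k(self):
        # a deeper error threshold that adds no gold items only dilutes the
        # terminal precision: [TP, FP, FP] scores (1 + 1/2)/2 at k=1 but
        # (1 + 1/3)/2 once the second false positive is tolerated
        items, gold = as_items((1, 0, 0), 1)
        assert tap_k(items, gold, 1) == pytest.approx(0.75)
        assert tap_k(items, gold, 2) == pytest.approx((1 + 1 / 3) / 2)
        assert tap_k(items, gold, 3) == pytest.approx((1 + 1 / 3) / 2)
        # whereas a deeper threshold that reaches extra gold raises the score
        items, gold = as_items((1, 0, 1), 2)
        assert tap_k(items, gold, 2) > tap_k(items, gold, 1)

    def test_auc_non_decreasing_in_cutoff(self):
        items, gold = as_items((0, 1, 0, 1, 1, 0, 1), 5)
        values = [auc_ipr(items, gold, c) for c in range(1, 9)]
        assert values == sorted(values)

    def test_duplicate_predictions_collapsed_to_best_rank(self):
        assert tap_k(["a", "a", "x"], {"a"}, k=1) == tap_k(
            ["a", "x"], {"a"}, k=1
        )
        assert auc_ipr(["x", "a", "a"], {"a"}, 50) == auc_ipr(
            ["x", "a"], {"a"}, 50
        )


class TestPrfAtCutoff:
    def test_counts_in_top_cutoff(self):
        items, gold = as_items((1, 0, 1, 0, 0), 4)
        p, r, f = prf_at_cutoff(items, gold, cutoff=5)
        assert (p, r) == (0.4, 0.5)
        assert f == pytest.approx(4 / 9)

    def test_perfect_list(self):
        items, gold = as_items((1, 1, 1), 3)
        assert prf_at_cutoff(items, gold, cutoff=3) == (1.0, 1.0, 1.0)

    def test_no_gold_retrieved(self):
        items, gold = as_items((0, 0), 2)
        assert prf_at_cutoff(items, gold, cutoff=2) == (0.0, 0.0, 0.0)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValidationError):
            prf_at_cutoff(["a"], set(), 5)


class TestPerfectRankingBound:
    def test_stable_partition(self):
        assert perfect_ranking_bound(["f1", "t1", "f2", "t2"], {"t1", "t2"}) == [
            "t1", "t2", "f1", "f2",
        ]

    def test_already_perfect_unchanged(self):
        assert perfect_ranking_bound(["t1", "f1"], {"t1"}) == ["t1", "f1"]

    def test_all_false_positives_unchanged(self):
        assert perfect_ranking_bound(["f1", "f2"], {"g"}) == ["f1", "f2"]

    def test_never_lowers_any_metric(self):
        for relevance in all_binary_lists(7):
            items, gold = as_items(relevance, max(sum(relevance), 1))
            reranked = perfect_ranking_bound(items, gold)
            assert auc_ipr(reranked, gold, 8) >= auc_ipr(items, gold, 8) - 1e-12
            for k in (1, 2, 3):
                assert tap_k(reranked, gold, k) >= tap_k(items, gold, k) - 1e-12


class TestMacroAverage:
    def test_plain_mean(self):
        mean, sd = macro_average({"a": 1.0, "b": 0.0})
        assert mean == 0.5

    def test_prediction_less_document_excluded_or_zeroed(self):
        values = {"a": 1.0, "b": None}
        mean_all, _ = macro_average(values, "all_gold_docs")
        mean_pred, _ = macro_average(values, "docs_with_predictions")
        assert mean_all == 0.5
        assert mean_pred == 1.0

    def test_zero_documents_rejected(self):
        with pytest.raises(ValidationError):
            macro_average({"a": None}, "docs_with_predictions")


class TestStratifiedFolds:
    def test_even_strata_deal_evenly(self):
        counts = {f"d{i}": 1 for i in range(20)}
        folds = stratified_folds(counts, n_folds=10, seed=3)
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert list(sizes) == [2] * 10

    def test_uneven_stratum_sizes_differ_by_at_most_one(self):
        counts = {f"d{i}": 3 for i in range(13)}
        folds = stratified_folds(counts, n_folds=10, seed=3)
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert set(sizes) <= {1, 2}

    def test_same_seed_is_deterministic(self):
        counts = {f"d{i}": (i % 4) + 1 for i in range(37)}
        assert stratified_folds(counts, 10, seed=5) == stratified_folds(
            counts, 10, seed=5
        )

    def test_stratification_respected(self):
        counts = {f"a{i}": 1 for i in range(10)}
        counts.update({f"b{i}": 7 for i in range(10)})
        folds = stratified_folds(counts, n_folds=5, seed=0)
        for stratum in ("a", "b"):
            sizes = np.bincount(
                [f for d, f in folds.items() if d.startswith(stratum)],
                minlength=5,
            )
            assert list(sizes) == [2] * 5

    def test_doc_without_relations_rejected(self):
        with pytest.raises(ValidationError):
            stratified_folds({"d": 0}, 10, 0)


class TestPairedWilcoxon:
    def test_all_positive_ten_pairs(self):
        p, _ = paired_wilcoxon([0.0] * 10, list(range(1, 11)))
        assert p == pytest.approx(1 / 1024)

    def test_identical_samples(self):
        assert paired_wilcoxon([1.0] * 10, [1.0] * 10) == (1.0, 0.0)

    def test_single_flip_of_smallest_difference(self):
        b = list(range(1, 11))
        b[0] = -1  # the smallest |difference| now argues the other way
        p, _ = paired_wilcoxon([0.0] * 10, b)
        assert p == pytest.approx(2 / 1024)

    @pytest.mark.parametrize("n", [6, 8, 10, 12])
    def test_agrees_with_scipy_exact_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            a = rng.normal(size=n)
            b = a + rng.normal(0.3, 1.0, size=n)
            p_ours, _ = paired_wilcoxon(list(a), list(b))
            p_scipy = scipy_wilcoxon(
                b, a, alternative="greater", method="exact"
            ).pvalue
            assert p_ours == pytest.approx(p_scipy)

    def test_confidence_bound_matches_r_exact_oracle(self):
        # frozen from R stats::wilcox.test(b, a, paired=TRUE,
        #   alternative="greater", conf.int=TRUE, exact=TRUE)
        cases = [
            ([0.0] * 10,
             [0.5, -0.2, 1.3, 2.1, -0.7, 3.3, 0.9, 1.7, 2.9, 4.1],
             0.006835937500, 0.55),
            ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
             [1.9, 1.7, 3.6, 5.2, 5.1, 8.0, 7.4],
             0.023437500000, 0.10),
            ([0.0] * 10, list(range(1, 11)), 0.0009765625, 3.5),
        ]
        for a, b, p_expected, ci_expected in cases:
            p, ci = paired_wilcoxon(a, b)
            assert p == pytest.approx(p_expected, abs=1e-10)
            assert ci == pytest.approx(ci_expected, abs=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            paired_wilcoxon([1, 2, 3, 4, 5], [1, 2, 3, 4])


class TestGreedyParameterAscent:
    @staticmethod
    def grid_with_planted_effects(effects, base=0.30, noise_sd=0.002, seed=0):
        """Fold means for a full factorial over three binary parameters.

        ``effects`` maps parameter position (4=n, 5=c, 6=s) to the additive
        gain of its "on" value; fold noise is tiny so the greedy path is
        decided by the planted effect sizes.
        """
        rng = np.random.default_rng(seed)
        grid = {}
        for n in ("n0", "n3"):
            for c in ("c0", "c6"):
                for s in ("s0", "s1"):
                    mean = base
                    if n == "n3":
                        mean += effects["n"]
                    if c == "c6":
                        mean += effects["c"]
                    if s == "s1":
                        mean += effects["s"]
                    label = f"t-e0-r0-m1-{n}-{c}-{s}"
                    grid[label] = list(mean + rng.normal(0, noise_sd, 10))
        return grid

    def test_single_setting_grid_yields_empty_ladder(self):
        steps = greedy_parameter_ascent(
            {"t-e0-r0-m0-n0-c0-s0": [0.3] * 10}, "t-e0-r0-m0-n0-c0-s0"
        )
        assert steps == []

    def test_two_settings_one_step(self):
        grid = {
            "t-e0-r0-m0-n0-c0-s0": [0.30 + 0.001 * i for i in range(10)],
            "t-e1-r0-m0-n0-c0-s0": [0.35 + 0.001 * i for i in range(10)],
        }
        steps = greedy_parameter_ascent(grid, "t-e0-r0-m0-n0-c0-s0")
        assert len(steps) == 1
        step = steps[0]
        assert step.changed == ("e",)
        assert step.delta_abs == pytest.approx(0.05)
        assert step.delta_rel == pytest.approx(step.delta_rel_baseline)

    def test_planted_effect_ordering_recovered(self):
        grid = self.grid_with_planted_effects({"n": 0.06, "c": 0.03, "s": 0.01})
        steps = greedy_parameter_ascent(grid, "t-e0-r0-m1-n0-c0-s0")
        assert [s.changed for s in steps] == [("n",), ("c",), ("s",)]
        # cumulative relative gain grows along the ladder
        gains = [s.delta_rel_baseline for s in steps]
        assert gains == sorted(gains)

    def test_stops_when_no_improvement(self):
        grid = self.grid_with_planted_effects({"n": 0.05, "c": -0.04, "s": -0.02})
        steps = greedy_parameter_ascent(grid, "t-e0-r0-m1-n0-c0-s0")
        assert [s.changed for s in steps] == [("n",)]
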