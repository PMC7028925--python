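"""Threshold grid machinery, selection rules and classification boundaries."""

import numpy as np
import pandas as pd
import pytest

from hybridgate.thresholds import (CATEGORY_RANK, ClassSplit, ThresholdPair,
                                   classify_individual, classify_table,
                                   default_threshold_grid,
                                   efficiency_accuracy, enumerate_splits,
                                   error_rates, performance_grid,
                                   select_pure_threshold,
                                   select_recent_threshold)


class TestSplits:
    def test_family_size_and_ends(self):
        splits = enumerate_splits()
        assert len(splits) == 8
        assert splits[0].pure_side == ("PW",)
        assert set(splits[-1].admixed_side) == {"BC1W", "F2", "F1"}

    def test_f1_f2_bc1w_never_pure(self):
        for s in enumerate_splits():
            assert not ({"F1", "F2", "BC1W"} & set(s.pure_side))

    def test_nesting_follows_ladder_order(self):
        splits = enumerate_splits()
        for a, b in zip(splits, splits[1:]):
            assert set(a.pure_side) < set(b.pure_side)

    def test_split_validation(self):
        with pytest.raises(ValueError):
            ClassSplit("bad", ("PW",), ("PW", "F1"))


def brute_force_eff_acc(labels, q, admixed_side, t):
    """Confusion-table recomputation independent of the implementation."""
    tp = fp = fn = 0
    for lab, qi in zip(labels, q):
        called = qi < t
        truth = lab in admixed_side
        if called and truth:
            tp += 1
        elif called and not truth:
            fp += 1
        elif not called and truth:
            fn += 1
    eff = tp / (tp + fn)
    acc = tp / (tp + fp) if (tp + fp) else 1.0
    return eff, acc


class TestEfficiencyAccuracy:
    SPLIT = ClassSplit("S", ("PW",), ("F1",))

    def table(self, rows):
        return pd.DataFrame(rows, columns=["label", "q_wild"])

    def test_hand_computed_confusion(self):
        """10 true admixed, 8 detected, plus 2 pure false positives."""
        rows = ([("F1", 0.3)] * 8 + [("F1", 0.99)] * 2
                + [("PW", 0.5)] * 2 + [("PW", 0.999)] * 8)
        eff, acc = efficiency_accuracy(self.table(rows), self.SPLIT, 0.955)
        assert eff == pytest.approx(0.8)
        assert acc == pytest.approx(0.8)
        assert eff * acc == pytest.approx(0.64)

    def test_perfect_separation(self):
        rows = [("F1", 0.4)] * 5 + [("PW", 0.99)] * 5
        assert efficiency_accuracy(self.table(rows), self.SPLIT, 0.7) == (1.0, 1.0)

    def test_nothing_called_admixed(self):
        rows = [("F1", 0.9)] * 5 + [("PW", 0.99)] * 5
        eff, acc = efficiency_accuracy(self.table(rows), self.SPLIT, 0.5)
        assert eff == 0.0
        assert acc == 1.0  # vacuous by convention

    def test_two_sided_mode_averages_both_sides(self):
        rows = [("F1", 0.3)] * 10 + [("PW", 0.999)] * 10
        eff, acc = efficiency_accuracy(self.table(rows), self.SPLIT, 0.955,
                                       mode="two_sided")
        assert eff == pytest.approx(1.0)
        assert acc == pytest.approx(1.0)

    def test_brute_force_agreement_on_random_tables(self):
        """1,000 random labelled q tables match an independent recount."""
        rng = np.random.default_rng(99)
        splits = enumerate_splits()
        classes = ("PW", "BC8W", "BC4W", "BC1W", "F2", "F1")
        for _ in range(1_000):
            n = rng.integers(5, 40)
            labels = rng.choice(classes, size=n)
            q = np.round(rng.random(n), 3)
            split = splits[rng.integers(0, len(splits))]
            if not np.isin(labels, split.admixed_side).any():
                continue
            t = float(rng.choice(default_threshold_grid()))
            table = pd.DataFrame({"label": labels, "q_wild": q})
            got = efficiency_accuracy(table, split, t)
            want = brute_force_eff_acc(labels, q, set(split.admixed_side), t)
            assert got == pytest.approx(want)


class TestGridAndSelection:
    def test_grid_has_101_thresholds_ending_at_0999(self):
        g = default_threshold_grid()
        assert len(g) == 101
        assert g[0] == 0.5 and g[-1] == 0.999
        assert np.allclose(np.diff(g)[:-1], 0.005)

    def test_performance_bounded_by_factors(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "label": rng.choice(("PW", "F1", "BC1W"), size=60),
            "q_wild": rng.random(60),
        })
        grid = performance_grid(table)
        assert (grid["performance"]
                <= np.minimum(grid["efficiency"], grid["accuracy"]) + 1e-12).all()

    def test_highest_threshold_across_retained_splits(self):
        """Three retained splits peaking at 0.670 / 0.840 / 0.950-0.955:
        the conservative choice is the top of the highest plateau, 0.955."""
        rows = []
        for t in default_threshold_grid():
            rows.append((t, "SA", 0.982 if np.isclose(t, 0.670) else 0.5))
            rows.append((t, "SB", 0.922 if np.isclose(t, 0.840) else 0.5))
            peak = np.isclose(t, 0.950) or np.isclose(t, 0.955)
            rows.append((t, "SC", 0.900 if peak else 0.5))
        grid = pd.DataFrame(rows, columns=["threshold", "split_name",
                                           "performance"])
        grid["efficiency"] = grid["performance"]
        grid["accuracy"] = 1.0
        t_recent, retained = select_recent_threshold(grid, 0.90)
        assert t_recent == pytest.approx(0.955)
        assert len(retained) == 3

    def test_plateau_rule_takes_highest(self):
        rows = []
        for t in default_threshold_grid():
            perf = 0.95 if 0.90 <= t <= 0.92 else 0.2
            rows.append((t, "S1", perf, perf, perf))
        grid = pd.DataFrame(rows, columns=["threshold", "split_name",
                                           "efficiency", "accuracy",
                                           "performance"])
        t_recent, _ = select_recent_threshold(grid, 0.90)
        assert t_recent == pytest.approx(0.92)

    def test_no_split_reaches_minimum(self):
        grid = pd.DataFrame({
            "threshold": [0.5, 0.6], "split_name": ["S1", "S1"],
            "efficiency": [0.5, 0.5], "accuracy": [0.5, 0.5],
            "performance": [0.25, 0.25],
        })
        with pytest.raises(ValueError, match="more markers"):
            select_recent_threshold(grid, 0.90)

    def test_pure_threshold_floors_parental_minimum(self):
        table = pd.DataFrame({
            "label": ["RW", "PW", "PW"], "q_wild": [0.9987, 0.9953, 0.9991]})
        assert select_pure_threshold(table) == pytest.approx(0.995)

    def test_pure_threshold_mislabeled_parental_surfaces_error(self):
        table = pd.DataFrame({"label": ["PW", "PW"], "q_wild": [0.5, 0.99]})
        t_pure = select_pure_threshold(table)
        with pytest.raises(ValueError):
            ThresholdPair(0.955, t_pure)

    def test_all_parentals_at_one(self):
        table = pd.DataFrame({"label": ["PW"], "q_wild": [1.0]})
        assert select_pure_threshold(table) == 1.0


class TestClassification:
    PAIR = ThresholdPair(0.955, 0.995)

    @pytest.mark.parametrize("q,cls,cat", [
        (0.996, "pure", "operational_pure"),
        (0.995, "pure", "operational_pure"),           # boundary: >= t_pure
        (0.994, "older_admixed", "introgressed"),
        (0.970, "older_admixed", "introgressed"),
        (0.955, "older_admixed", "introgressed"),      # boundary: >= t_recent
        (0.954, "recent_admixed", "operational_hybrid"),
        (0.40, "recent_admixed", "operational_hybrid"),
    ])
    def test_boundaries_exact(self, q, cls, cat):
        assert classify_individual(q, self.PAIR) == (cls, cat)

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(5)
        q = np.sort(rng.random(500))
        cats = [classify_individual(x, self.PAIR)[1] for x in q]
        ranks = [CATEGORY_RANK[c] for c in cats]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({
            "label": ["F1"] * 50, "q_wild": rng.random(50)})
        out = classify_table(table, self.PAIR)
        for _, row in out.iterrows():
            cls, cat = classify_individual(row["q_wild"], self.PAIR)
            assert (row["assignment_class"], row["management_category"]) \
                == (cls, cat)

    def test_threshold_pair_invariants(self):
        with pytest.raises(ValueError):
            ThresholdPair(0.995, 0.955)
        with pytest.raises(ValueError):
            ThresholdPair(0.4, 0.995)


class TestErrorRates:
    def test_absent_type_i_when_parentals_pure(self):
        table = pd.DataFrame({
            "label": ["PW"] * 10 + ["F1"] * 10,
            "q_wild": [0.999] * 10 + [0.4] * 10,
        })
        classified = classify_table(table, ThresholdPair(0.955, 0.995))
        type_i, type_ii, conf = error_rates(classified)
        assert type_i == 0.0
        assert type_ii == 0.0
        assert conf.loc["F1", "operational_hybrid"] == pytest.approx(100.0)

    def test_type_ii_counts_admixed_called_pure(self):
        table = pd.DataFrame({
            "label": ["PW", "BC4W", "BC4W", "BC4W", "BC4W"],
            "q_wild": [0.999, 0.999, 0.999, 0.999, 0.5],
        })
        classified = classify_table(table, ThresholdPair(0.955, 0.995))
        type_i, type_ii, conf = error_rates(classified)
        assert type_i == 0.0
        assert type_ii == pytest.approx(0.75)
        assert conf.loc["BC4W", "operational_pure"] == pytest.approx(75.0)

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({
            "label": rng.choice(("PW", "F1", "BC2W"), 90),
            "q_wild": rng.random(90),
        })
        classified = classify_table(table, ThresholdPair(0.955, 0.995))
        _, _, conf = error_rates(classified)
        assert np.allclose(conf.sum(axis=1), 100.0)
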