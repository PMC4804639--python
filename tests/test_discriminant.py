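"""ROC/AUC, cutoff selection, panel screening and the count-over-cutoff sweep."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeclass.discriminant import (
    ASD_ABOVE,
    ASD_BELOW,
    CutoffRule,
    auc,
    count_items_met,
    hanley_mcneil_ci,
    round_half_away,
    rules_from_table4,
    select_cutoff,
    select_panel,
    sweep_from_counts,
)
from gazeclass.exceptions import InsufficientDataError, PanelEmptyError
from gazeclass.stats import compare_from_summary


def brute_force_auc(values_asd, values_td, direction):
    """All-pairs win/tie count, the defining form of the statistic."""
    sign = -1.0 if direction == ASD_BELOW else 1.0
    wins = ties = 0
    for a in values_asd:
        for t in values_td:
            if sign * a > sign * t:
                wins += 1
            elif a == t:
                ties += 1
    return (wins + 0.5 * ties) / (len(values_asd) * len(values_td))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([10, 20], [30, 40], ASD_BELOW) == 1.0

    def test_exchangeable_groups(self):
        assert auc([1, 2, 3], [1, 2, 3], ASD_BELOW) == 0.5

    def test_interleaved_example(self):
        # 6 wins of 9 pairs under the ASD-below orientation
        assert auc([1, 3, 5], [2, 4, 6], ASD_BELOW) == pytest.approx(2 / 3)

    def test_empty_group_raises(self):
        with pytest.raises(InsufficientDataError):
            auc([], [1.0], ASD_BELOW)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.sampled_from([ASD_BELOW, ASD_ABOVE]),
    )
    def test_equals_brute_force_all_pairs(self, xs, ys, direction):
        """Rank-based AUC equals exhaustive pair counting, ties included."""
        assert auc(xs, ys, direction) == pytest.approx(
            brute_force_auc(xs, ys, direction), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        x = rng.normal(40, 20, 21)
        y = rng.normal(60, 15, 35)
        ours = auc(x, y, ASD_BELOW)
        ref = roc_auc_score([1] * 21 + [0] * 35, np.concatenate([-x, -y]))
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_hanley_mcneil_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = auc(rng.normal(40, 20, 15), rng.normal(55, 20, 20), ASD_BELOW)
            lo, hi = hanley_mcneil_ci(a, 15, 20)
            assert 0 <= lo <= a <= hi <= 1


class TestSelectCutoff:
    def test_separated_groups_midpoint(self):
        rule = select_cutoff([10, 20], [30, 40], ASD_BELOW)
        assert rule.cutoff_value == 25.0
        assert rule.meets(20) and not rule.meets(30)

    def test_partial_overlap(self):
        """Exhaustive sweep: J is maximised at the 10/30 midpoint with J=0.5."""
        rule = select_cutoff([10, 40], [30, 50], ASD_BELOW)
        assert rule.cutoff_value == 20.0

    def test_identical_groups_most_specific(self):
        rule = select_cutoff([1, 2, 3], [1, 2, 3], ASD_BELOW)
        # J=0 everywhere; the tie-break picks full specificity (no TD meets it)
        assert not any(rule.meets(v) for v in [1, 2, 3])

    def test_direction_above(self):
        rule = select_cutoff([30, 40], [10, 20], ASD_ABOVE)
        assert rule.cutoff_value == 25.0
        assert rule.meets(30) and not rule.meets(20)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=10),
        st.lists(st.integers(0, 100), min_size=2, max_size=10),
    )
    def test_youden_optimality_over_thresholds(self, xs, ys):
        """No strict-inequality threshold beats the selected one on J."""
        rule = select_cutoff(xs, ys, ASD_BELOW)
        sens = np.mean([v < rule.cutoff_value for v in xs])
        spec = np.mean([v >= rule.cutoff_value for v in ys])
        best_j = sens + spec - 1
        for c in np.unique(xs + ys).astype(float):
            for cand in (c - 0.5, c + 0.5):
                j = np.mean([v < cand for v in xs]) + np.mean([v >= cand for v in ys]) - 1
                assert j <= best_j + 1e-12


class TestPanelSelection:
    def test_published_large_effect_panel(self, fixtures, battery):
        comps = compare_from_summary(fixtures.table2, battery)
        assert select_panel(comps, d_min=0.8, battery=battery) == [
            "B.eyes",
            "D.eyes",
            "G.people",
        ]

    def test_zero_threshold_keeps_all_primary_aois(self, fixtures, battery):
        comps = compare_from_summary(fixtures.table2, battery)
        panel = select_panel(comps, d_min=0.0, battery=battery)
        assert len(panel) == 8
        assert panel[0] == "A.eyes" and panel[-1] == "H.geometry"

    def test_unreachable_threshold_raises(self, fixtures, battery):
        comps = compare_from_summary(fixtures.table2, battery)
        with pytest.raises(PanelEmptyError):
            select_panel(comps, d_min=2.0, battery=battery)


class TestCountItemsMet:
    RULES = [
        CutoffRule("B.eyes", ASD_BELOW, 81),
        CutoffRule("D.eyes", ASD_BELOW, 32),
        CutoffRule("G.people", ASD_BELOW, 57),
    ]

    def test_value_above_cutoff_not_met(self):
        assert count_items_met({"B.eyes": 90.0, "D.eyes": 40, "G.people": 60}, self.RULES) == 0

    def test_boundary_is_strict(self):
        assert count_items_met({"B.eyes": 81.0, "D.eyes": 32.0, "G.people": 57.0}, self.RULES) == 0
        assert count_items_met({"B.eyes": 80.9, "D.eyes": 31.9, "G.people": 56.9}, self.RULES) == 3

    def test_missing_item_raises(self):
        with pytest.raises(InsufficientDataError):
            count_items_met({"B.eyes": 10.0}, self.RULES)

    def test_printed_cutoffs_loadable(self, fixtures):
        rules = rules_from_table4(fixtures.table4, ["B.eyes", "D.eyes", "G.people"])
        assert [r.printed for r in rules] == ["<81", "<32", "<57"]


class TestSweep:
    def test_published_counts_reproduce_discriminant_rows(self, fixtures):
        """The printed breakdown implies the printed sensitivity/specificity."""
        counts = fixtures.panel_counts(["B.eyes", "D.eyes", "G.people"])
        sweep = sweep_from_counts(counts)
        by_k = {m.k: m for m in sweep}
        assert by_k[2].tp == 17 and by_k[2].sensitivity == pytest.approx(17 / 21)
        assert by_k[2].tn == 28 and by_k[2].specificity == pytest.approx(28 / 35)
        assert by_k[3].plr == pytest.approx((9 / 21) / (3 / 35))  # exactly 5
        assert by_k[3].plr == pytest.approx(5.0)

    def test_reported_rounding_convention(self, fixtures):
        """One-decimal PLR/NLR recomputed from the rounded percentages."""
        counts = fixtures.panel_counts(["B.eyes", "D.eyes", "G.people"])
        sweep = sweep_from_counts(counts)
        t6 = fixtures.table6.set_index("k").loc[lambda d: d["panel"] == "large_effect"]
        for m in sweep:
            row = t6.loc[m.k]
            assert m.sensitivity_pct == row["sensitivity_pct"]
            assert m.specificity_pct == row["specificity_pct"]
            assert m.plr_reported == row["plr"]
            assert m.nlr_reported == row["nlr"]

    def test_perfect_classifier_infinite_plr(self):
        counts = {frozenset(): (0, 10), frozenset({"a"}): (10, 0)}
        (m,) = sweep_from_counts(counts)
        assert m.specificity == 1.0
        assert math.isinf(m.plr)
        assert math.isinf(m.plr_reported)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), min_size=4, max_size=4))
    def test_monotone_in_count_threshold(self, cells):
        """Sensitivity never rises and specificity never falls as k grows."""
        items = ["i1", "i2"]
        subsets = [frozenset(), frozenset({"i1"}), frozenset({"i2"}), frozenset(items)]
        counts = dict(zip(subsets, cells))
        if sum(a for a, _ in cells) == 0 or sum(t for _, t in cells) == 0:
            return
        sweep = sweep_from_counts(counts)
        for a, b in zip(sweep, sweep[1:]):
            assert b.sensitivity <= a.sensitivity + 1e-12
            assert b.specificity >= a.specificity - 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), min_size=4, max_size=4))
    def test_likelihood_ratio_consistency(self, cells):
        """plr > 1 iff sens + spec > 1 iff nlr < 1, whenever 0 < spec < 1."""
        items = ["i1", "i2"]
        subsets = [frozenset(), frozenset({"i1"}), frozenset({"i2"}), frozenset(items)]
        counts = dict(zip(subsets, cells))
        if sum(a for a, _ in cells) == 0 or sum(t for _, t in cells) == 0:
            return
        for m in sweep_from_counts(counts):
            if 0 < m.specificity < 1:
                j_positive = m.sensitivity + m.specificity > 1
                assert (m.plr > 1) == j_positive
                assert (m.nlr < 1) == j_positive


class TestRounding:
    @pytest.mark.parametrize(
        "x,want",
        [(4.05, 4.1), (0.25, 0.3), (-4.05, -4.1), (2.04, 2.0), (0.951, 1.0)],
    )
    def test_half_away_from_zero(self, x, want):
        assert round_half_away(x, 1) == want
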