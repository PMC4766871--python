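"""IST scoring, questionnaire k estimation and the group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reflectim.metrics import (ISTTrial, MCQItem, PointSchedule, group_tests,
                               ist_error_type, ist_p_correct, ist_points,
                               kirby_k, load_mcq_items, mixed_anova_2x2,
                               remove_outliers, score_ist_frame)

from oracles import (oracle_exact_ranksum_p, oracle_ist_p_correct,
                     oracle_mixed_anova_2x2, oracle_pooled_t)


def make_trial(n_majority=15, opened_cells=((0, 0),), choice=None,
               condition="fixed_win", majority="R"):
    minority = "B" if majority == "R" else "R"
    grid = majority * n_majority + minority * (25 - n_majority)
    trial_choice = choice or majority
    return ISTTrial(grid=grid, opened=tuple(opened_cells), choice=trial_choice,
                    condition=condition)


def open_n(n):
    return tuple((i // 5, i % 5) for i in range(n))


class TestPCorrect:
    def test_fully_revealed_board_is_certain(self):
        trial = make_trial(opened_cells=open_n(25))
        assert ist_p_correct(trial) == 1.0

    def test_single_box_tail_probability(self):
        trial = make_trial(opened_cells=((0, 0),), choice="R")
        # P(Bin(24, 0.5) >= 12), the chosen colour needing 12 of 24 coins
        expected = sum(math.comb(24, j) for j in range(12, 25)) / 2 ** 24
        assert ist_p_correct(trial) == pytest.approx(expected, abs=1e-12)
        assert ist_p_correct(trial) == pytest.approx(0.58059, abs=1e-5)

    def test_thirteen_of_chosen_colour_guarantees_majority(self):
        trial = make_trial(n_majority=13, opened_cells=open_n(13))
        assert ist_p_correct(trial) == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n_open = int(rng.integers(13, 25))  # u <= 12 keeps 2^u enumerable
            n_majority = int(rng.integers(13, 18))
            cells = open_n(n_open)
            trial = make_trial(n_majority=n_majority, opened_cells=cells,
                               choice=rng.choice(["R", "B"]))
            m = sum(1 for c in trial.opened_colours if c == trial.choice)
            assert ist_p_correct(trial) == pytest.approx(
                oracle_ist_p_correct(n_open, m), abs=1e-12
            )

    def test_monotone_in_opened_chosen_colour(self):
        grid = "R" * 15 + "B" * 10
        prev = 0.0
        for n in range(1, 16):
            trial = ISTTrial(grid=grid, opened=open_n(n), choice="R")
            p = ist_p_correct(trial)
            assert p >= prev - 1e-12
            prev = p
        assert prev == 1.0  # 15 >= 13 chosen cells seen


class TestPointsAndErrors:
    def test_fixed_win_ignores_boxes(self):
        assert ist_points(make_trial(opened_cells=open_n(20))) == 100

    def test_decreasing_win_schedule(self):
        trial = make_trial(opened_cells=open_n(5), condition="decreasing_win")
        assert ist_points(trial) == 200

    def test_decreasing_win_floor(self):
        trial = make_trial(opened_cells=open_n(25), condition="decreasing_win")
        assert ist_points(trial) == 0

    def test_incorrect_choice_penalty(self):
        trial = make_trial(opened_cells=open_n(3), choice="B")
        assert ist_points(trial) == -100
        assert ist_points(trial, PointSchedule(penalty=50)) == -50

    def test_correct_choice_has_no_error(self):
        assert ist_error_type(make_trial()) == "none"

    def test_error_classification_all_three_cell_colourings(self):
        """Enumerate every colouring of 3 opened cells and check the split
        between sampling and discrimination errors."""
        for colours in itertools.product("RB", repeat=3):
            n_r = colours.count("R")
            # board: B majority 13; opened cells arranged to show `colours`
            cells = "".join(colours)
            rest = "R" * (12 - n_r) + "B" * (13 - (3 - n_r))
            grid = cells + rest
            trial = ISTTrial(grid=grid, opened=open_n(3), choice="R")
            err = ist_error_type(trial)  # true majority is B, chose R
            opened_majority_r = n_r > 3 - n_r
            if opened_majority_r:
                assert err == "sampling_error"
            elif n_r == 3 - n_r:  # impossible for 3 cells, kept for clarity
                assert err == "sampling_error"
            else:
                assert err == "discrimination_error"

    def test_score_frame_roundtrip(self):
        frame = pd.DataFrame([
            dict(subject_id="s1", trial_index=0, condition="decreasing_win",
                 grid="R" * 15 + "B" * 10,
                 opened="0,0;0,1;0,2", choice="R"),
        ])
        scored = score_ist_frame(frame)
        assert scored.loc[0, "points"] == 220
        assert scored.loc[0, "boxes_opened"] == 3
        assert scored.loc[0, "error_type"] == "none"


class TestKirby:
    def test_all_delayed_assigns_smallest_candidate(self):
        items = load_mcq_items()
        k, consistency = kirby_k(["delayed"] * 27, items)
        assert consistency == 1.0
        assert k == pytest.approx(min(it.k_indiff for it in items))

    def test_deterministic_chooser_recovers_k_bracket(self):
        items = load_mcq_items()
        boundaries = sorted(it.k_indiff for it in items)
        true_k = 1 / 30  # indifference k of a 50-now vs 100-in-30-days item
        responses = [
            "immediate" if true_k > it.k_indiff else "delayed" for it in items
        ]
        k, consistency = kirby_k(responses, items)
        assert consistency == 1.0
        below = [b for b in boundaries if b < true_k]
        above = [b for b in boundaries if b >= true_k]
        assert (below[-1] if below else 0.0) < true_k <= k <= above[0]

    def test_random_responses_stay_in_candidate_range(self, rng):
        items = load_mcq_items()
        boundaries = [it.k_indiff for it in items]
        for _ in range(10):
            responses = [str(rng.choice(["immediate", "delayed"])) for _ in items]
            k, consistency = kirby_k(responses, items)
            assert consistency <= 1.0
            assert min(boundaries) <= k <= max(boundaries)

    def test_item_order_invariance(self, rng):
        items = load_mcq_items()
        responses = ["immediate" if 0.02 > it.k_indiff else "delayed" for it in items]
        k1, c1 = kirby_k(responses, items)
        perm = rng.permutation(len(items))
        k2, c2 = kirby_k([responses[i] for i in perm], [items[i] for i in perm])
        assert (k1, c1) == (k2, c2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            kirby_k(["delayed"] * 5, load_mcq_items())


class TestOutliers:
    def test_identical_values_keep_everything(self):
        kept, removed = remove_outliers({"HV": pd.Series([3.0] * 6)})
        assert removed == [] and len(kept["HV"]) == 6

    def test_planted_extreme_value(self):
        values = pd.Series([0.0] * 9 + [100.0], index=[f"s{i}" for i in range(10)])
        mean, sd = values.mean(), values.std(ddof=1)
        expect_removed = abs(100.0 - mean) > 3 * sd
        kept, removed = remove_outliers({"BD": values})
        assert (removed == ["s9"]) == expect_removed

    def test_normal_samples_rarely_flagged(self):
        clean = 0
        for rep in range(40):
            rng = np.random.default_rng(rep)
            values = pd.Series(rng.standard_normal(30))
            _, removed = remove_outliers({"HV": values})
            clean += not removed
        assert clean >= 38  # ~P(all 30 within 3 SD) > 0.95


class TestGroupStats:
    def outcome_table(self, hv, bd, col="beads_draws_mean"):
        rows = [dict(subject_id=f"h{i}", group="HV", **{col: v})
                for i, v in enumerate(hv)]
        rows += [dict(subject_id=f"b{i}", group="BD", **{col: v})
                 for i, v in enumerate(bd)]
        return pd.DataFrame(rows)

    def test_identical_groups_null_statistics(self):
        table = self.outcome_table([1, 2, 3], [1, 2, 3])
        res = group_tests(table)
        t_row = res[res["test"] == "t_beads_draws"].iloc[0]
        assert t_row["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_pooled_t(self):
        # raw values chosen so the sqrt transform is the identity
        table = self.outcome_table([1, 4, 9], [16, 25, 36])
        res = group_tests(table)
        row = res[res["test"] == "t_beads_draws"].iloc[0]
        assert row["statistic"] == pytest.approx(-3.674, abs=5e-4)
        assert row["df"] == 4

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 3)])
    def test_pooled_t_matches_hand_formula(self, rng, n1, n2):
        x = list(rng.normal(size=n1))
        y = list(rng.normal(size=n2) + 0.5)
        res = stats.ttest_ind(x, y, equal_var=True)
        t_ref, df_ref = oracle_pooled_t(x, y)
        assert res.statistic == pytest.approx(t_ref, abs=1e-10)
        assert res.df == df_ref

    def test_exact_wilcoxon_small_sample(self):
        p = stats.mannwhitneyu([1, 2], [3, 4], alternative="two-sided",
                               method="exact").pvalue
        assert p == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5)])
    def test_wilcoxon_matches_enumeration(self, rng, n1, n2):
        x = list(rng.normal(size=n1))
        y = list(rng.normal(size=n2))
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(oracle_exact_ranksum_p(x, y), abs=1e-10)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 5)])
    def test_mixed_anova_matches_ss_decomposition(self, rng, n1, n2):
        groups = {
            "HV": [tuple(rng.normal(size=2)) for _ in range(n1)],
            "BD": [tuple(rng.normal(size=2) + 0.3) for _ in range(n2)],
        }
        rows = []
        for g, subs in groups.items():
            for i, (v1, v2) in enumerate(subs):
                rows += [
                    dict(subject_id=f"{g}{i}", group=g, condition="fixed", value=v1),
                    dict(subject_id=f"{g}{i}", group=g, condition="cost", value=v2),
                ]
        aov = mixed_anova_2x2(pd.DataFrame(rows))
        ref = oracle_mixed_anova_2x2(groups)
        by_source = dict(zip(aov["Source"], aov["F"]))
        assert by_source["group"] == pytest.approx(ref["f_group"], rel=1e-9)
        assert by_source["condition"] == pytest.approx(ref["f_cond"], rel=1e-9)
        assert by_source["Interaction"] == pytest.approx(ref["f_inter"], rel=1e-9)

    def test_identical_groups_zero_interaction(self):
        subs = [(1.0, 2.0), (2.0, 4.0), (3.0, 1.0)]
        ref = oracle_mixed_anova_2x2({"HV": subs, "BD": subs})
        assert ref["f_inter"] == pytest.approx(0.0, abs=1e-12)
        assert ref["f_group"] == pytest.approx(0.0, abs=1e-12)

    def test_log10_transform_rejects_nonpositive_k(self):
        table = self.outcome_table([0.1, 0.2, 0.3], [0.4, -0.5, 0.6], col="k_value")
        with pytest.raises(ValueError, match="k_value"):
            group_tests(table)

    def test_transform_leaves_original_columns(self):
        table = self.outcome_table([1, 2, 3], [4, 5, 6])
        original = table["beads_draws_mean"].copy()
        group_tests(table)
        pd.testing.assert_series_equal(table["beads_draws_mean"], original)
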