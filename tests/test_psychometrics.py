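import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recallpsych.config import AnalysisConfig
from recallpsych.psychometrics import (
    aggregate_indices,
    average_over_visits,
    compute_index_table,
    condition_differences,
    corrected_item_total,
    difficulty_index,
    discrimination_index,
)


class TestDifficultyIndex:
    @pytest.mark.parametrize(
        "vec,expected",
        [(np.ones(50), 1.0), (np.zeros(17), 0.0), ([1] * 30 + [0] * 20, 0.6)],
    )
    def test_exact_fractions(self, vec, expected):
        assert difficulty_index(vec) == pytest.approx(expected, abs=0)

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            difficulty_index([])

    def test_non_binary_raises(self):
        with pytest.raises(ValueError):
            difficulty_index([0, 1, 2])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_participant_order_and_monotone(self, vec):
        rng = np.random.default_rng(0)
        assert difficulty_index(vec) == difficulty_index(rng.permutation(vec))
        if 0 in vec:
            raised = list(vec)
            raised[raised.index(0)] = 1
            assert difficulty_index(raised) >= difficulty_index(vec)


def _pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return np.corrcoef(x, y)[0, 1]


class TestDiscriminationIndex:
    def test_hand_oracle_two_over_root_five(self):
        # item x = (1,1,0,0) against rest-scores (3,2,1,0): r = 2/sqrt(5)
        rest = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]])
        x = np.array([[1], [1], [0], [0]])
        matrix = np.hstack([x, rest])
        assert discrimination_index(matrix, 0) == pytest.approx(2 / np.sqrt(5), abs=1e-12)

    def test_twin_items_correlate_perfectly(self):
        col = np.array([1, 0, 1, 0, 1])
        matrix = np.column_stack([col, col])
        assert discrimination_index(matrix, 0) == pytest.approx(1.0)

    def test_constant_item_is_undefined_not_zero(self):
        matrix = np.array([[1, 0, 1], [1, 1, 0], [1, 1, 1], [1, 0, 0]])
        assert np.isnan(discrimination_index(matrix, 0))

    def test_fewer_than_three_participants_raises(self):
        with pytest.raises(ValueError, match="3 participants"):
            corrected_item_total(np.array([[1, 0], [0, 1]]))

    def test_matches_direct_pearson_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n, m = rng.integers(3, 15), rng.integers(2, 12)
            matrix = rng.integers(0, 2, size=(n, m)).astype(float)
            rs = corrected_item_total(matrix)
            for j in range(m):
                rest = matrix.sum(axis=1) - matrix[:, j]
                if matrix[:, j].std() == 0 or rest.std() == 0:
                    assert np.isnan(rs[j])
                else:
                    assert rs[j] == pytest.approx(_pearson(matrix[:, j], rest), abs=1e-12)

    def test_invariant_to_affine_rescaling_of_rest_scores(self):
        rng = np.random.default_rng(7)
        matrix = rng.integers(0, 2, size=(20, 6)).astype(float)
        x = matrix[:, 0]
        rest = matrix[:, 1:].sum(axis=1)
        assert _pearson(x, rest) == pytest.approx(_pearson(x, 3.7 * rest + 11.0), abs=1e-12)

    def test_pure_noise_item_discriminates_near_zero(self, taxonomy):
        rng = np.random.default_rng(1234)
        n = 2000
        ability = rng.normal(size=n)
        real = (rng.random((n, 49)) < 1 / (1 + np.exp(-ability[:, None]))).astype(float)
        noise = rng.integers(0, 2, size=(n, 1)).astype(float)
        matrix = np.hstack([noise, real])
        assert abs(discrimination_index(matrix, 0)) < 0.1


class TestComputeIndexTable:
    def test_row_cardinality(self, small_cohort):
        responses, _, _ = small_cohort
        table = compute_index_table(responses)
        visits = responses["visit"].nunique()
        assert len(table) == 50 * 2 * visits
        assert table["difficulty"].between(0, 1).all()
        defined = table["discrimination"].dropna()
        assert defined.between(-1, 1).all()
        assert (table["n_respondents"] > 0).all()

    def test_qc_flags_follow_acceptability_bands(self, small_cohort):
        responses, _, _ = small_cohort
        table = compute_index_table(responses)
        hard = table[table.difficulty > 0.8]
        assert not hard["qc_difficulty_ok"].any()
        good = table[(table.difficulty >= 0.2) & (table.difficulty <= 0.8)]
        assert good["qc_difficulty_ok"].all()
        assert (table.loc[table.discrimination >= 0.2, "qc_discrimination_ok"]).all()

    def test_small_group_skipped_with_warning(self, small_cohort, caplog):
        responses, _, _ = small_cohort
        ids = responses["participant_id"].unique()
        grouping = {pid: ("tiny" if i < 2 else "rest") for i, pid in enumerate(ids)}
        table = compute_index_table(responses, grouping=grouping)
        assert set(table["group"]) == {"rest"}

    def test_null_group_split_converges_to_common_expectation(self):
        """With zero amyloid effects both groups estimate the same difficulty."""
        from recallpsych.simulate import generate_cohort, paper_like_params, with_overrides

        params = with_overrides(
            paper_like_params(n_participants=2000, n_visits=1, seed=2718),
            amyloid_effects={},
            pet_fraction=1.0,
        )
        responses, participants, truth = generate_cohort(params)
        grouping = participants.set_index("participant_id")["amyloid_status"]
        table = compute_index_table(responses, grouping=grouping)
        expected = truth.expected.query("group == 'negative'").set_index(
            ["story", "item", "condition"]
        )["expected_difficulty"]
        merged = table.set_index(["story", "item", "condition"])
        for group in ("positive", "negative"):
            sub = merged[merged.group == group]
            err = (sub["difficulty"] - expected.loc[sub.index]).abs()
            # binomial tolerance at the smaller (23%) group size
            assert err.max() < 0.08
            assert err.mean() < 0.02


class TestAggregates:
    def test_single_item_stratum_mean_equals_item_sd_zero(self):
        table = pd.DataFrame(
            {
                "group": ["all"] * 2,
                "condition": ["immediate"] * 2,
                "visit": [1, 1],
                "story": ["A", "A"],
                "item": [3, 9],
                "difficulty": [0.7, 0.4],
                "discrimination": [0.3, 0.2],
            }
        )
        agg = aggregate_indices(table, "serial_position")
        primacy = agg[agg.serial_position == "primacy"].iloc[0]
        assert primacy["difficulty_mean"] == 0.7
        assert primacy["difficulty_sd"] == 0.0

    def test_category_aggregates_use_full_membership(self, small_cohort, taxonomy):
        responses, _, _ = small_cohort
        table = compute_index_table(responses)
        agg = aggregate_indices(table, "lexical_category", taxonomy)
        one = agg[(agg.condition == "immediate") & (agg.visit == 1)]
        counts = one.set_index("lexical_category")["n_items"].to_dict()
        assert counts == {"proper_name": 9, "verb": 14, "number": 4, "other": 23}

    def test_mean_of_strata_means_differs_from_grand_mean_when_unbalanced(self):
        # 1 primacy item at 0.9 and 3 middle items at 0.1: grand mean 0.3,
        # mean of stratum means 0.5
        table = pd.DataFrame(
            {
                "group": ["all"] * 4,
                "condition": ["immediate"] * 4,
                "visit": [1] * 4,
                "story": ["A"] * 4,
                "item": [1, 9, 10, 11],
                "difficulty": [0.9, 0.1, 0.1, 0.1],
                "discrimination": [0.2] * 4,
            }
        )
        agg = aggregate_indices(table, "serial_position")
        strata_mean = agg["difficulty_mean"].mean()
        grand = table["difficulty"].mean()
        assert strata_mean == pytest.approx(0.5)
        assert grand == pytest.approx(0.3)
        assert strata_mean != grand


class TestConditionDifferences:
    def _mini_table(self):
        rows = []
        for cond, diff in (("immediate", 0.8), ("delayed", 0.7)):
            rows.append(
                {
                    "group": "all", "condition": cond, "visit": 1, "story": "A",
                    "item": 1, "difficulty": diff, "discrimination": 0.3 if cond == "immediate" else 0.4,
                }
            )
        return pd.DataFrame(rows)

    def test_signs_match_reporting_conventions(self):
        out = condition_differences(self._mini_table())
        row = out.iloc[0]
        assert row["diff_difficulty"] == pytest.approx(0.1)  # harder at delay
        assert row["plot_difficulty_change"] == pytest.approx(-0.1)  # plotted convention
        assert row["diff_discrimination"] == pytest.approx(0.1)  # more discriminating at delay

    def test_identical_conditions_give_zero(self):
        t = self._mini_table()
        t.loc[t.condition == "delayed", ["difficulty", "discrimination"]] = [0.8, 0.3]
        out = condition_differences(t)
        assert out["diff_difficulty"].iloc[0] == 0.0
        assert out["diff_discrimination"].iloc[0] == 0.0

    def test_rows_missing_a_condition_are_omitted(self, small_cohort):
        responses, _, _ = small_cohort
        table = compute_index_table(responses)
        # drop one item's delayed rows entirely
        mask = (table.story == "A") & (table.item == 1) & (table.condition == "delayed")
        out = condition_differences(table[~mask])
        assert not ((out.story == "A") & (out.item == 1)).any()

    def test_differences_are_exact_arithmetic(self, small_cohort):
        responses, _, _ = small_cohort
        table = compute_index_table(responses)
        out = condition_differences(table)
        piv = table.pivot_table(
            index=["group", "visit", "story", "item"], columns="condition", values="difficulty"
        )
        joined = out.set_index(["group", "visit", "story", "item"])
        expect = piv["immediate"] - piv["delayed"]
        assert np.allclose(joined["diff_difficulty"], expect.loc[joined.index], atol=1e-12)


def test_average_over_visits_is_unweighted(self=None):
    table = pd.DataFrame(
        {
            "group": ["all"] * 2,
            "condition": ["immediate"] * 2,
            "visit": [1, 2],
            "story": ["A", "A"],
            "item": [1, 1],
            "difficulty": [0.6, 0.8],
            "discrimination": [0.1, 0.3],
            "n_respondents": [100, 10],
        }
    )
    out = average_over_visits(table)
    assert out["difficulty"].iloc[0] == pytest.approx(0.7)  # not weighted by n
    assert out["discrimination"].iloc[0] == pytest.approx(0.2)
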