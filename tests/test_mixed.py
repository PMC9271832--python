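import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from recallpsych.mixed import condition_change_model, fit_index_model, posthoc_pairwise
from recallpsych.psychometrics import compute_index_table, condition_differences
from recallpsych.taxonomy import assign_serial_position


def _synthetic_index_table(rng, n_visits=3, category_effects=None, story_effect=0.0,
                           item_sd=0.4, noise_sd=0.25, mu=0.1, taxonomy=None):
    """Index values drawn from the model's own data-generating process."""
    category_effects = category_effects or {}
    rows = []
    for (story, item), cat in taxonomy.category_map.items():
        u = rng.normal(0, item_sd)
        for visit in range(1, n_visits + 1):
            z = (
                mu
                + u
                + category_effects.get(cat, 0.0)
                + (story_effect if story == "B" else 0.0)
                + rng.normal(0, noise_sd)
            )
            rows.append(
                {"story": story, "item": item, "visit": visit,
                 "condition": "immediate", "difficulty": float(expit(z))}
            )
    return pd.DataFrame(rows)


class TestFitIndexModel:
    def test_single_visit_equals_fixed_effects_oracle(self, taxonomy):
        rng = np.random.default_rng(11)
        table = _synthetic_index_table(rng, n_visits=1, taxonomy=taxonomy)
        fit = fit_index_model(table, taxonomy, response="difficulty")
        assert fit.random_intercept_variance == 0.0
        assert "fixed-effects" in fit.note

        # independent oracle: direct least-squares on the hand-built design
        df = table.copy()
        df["category"] = [taxonomy.category_map[(s, i)] for s, i in zip(df.story, df.item)]
        df["position"] = [assign_serial_position(i) for i in df["item"]]
        z = logit(np.clip(df["difficulty"].to_numpy(), 0.005, 0.995))
        X = [np.ones(len(df))]
        names = ["Intercept"]
        for col, ref, levels in (
            ("story", "A", ["B"]),
            ("category", "proper_name", ["verb", "number", "other"]),
            ("position", "primacy", ["middle", "recency"]),
        ):
            for level in levels:
                X.append((df[col] == level).to_numpy(float))
                names.append(level)
        beta, *_ = np.linalg.lstsq(np.column_stack(X), z, rcond=None)
        oracle = dict(zip(names, beta))

        coef = {k: v[0] for k, v in fit.coefficients.items()}
        assert coef["Intercept"] == pytest.approx(oracle["Intercept"], abs=1e-8)
        assert coef["C(story, Treatment('A'))[T.B]"] == pytest.approx(oracle["B"], abs=1e-8)
        assert coef["C(category, Treatment('proper_name'))[T.other]"] == pytest.approx(
            oracle["other"], abs=1e-8
        )
        assert coef["C(position, Treatment('primacy'))[T.recency]"] == pytest.approx(
            oracle["recency"], abs=1e-8
        )

    def test_row_permutation_leaves_estimates_unchanged(self, taxonomy):
        rng = np.random.default_rng(21)
        table = _synthetic_index_table(rng, taxonomy=taxonomy)
        fit1 = fit_index_model(table, taxonomy)
        fit2 = fit_index_model(table.sample(frac=1.0, random_state=5), taxonomy)
        for term, (e1, *_), in fit1.coefficients.items():
            assert fit2.coefficients[term][0] == pytest.approx(e1, abs=1e-8)

    def test_reference_levels_and_ci_ordering(self, taxonomy):
        rng = np.random.default_rng(31)
        fit = fit_index_model(_synthetic_index_table(rng, taxonomy=taxonomy), taxonomy)
        # treatment coding against story A / proper_name / primacy
        assert "C(story, Treatment('A'))[T.B]" in fit.coefficients
        assert "C(category, Treatment('proper_name'))[T.verb]" in fit.coefficients
        assert "C(position, Treatment('primacy'))[T.middle]" in fit.coefficients
        for est, lo, hi, p in fit.coefficients.values():
            assert lo <= est <= hi
            assert 0.0 <= p <= 1.0
        for p in fit.omnibus.values():
            assert 0.0 <= p <= 1.0

    def test_nesting_full_likelihood_dominates_reduced(self, taxonomy):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(41)
        table = _synthetic_index_table(rng, n_visits=1, taxonomy=taxonomy)
        full = fit_index_model(table, taxonomy)
        # oracle: dropping any factor cannot raise the ML likelihood
        df = table.copy()
        df["category"] = [taxonomy.category_map[(s, i)] for s, i in zip(df.story, df.item)]
        df["position"] = [assign_serial_position(i) for i in df["item"]]
        df["z"] = logit(np.clip(df["difficulty"], 0.005, 0.995))
        for dropped in (
            "C(category, Treatment('proper_name')) + C(position, Treatment('primacy'))",
            "C(story, Treatment('A')) + C(position, Treatment('primacy'))",
            "C(story, Treatment('A')) + C(category, Treatment('proper_name'))",
        ):
            reduced = smf.ols(f"z ~ {dropped}", data=df).fit()
            assert full.log_likelihood >= reduced.llf - 1e-8
        assert all(np.isfinite(p) for p in full.omnibus.values())

    def test_injected_category_deficit_is_detected(self, taxonomy):
        hits_omni = hits_contrast = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            table = _synthetic_index_table(
                rng, category_effects={"other": -0.8}, taxonomy=taxonomy
            )
            fit = fit_index_model(table, taxonomy)
            hits_omni += fit.omnibus["lexical_category"] < 0.05
            pn_other = [c for c in fit.posthoc if c.label == "proper_name vs other"]
            hits_contrast += bool(pn_other) and pn_other[0].p_value < 0.05
        assert hits_omni >= 0.9 * n_rep
        assert hits_contrast >= 0.9 * n_rep


class TestPosthoc:
    def test_contrast_counts(self, taxonomy):
        rng = np.random.default_rng(51)
        fit = fit_index_model(_synthetic_index_table(rng, taxonomy=taxonomy), taxonomy)
        assert len(posthoc_pairwise(fit, "lexical_category")) == 6  # C(4,2)
        assert len(posthoc_pairwise(fit, "serial_position")) == 3
        assert len(posthoc_pairwise(fit, "story")) == 1

    def test_contrast_antisymmetry(self, taxonomy):
        rng = np.random.default_rng(61)
        fit = fit_index_model(_synthetic_index_table(rng, taxonomy=taxonomy), taxonomy)
        for c in posthoc_pairwise(fit, "lexical_category"):
            assert c.reversed().estimate == pytest.approx(-c.estimate)
            assert c.p_value <= c.p_tukey + 1e-12  # Tukey never less conservative


class TestConditionChangeModel:
    def _diff_frame(self, rng, n_visits=2, shift=0.05, story_extra=0.0):
        rows = []
        for story in "AB":
            for item in range(1, 26):
                for visit in range(1, n_visits + 1):
                    d = shift + (story_extra if story == "B" else 0.0) + rng.normal(0, 0.03)
                    rows.append(
                        {"group": "all", "visit": visit, "story": story, "item": item,
                         "diff_difficulty": d}
                    )
        return pd.DataFrame(rows)

    def test_identically_zero_differences(self):
        rng = np.random.default_rng(71)
        df = self._diff_frame(rng)
        df["diff_difficulty"] = 0.0
        fit = condition_change_model(df)
        assert fit.coefficients["Intercept"][0] == 0.0
        assert fit.coefficients["C(story, Treatment('A'))[T.B]"][0] == 0.0

    def test_recovers_mean_change_and_tests_intercept(self):
        rng = np.random.default_rng(81)
        fit = condition_change_model(self._diff_frame(rng, shift=0.05))
        est, lo, hi, p = fit.coefficients["Intercept"]
        assert est == pytest.approx(0.05, abs=0.015)
        assert p < 0.001

    def test_story_neutral_shift_gives_centered_story_coefficient(self):
        ests = []
        for rep in range(40):
            rng = np.random.default_rng(2000 + rep)
            fit = condition_change_model(self._diff_frame(rng, shift=0.05))
            ests.append(fit.coefficients["C(story, Treatment('A'))[T.B]"][0])
        assert abs(np.mean(ests)) < 0.005

    def test_story_specific_shift_detected(self):
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            fit = condition_change_model(
                self._diff_frame(rng, shift=0.02, story_extra=0.04)
            )
            hits += fit.coefficients["C(story, Treatment('A'))[T.B]"][3] < 0.05
        assert hits >= 0.9 * n_rep

    def test_pipeline_differences_accepted(self, small_cohort, taxonomy):
        responses, _, _ = small_cohort
        diffs = condition_differences(compute_index_table(responses))
        fit = condition_change_model(diffs)
        assert fit.converged
        assert fit.coefficients["Intercept"][0] > 0  # harder at delay
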