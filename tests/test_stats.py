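"""Tuning statistics: condition summaries, the dummy-coded GLM against a
textbook oracle, response classification and the category comparison."""

import numpy as np
import pytest
from helpers import pooled_two_sample_t
from hypothesis import given, settings
from hypothesis import strategies as st

from numecog.stats import (
    classify_electrode,
    compare_with_categories,
    condition_summary,
    fit_condition_glm,
)


def scalars_for(means: dict[str, float], n: int, rng, sd: float = 1.0):
    conds, vals = [], []
    for cond, mu in means.items():
        conds += [cond] * n
        vals += list(mu + sd * rng.standard_normal(n))
    return np.array(vals), np.array(conds)


class TestConditionSummary:
    def test_closed_form_mean_and_sem(self):
        summary, pref = condition_summary([1.0, 3.0, 0.0, 0.0], ["1", "1", "2", "2"])
        row = summary.set_index("condition").loc["1"]
        assert row["mean"] == 2.0 and row["sem"] == 1.0
        assert pref == "1"

    def test_tie_breaks_to_lower_numerosity(self):
        _, pref = condition_summary([1.0, 1.0, 1.0, 1.0], ["7", "7", "2", "2"])
        assert pref == "2"

    def test_condition_with_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="'2'"):
            condition_summary([1.0, 2.0, 3.0], ["1", "1", "2"])


class TestConditionGlm:
    def test_residual_df_bookkeeping(self, rng):
        # 180 kept trials over 8 conditions leave 172 residual df
        conds = np.repeat([str(n) for n in (1, 2, 3, 4, 5, 6, 7)], 20).tolist() + ["20"] * 40
        fit = fit_condition_glm(rng.standard_normal(180), np.array(conds))
        assert fit.residual_df == 172
        assert (fit.glm["df"] == 172).all()

    def test_identical_groups_give_zero_t(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        conds = np.array(["1", "1", "1", "2", "2", "2"])
        fit = fit_condition_glm(y, conds, reference="1")
        term = fit.glm.set_index("term").loc["2"]
        assert term["t"] == pytest.approx(0.0, abs=1e-12)

    def test_two_condition_t_equals_pooled_oracle(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        fit = fit_condition_glm(
            np.concatenate([a, b]), np.array(["1"] * 3 + ["2"] * 3), reference="1"
        )
        t_glm = float(fit.glm.set_index("term").loc["2", "t"])
        assert t_glm == pytest.approx(pooled_two_sample_t(a, b), abs=1e-9)

    def test_oracle_equivalence_on_random_fixtures(self, rng):
        for _ in range(100):
            na, nb = rng.integers(3, 30, size=2)
            a = rng.standard_normal(na) * rng.uniform(0.5, 2.0)
            b = rng.standard_normal(nb) + rng.uniform(-1, 1)
            fit = fit_condition_glm(
                np.concatenate([a, b]),
                np.array(["1"] * na + ["2"] * nb),
                reference="1",
            )
            t_glm = float(fit.glm.set_index("term").loc["2", "t"])
            t_ref = pooled_two_sample_t(a, b)
            assert t_glm == pytest.approx(t_ref, abs=max(1e-9, abs(t_ref) * 1e-9))

    @given(k=st.integers(2, 6), n=st.integers(3, 12))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_df_equals_trials_minus_conditions(self, k, n):
        rng = np.random.default_rng(1000 * k + n)
        conds = np.repeat([str(i + 1) for i in range(k)], n)
        fit = fit_condition_glm(rng.standard_normal(k * n), conds)
        assert fit.residual_df == k * n - k

    def test_intercept_estimates_preferred_mean(self, rng):
        y, conds = scalars_for({"1": 0.2, "4": 2.0, "7": 0.1}, 15, rng)
        fit = fit_condition_glm(y, conds)
        assert fit.preferred == "4"
        intercept = float(fit.glm.set_index("term").loc["intercept", "estimate"])
        assert intercept == pytest.approx(y[conds == "4"].mean(), abs=1e-12)

    def test_empty_condition_after_masking_rejected(self, rng):
        y = rng.standard_normal(6)
        conds = np.array(["1", "1", "1", "1", "2", "2"])
        kept = np.array([True] * 4 + [False, False])
        with pytest.raises(ValueError):
            fit_condition_glm(y, conds, kept=kept)


LEVELS = ("1", "2", "3", "4", "5", "6", "7", "20")


class TestClassification:
    def make_fit(self, means, rng, n=20, sd=0.5):
        y, conds = scalars_for(dict(zip(LEVELS, means)), n, rng, sd)
        return fit_condition_glm(y, conds)

    def test_peaked_profile_is_tuned(self, rng):
        means = [0.1, 0.5, 1.5, 3.0, 1.5, 0.5, 0.1, 0.0]  # peak at 4
        fit = self.make_fit(means, rng)
        assert fit.preferred == "4"
        assert classify_electrode(fit) == "tuned"

    def test_preference_for_smallest_level_counts_as_tuned(self, rng):
        means = [3.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.1, 0.0]
        fit = self.make_fit(means, rng)
        assert classify_electrode(fit) == "tuned"

    def test_increasing_profile_is_energy_monotonic(self, rng):
        means = [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 3.0]
        fit = self.make_fit(means, rng)
        assert classify_electrode(fit) == "energy_monotonic"

    def test_uniform_strong_response_is_flat(self, rng):
        fit = self.make_fit([2.0] * 8, rng, sd=0.3)
        assert classify_electrode(fit) == "flat_responsive"

    def test_null_is_nonresponsive(self):
        rng = np.random.default_rng(77)
        fit = self.make_fit([0.0] * 8, rng, sd=1.0)
        assert classify_electrode(fit) == "nonresponsive"


class TestCategoryComparison:
    def test_separated_categories_strongly_negative(self, rng):
        ref = rng.standard_normal(40) + 5.0
        cat_conds = np.repeat(["face", "letter", "house"], 12)
        cats = rng.standard_normal(36)  # 5 SD below the reference
        cmp = compare_with_categories(ref, cats, cat_conds)
        table = cmp.glm.set_index("term")
        for term in ("face", "letter", "house"):
            assert table.loc[term, "estimate"] < 0
            assert table.loc[term, "p"] < 0.001
        assert cmp.residual_df == 40 + 36 - 4

    def test_null_per_term_rejection_rate_nominal(self):
        rng = np.random.default_rng(6)
        cat_conds = np.repeat(["face", "letter", "house"], 12)
        hits = 0
        reps = 300
        for _ in range(reps):
            cmp = compare_with_categories(
                rng.standard_normal(40), rng.standard_normal(36), cat_conds
            )
            hits += int((cmp.glm["p"].iloc[1:] < 0.05).sum())
        rate = hits / (3 * reps)
        assert 0.02 < rate < 0.09  # ~5% per-term false positives

    def test_missing_category_rejected(self, rng):
        with pytest.raises(ValueError, match="house"):
            compare_with_categories(
                rng.standard_normal(10),
                rng.standard_normal(8),
                np.repeat(["face", "letter"], 4),
            )
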