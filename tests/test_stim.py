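"""Stimulus-plan construction: timing bookkeeping, retention counts,
seeded determinism and oddball marking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numecog.stim import (
    StimParamError,
    StimParams,
    build_category_plan,
    build_randomized_plan,
    build_sequential_plan,
    mark_oddballs,
    retained_trial_filter,
    validate_events,
)


class TestSequentialPlan:
    def test_default_run_timing(self, sequential_plan):
        # 2 x (7*6 + 12 + 7*6 + 12) presentations at 850 ms plus 2.4 s grey
        assert sequential_plan.n_events == 216
        assert sequential_plan.total_duration_s == 186.0

    def test_block_structure(self, sequential_plan):
        ev = sequential_plan.events
        counts = ev.groupby("trial_type").size()
        for lev in range(1, 8):
            assert counts[str(lev)] == 24
        assert counts["20"] == 48
        # ascending sweep first: first six presentations are numerosity 1
        assert list(ev["trial_type"].iloc[:6]) == ["1"] * 6
        # descending sweep ends each repeat half: block before the 2nd '20'
        # block is numerosity 7 then descending
        assert ev["trial_type"].iloc[42:54].unique().tolist() == ["20"]

    def test_onsets_increasing_and_nonoverlapping(self, sequential_plan):
        validate_events(sequential_plan.events)
        gaps = np.diff(sequential_plan.events["onset"].to_numpy())
        assert np.allclose(gaps, 0.850)

    def test_zero_repeats_degenerate(self):
        plan = build_sequential_plan(StimParams(n_sequence_repeats=0))
        assert plan.n_events == 0
        assert plan.total_duration_s == pytest.approx(2.4)

    @given(repeats=st.integers(0, 4), small=st.integers(1, 8), large=st.integers(1, 16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_duration_closed_form(self, repeats, small, large):
        params = StimParams(
            n_sequence_repeats=repeats,
            presentations_per_small_block=small,
            presentations_per_20_block=large,
        )
        plan = build_sequential_plan(params)
        n = repeats * (2 * 7 * small + 2 * large)
        assert plan.n_events == n
        expected = 2.4 + n * (params.stim_duration_s + params.isi_s)
        assert plan.total_duration_s == pytest.approx(expected, abs=1e-9)

    def test_invalid_params_name_the_field(self):
        with pytest.raises(StimParamError, match="stim_duration_s"):
            StimParams(stim_duration_s=0)
        with pytest.raises(StimParamError, match="oddball_rate"):
            StimParams(oddball_rate=1.5)
        with pytest.raises(StimParamError, match="numerosity_levels"):
            StimParams(numerosity_levels=(1, 2, -3))


class TestRandomizedPlan:
    def test_counts_and_isi_bounds(self):
        plan = build_randomized_plan(seed=11)
        counts = plan.events.groupby("trial_type").size()
        assert (counts == 24).all() and len(counts) == 8
        gaps = np.diff(plan.events["onset"].to_numpy()) - 0.250
        assert gaps.min() >= 0.650 - 1e-12 and gaps.max() <= 0.950 + 1e-12

    def test_seeded_determinism(self):
        a = build_randomized_plan(seed=7)
        b = build_randomized_plan(seed=7)
        pd.testing.assert_frame_equal(a.events, b.events)
        c = build_randomized_plan(seed=8)
        assert not a.events["trial_type"].equals(c.events["trial_type"])
        # different seed still preserves per-condition counts
        assert (c.events.groupby("trial_type").size() == 24).all()

    def test_missing_seed_is_an_error(self):
        with pytest.raises(StimParamError, match="seed"):
            build_randomized_plan()

    def test_no_immediate_repeat_option(self):
        plan = build_randomized_plan(seed=3, no_immediate_repeat=True)
        tt = plan.events["trial_type"].to_numpy()
        assert (tt[1:] != tt[:-1]).all()


class TestCategoryPlan:
    def test_counts_and_isi_bounds(self):
        plan = build_category_plan(seed=5)
        assert plan.n_events == 36
        assert (plan.events.groupby("trial_type").size() == 12).all()
        gaps = np.diff(plan.events["onset"].to_numpy()) - 0.500
        assert gaps.min() >= 1.250 - 1e-12 and gaps.max() <= 1.750 + 1e-12

    def test_determinism(self):
        pd.testing.assert_frame_equal(
            build_category_plan(seed=9).events, build_category_plan(seed=9).events
        )


class TestOddballs:
    def test_exact_rule_two_per_level(self, sequential_plan):
        plan = mark_oddballs(sequential_plan, seed=1)
        per_level = plan.events.groupby("trial_type")["is_oddball"].sum()
        assert (per_level == 2).all()

    def test_rate_zero_marks_nothing(self):
        plan = build_sequential_plan(StimParams(oddball_rate=0.0))
        plan = mark_oddballs(plan, seed=1)
        assert not plan.events["is_oddball"].any()

    def test_seeded_and_timing_neutral(self, sequential_plan):
        a = mark_oddballs(sequential_plan, seed=4)
        b = mark_oddballs(sequential_plan, seed=4)
        assert a.events["is_oddball"].equals(b.events["is_oddball"])
        assert a.events["onset"].equals(sequential_plan.events["onset"])

    def test_bernoulli_rule(self, sequential_plan):
        plan = mark_oddballs(sequential_plan, seed=2, rule="bernoulli")
        # rate 0.10 over 216 events: loose binomial bound
        assert 5 <= plan.events["is_oddball"].sum() <= 45


class TestRetention:
    def test_sequential_counts(self, sequential_plan):
        kept = retained_trial_filter(sequential_plan.events, "sequential")
        counts = kept.loc[kept["keep"]].groupby("trial_type").size()
        for lev in range(1, 8):
            assert counts[str(lev)] == 20
        assert counts["20"] == 40

    def test_randomized_keeps_everything(self):
        plan = build_randomized_plan(seed=2)
        kept = retained_trial_filter(plan.events, "randomized")
        assert kept["keep"].all()
        assert (kept.loc[kept["keep"]].groupby("trial_type").size() == 24).all()

    def test_first_of_block_dropped(self, sequential_plan):
        kept = retained_trial_filter(sequential_plan.events, "sequential")
        dropped = kept.loc[~kept["keep"]]
        small = dropped[dropped["trial_type"] != "20"]
        assert (small["within_block_index"] == 0).all()
        large = dropped[dropped["trial_type"] == "20"]
        assert set(large["within_block_index"]) == {0, 1}

    def test_unknown_run_kind(self, sequential_plan):
        with pytest.raises(StimParamError, match="run kind"):
            retained_trial_filter(sequential_plan.events, "mystery")
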