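"""Stimulus-presentation plans for numerosity and visual-category runs.

Three run kinds are supported:

* sequential numerosity runs: numerosities 1-7 shown in ascending then
  descending sweeps of six consecutive presentations each, the two sweeps
  separated by twelve presentations of numerosity 20, the whole sequence
  repeated twice; 250 ms stimulus, fixed 600 ms inter-stimulus interval,
  1200 ms grey lead-in and lead-out (total 186 s with the defaults);
* randomized numerosity runs: each numerosity 24 times in seeded random
  order with ISIs drawn uniformly from 650-950 ms;
* visual-category runs: 12 faces, 12 letters and 12 houses in seeded random
  order, 500 ms stimulus, ISIs uniform in 1250-1750 ms.

All onsets are seconds from run start.  Oddball (white-dot attention) trials
are flagged separately and never alter timing.  The retention filter encodes
which presentations enter analysis: in sequential runs the first presentation
of every numerosity-1-7 block and the first two of every numerosity-20 block
are dropped (leaving 20 per numerosity 1-7 and 40 of numerosity 20 per run);
randomized and category runs keep everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS

NUMEROSITY_LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 20)
CATEGORY_LEVELS: tuple[str, ...] = ("face", "letter", "house")


class StimParamError(ValueError):
    """A stimulus-plan parameter violates its invariant."""


@dataclass(frozen=True)
class StimParams:
    """Timing and counting parameters for all three run kinds.

    Durations are seconds.  ``isi_s`` is the fixed ISI of sequential runs;
    ``isi_range_s`` / ``category_isi_range_s`` are uniform-draw bounds for
    the randomized and category runs.
    """

    stim_duration_s: float = 0.250
    isi_s: float = 0.600
    isi_range_s: tuple[float, float] = (0.650, 0.950)
    category_stim_duration_s: float = 0.500
    category_isi_range_s: tuple[float, float] = (1.250, 1.750)
    presentations_per_small_block: int = 6
    presentations_per_20_block: int = 12
    randomized_presentations_per_numerosity: int = 24
    category_presentations_per_level: int = 12
    lead_in_s: float = 1.200
    lead_out_s: float = 1.200
    n_sequence_repeats: int = 2
    numerosity_levels: tuple[int, ...] = NUMEROSITY_LEVELS
    category_levels: tuple[str, ...] = CATEGORY_LEVELS
    oddball_rate: float = 0.10
    oddballs_per_level: int = 2

    def __post_init__(self) -> None:
        for name in (
            "stim_duration_s",
            "isi_s",
            "category_stim_duration_s",
            "lead_in_s",
            "lead_out_s",
        ):
            if getattr(self, name) <= 0:
                raise StimParamError(f"{name} must be > 0")
        for name in ("isi_range_s", "category_isi_range_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise StimParamError(f"{name} must satisfy 0 < lo <= hi")
        for name in (
            "presentations_per_small_block",
            "presentations_per_20_block",
            "randomized_presentations_per_numerosity",
            "category_presentations_per_level",
        ):
            if getattr(self, name) < 1:
                raise StimParamError(f"{name} must be >= 1")
        if self.n_sequence_repeats < 0:
            raise StimParamError("n_sequence_repeats must be >= 0")
        if any(n <= 0 or int(n) != n for n in self.numerosity_levels):
            raise StimParamError("numerosity_levels must be positive integers")
        if not 0.0 <= self.oddball_rate <= 1.0:
            raise StimParamError("oddball_rate must lie in [0, 1]")
        if self.oddballs_per_level < 0:
            raise StimParamError("oddballs_per_level must be >= 0")

    @property
    def small_levels(self) -> tuple[int, ...]:
        return tuple(n for n in self.numerosity_levels if n != max(self.numerosity_levels))

    @property
    def large_level(self) -> int:
        return max(self.numerosity_levels)


@dataclass(frozen=True)
class StimulusPlan:
    """A fully laid-out run: event table plus timing bookkeeping."""

    run_kind: str  # 'sequential' | 'randomized' | 'category'
    params: StimParams
    events: pd.DataFrame = field(repr=False)
    total_duration_s: float = 0.0
    seed: int | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)


def _assemble_events(
    conditions: Sequence[str],
    stim_dur: float,
    isis: np.ndarray,
    block_index: Sequence[int],
    within_block: Sequence[int],
    lead_in: float,
) -> pd.DataFrame:
    n = len(conditions)
    onsets = np.empty(n)
    t = lead_in
    for i in range(n):
        onsets[i] = t
        t += stim_dur + isis[i]
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": stim_dur,
            "trial_type": list(conditions),
            "block_index": list(block_index),
            "within_block_index": list(within_block),
            "is_oddball": False,
            "keep": True,
        },
        columns=list(EVENT_COLUMNS),
    )


def _total_duration(params: StimParams, stim_dur: float, isis: np.ndarray) -> float:
    total = params.lead_in_s + float(np.sum(stim_dur + isis)) + params.lead_out_s
    # bookkeeping is exact in the model; shed float accumulation error
    return float(np.round(total, 9))


def build_sequential_plan(params: StimParams | None = None) -> StimulusPlan:
    """Sequential-order numerosity run.

    Per repeat: ascending sweep 1..7 (six consecutive presentations per
    numerosity), one twelve-presentation block of 20, descending sweep 7..1,
    another block of 20.  Deterministic; oddballs are marked separately.
    """
    params = params or StimParams()
    small = sorted(params.small_levels)
    blocks: list[tuple[int, int]] = []  # (level, n_presentations)
    for _ in range(params.n_sequence_repeats):
        for lev in small:
            blocks.append((lev, params.presentations_per_small_block))
        blocks.append((params.large_level, params.presentations_per_20_block))
        for lev in reversed(small):
            blocks.append((lev, params.presentations_per_small_block))
        blocks.append((params.large_level, params.presentations_per_20_block))

    conditions: list[str] = []
    block_index: list[int] = []
    within: list[int] = []
    for b, (lev, count) in enumerate(blocks):
        for j in range(count):
            conditions.append(str(lev))
            block_index.append(b)
            within.append(j)

    isis = np.full(len(conditions), params.isi_s)
    events = _assemble_events(
        conditions, params.stim_duration_s, isis, block_index, within, params.lead_in_s
    )
    total = _total_duration(params, params.stim_duration_s, isis)
    return StimulusPlan("sequential", params, events, total, seed=None)


def build_randomized_plan(params: StimParams | None = None, seed: int | None = None,
                          no_immediate_repeat: bool = False) -> StimulusPlan:
    """Randomized-order numerosity run with variable ISIs.

    Each numerosity appears exactly ``randomized_presentations_per_numerosity``
    times in a seeded permutation; ISIs are drawn uniformly from
    ``isi_range_s``.  With ``no_immediate_repeat`` the permutation is
    post-processed so no two consecutive presentations share a numerosity.
    """
    params = params or StimParams()
    if seed is None:
        raise StimParamError("randomized plans require an explicit seed")
    rng = np.random.default_rng(seed)
    levels = np.repeat(
        list(params.numerosity_levels), params.randomized_presentations_per_numerosity
    )
    order = rng.permutation(levels)
    if no_immediate_repeat:
        order = _break_repeats(order, rng)
    conditions = [str(int(v)) for v in order]
    lo, hi = params.isi_range_s
    isis = rng.uniform(lo, hi, size=len(conditions))
    events = _assemble_events(
        conditions,
        params.stim_duration_s,
        isis,
        block_index=list(range(len(conditions))),
        within_block=[0] * len(conditions),
        lead_in=params.lead_in_s,
    )
    total = _total_duration(params, params.stim_duration_s, isis)
    return StimulusPlan("randomized", params, events, total, seed=seed)


def _break_repeats(order: np.ndarray, rng: np.random.Generator,
                   max_passes: int = 100) -> np.ndarray:
    order = order.copy()
    for _ in range(max_passes):
        bad = np.flatnonzero(order[1:] == order[:-1]) + 1
        if bad.size == 0:
            return order
        for i in bad:
            candidates = np.flatnonzero(
                (order != order[i])
                & (np.roll(order, -1) != order[i])
                & (np.roll(order, 1) != order[i])
            )
            if candidates.size:
                j = int(rng.choice(candidates))
                order[i], order[j] = order[j], order[i]
    return order


def build_category_plan(params: StimParams | None = None,
                        seed: int | None = None) -> StimulusPlan:
    """Visual-category run: faces, letters and houses in random order."""
    params = params or StimParams()
    if seed is None:
        raise StimParamError("category plans require an explicit seed")
    rng = np.random.default_rng(seed)
    levels = np.repeat(list(params.category_levels), params.category_presentations_per_level)
    order = rng.permutation(levels)
    lo, hi = params.category_isi_range_s
    isis = rng.uniform(lo, hi, size=len(order))
    events = _assemble_events(
        list(order),
        params.category_stim_duration_s,
        isis,
        block_index=list(range(len(order))),
        within_block=[0] * len(order),
        lead_in=params.lead_in_s,
    )
    total = _total_duration(params, params.category_stim_duration_s, isis)
    return StimulusPlan("category", params, events, total, seed=seed)


def mark_oddballs(plan: StimulusPlan, seed: int,
                  rule: str = "exact") -> StimulusPlan:
    """Flag oddball (white-dot) presentations on a numerosity plan.

    ``rule='exact'`` flags exactly ``params.oddballs_per_level`` seeded
    presentations per numerosity; ``rule='bernoulli'`` flags each presentation
    independently with probability ``params.oddball_rate``.  Flags never
    alter timing.
    """
    if plan.run_kind not in ("sequential", "randomized"):
        raise StimParamError("oddballs apply to numerosity plans only")
    if rule not in ("exact", "bernoulli"):
        raise StimParamError(f"unknown oddball rule {rule!r}")
    rng = np.random.default_rng(seed)
    events = plan.events.copy()
    flags = np.zeros(len(events), dtype=bool)
    if rule == "bernoulli":
        flags = rng.random(len(events)) < plan.params.oddball_rate
    else:
        k = plan.params.oddballs_per_level
        if plan.params.oddball_rate == 0:
            k = 0
        for lev in plan.params.numerosity_levels:
            idx = np.flatnonzero(events["trial_type"].to_numpy() == str(lev))
            if idx.size and k:
                flags[rng.choice(idx, size=min(k, idx.size), replace=False)] = True
    events["is_oddball"] = flags
    return StimulusPlan(plan.run_kind, plan.params, events, plan.total_duration_s, plan.seed)


def retained_trial_filter(events: pd.DataFrame, run_kind: str,
                          drop_first_small: int = 1,
                          drop_first_large: int = 2,
                          large_level: int = 20) -> pd.DataFrame:
    """Clear keep flags for block-onset presentations of sequential runs.

    Sequential runs: the first ``drop_first_small`` presentations of every
    numerosity-1-7 block and the first ``drop_first_large`` of every
    numerosity-20 block are dropped (numerosity-change onset effects).  This
    retains 20 presentations per numerosity 1-7 and 40 of numerosity 20 per
    default run.  Randomized and category runs keep all presentations.
    """
    if run_kind not in ("sequential", "randomized", "category"):
        raise StimParamError(f"unknown run kind {run_kind!r}")
    out = events.copy()
    if run_kind != "sequential":
        return out
    tt = out["trial_type"].to_numpy()
    wb = out["within_block_index"].to_numpy()
    is_large = tt == str(large_level)
    drop = np.where(is_large, wb < drop_first_large, wb < drop_first_small)
    out["keep"] = out["keep"].to_numpy() & ~drop
    return out


def validate_events(events: pd.DataFrame) -> None:
    """Check event-table invariants: ordering and non-overlap."""
    onsets = events["onset"].to_numpy()
    durs = events["duration"].to_numpy()
    if len(onsets) > 1:
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if not np.all(onsets[:-1] + durs[:-1] <= onsets[1:] + 1e-12):
            raise ValueError("events overlap in time")
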