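"""Trial-level quality control on normalized HFB time courses.

Two rules, both evaluated electrode-wise on the normalized (not yet
baseline-corrected) band course:

* pre-stimulus variation: a trial is flagged when its band course varies by
  more than ``prestim_threshold`` (normalized-power units, default 0.5)
  over the pre-stimulus window [-0.200, 0) s.  The default variation
  statistic is the standard deviation over that window; a max-minus-min
  range statistic is available via ``prestim_stat='range'``.  The SD default
  is what keeps the rule's false-positive rate on background activity at
  the sub-percent level implied by the pipeline's retained-trial counts;
  the range of the 300 ms sliding-window power estimator over these heavily
  overlapping windows exceeds 0.5 on nearly half of artifact-free trials,
  which would make a range rule at this threshold an aggressive subsampler
  rather than an artifact screen (see docs/methods.md).
* baseline outlier: with m_i the trial's mean over the baseline window
  (default [-0.200, -0.050] s), a trial is flagged when |m_i - mean(m)|
  exceeds ``baseline_sd_threshold`` (default 3) population standard
  deviations, where mean and SD pool all retained trials of that electrode
  and run in a single pass (no re-iteration after removal).

QC never modifies data values, only the per-trial, per-channel keep mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCConfig
from .containers import HFBResponse


def _check_state(hfb: HFBResponse) -> None:
    if not hfb.normalized:
        raise ValueError("trial QC expects normalized HFB input")
    if hfb.baseline_corrected:
        raise ValueError(
            "trial QC must run before baseline correction (the baseline-"
            "outlier rule is vacuous on baseline-corrected data)"
        )


def flag_prestim_variation(hfb: HFBResponse, cfg: QCConfig | None = None) -> np.ndarray:
    """Boolean flags (n_trials, n_channels): excessive pre-stimulus variation."""
    cfg = cfg or QCConfig()
    _check_state(hfb)
    lo, hi = cfg.prestim_window_s
    mask = (hfb.times >= lo - 1e-9) & (hfb.times < hi - 1e-9)  # half-open
    if not mask.any():
        raise ValueError(f"pre-stimulus window {cfg.prestim_window_s} is off the grid")
    seg = hfb.course[:, :, mask]
    if cfg.prestim_stat == "range":
        stat = seg.max(axis=2) - seg.min(axis=2)
    else:
        stat = seg.std(axis=2)
    return stat > cfg.prestim_threshold


def flag_baseline_outlier(hfb: HFBResponse, cfg: QCConfig | None = None) -> np.ndarray:
    """Boolean flags (n_trials, n_channels): baseline mean beyond 3 SD.

    The reference mean and population SD pool all retained trials of the
    electrode regardless of condition; the comparison uses a strict
    inequality, so a degenerate SD of zero flags nothing.
    """
    cfg = cfg or QCConfig()
    _check_state(hfb)
    lo, hi = cfg.baseline_window_s
    mask = (hfb.times >= lo - 1e-9) & (hfb.times <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window {cfg.baseline_window_s} is off the grid")
    m = hfb.course[:, :, mask].mean(axis=2)  # (n_trials, n_channels)
    flags = np.zeros_like(m, dtype=bool)
    for ch in range(hfb.n_channels):
        kept = hfb.kept[:, ch]
        n = int(kept.sum())
        if n < 3:
            raise ValueError(
                f"channel {hfb.channels['name'].iloc[ch]!r} has {n} retained "
                "trials; the baseline-outlier rule needs at least 3"
            )
        mu = m[kept, ch].mean()
        sd = m[kept, ch].std(ddof=0)
        flags[:, ch] = kept & (np.abs(m[:, ch] - mu) > cfg.baseline_sd_threshold * sd)
    return flags


def apply_qc(hfb: HFBResponse, *flag_sets: np.ndarray) -> tuple[HFBResponse, pd.DataFrame]:
    """Clear keep flags for the union of the given flag sets.

    Returns the updated response and a per-channel report of exclusion
    counts.  Raises if any channel would lose all its trials.  Idempotent:
    re-applying the same flags changes nothing.
    """
    out = hfb.copy()
    union = np.zeros_like(out.kept)
    for f in flag_sets:
        if f.shape != out.kept.shape:
            raise ValueError("flag array shape must be (n_trials, n_channels)")
        union |= f
    out.kept &= ~union
    empty = np.flatnonzero(~out.kept.any(axis=0))
    if empty.size:
        names = out.channels["name"].iloc[empty].tolist()
        raise ValueError(f"QC excluded every trial of channel(s) {names}")
    report = pd.DataFrame(
        {
            "channel": out.channels["name"].to_numpy(),
            "n_trials": hfb.kept.sum(axis=0),
            "n_flagged": (union & hfb.kept).sum(axis=0),
            "n_kept": out.kept.sum(axis=0),
        }
    )
    return out, report


def qc_report(hfb: HFBResponse, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Tidy per-trial, per-channel report of both rules and their statistics."""
    cfg = cfg or QCConfig()
    a = flag_prestim_variation(hfb, cfg)
    b = flag_baseline_outlier(hfb, cfg)
    rows = []
    for ch in range(hfb.n_channels):
        name = hfb.channels["name"].iloc[ch]
        for tr in range(hfb.n_trials):
            rows.append(
                {
                    "channel": name,
                    "trial": tr,
                    "trial_type": hfb.trials["trial_type"].iloc[tr],
                    "prestim_flag": bool(a[tr, ch]),
                    "baseline_flag": bool(b[tr, ch]),
                    "kept_before": bool(hfb.kept[tr, ch]),
                }
            )
    return pd.DataFrame(rows)


def run_qc(hfb: HFBResponse, cfg: QCConfig | None = None) -> tuple[HFBResponse, pd.DataFrame]:
    """Apply both rules and return the filtered response plus the report."""
    cfg = cfg or QCConfig()
    a = flag_prestim_variation(hfb, cfg)
    b = flag_baseline_outlier(hfb, cfg)
    return apply_qc(hfb, a, b)
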