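"""Shared in-memory containers for the analysis pipeline.

The pipeline's entry object is a :class:`RawRecording` (channels x samples
voltage matrix plus channel metadata); epoching produces an :class:`EpochSet`
(trials x channels x time), spectral analysis a :class:`TimeFreqPower`
(trials x channels x frequencies x times) and band-averaging an
:class:`HFBResponse` (trials x channels x times plus a per-trial scalar).

Trial metadata travels as a pandas DataFrame with BIDS-iEEG-style columns
(onset, duration, trial_type, block_index, within_block_index, is_oddball,
keep); channel metadata as a DataFrame with columns (name, anatomical_label,
include, kind).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = (
    "onset",
    "duration",
    "trial_type",
    "block_index",
    "within_block_index",
    "is_oddball",
    "keep",
)

CHANNEL_COLUMNS = ("name", "anatomical_label", "include", "kind")

ANATOMICAL_LABELS = ("parietal", "occipital", "temporal", "other")


def default_channels(names: Sequence[str], kind: str = "grid") -> pd.DataFrame:
    """Channel-metadata table with all channels included, label 'other'."""
    return pd.DataFrame(
        {
            "name": list(names),
            "anatomical_label": "other",
            "include": True,
            "kind": kind,
        }
    )


@dataclass
class RawRecording:
    """Multichannel voltage recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channels : DataFrame
        One row per channel with columns ``name``, ``anatomical_label``,
        ``include``, ``kind``.
    """

    data: np.ndarray
    sfreq: float
    channels: pd.DataFrame
    reference: str = "unknown"
    acq_band_hz: tuple[float, float] = (0.15, 536.0)
    notched: bool = False
    rereferenced: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows but data has "
                f"{self.data.shape[0]} channels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def ch_names(self) -> list[str]:
        return list(self.channels["name"])

    @property
    def included_names(self) -> list[str]:
        return list(self.channels.loc[self.channels["include"], "name"])

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy(), channels=self.channels.copy())


@dataclass
class EpochSet:
    """Trials x channels x time snippets time-locked to stimulus onset."""

    data: np.ndarray  # (n_trials, n_channels, n_times), microvolts
    times: np.ndarray  # seconds relative to onset, uniform at sfreq
    sfreq: float
    channels: pd.DataFrame
    trials: pd.DataFrame  # per-trial metadata incl. trial_type, keep
    notched: bool = False
    rereferenced: bool = False
    evoked_removed: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials, channels, times)")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial metadata rows must match trial count")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel table rows must match channel count")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("time axis must match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            channels=self.channels.copy(),
            trials=self.trials.copy(),
        )


@dataclass
class TimeFreqPower:
    """Sliding-window tapered spectral power.

    ``power`` is trials x channels x frequencies x times; nonnegative until
    baseline correction, dimensionless after normalization.  State flags are
    monotone: once normalized or baseline-corrected an object cannot go back.
    """

    power: np.ndarray  # (n_trials, n_channels, n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # window-centre times, s relative to onset
    window_s: float
    taper: str
    trials: pd.DataFrame
    channels: pd.DataFrame
    normalized: bool = False
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        if self.power.ndim != 4:
            raise ValueError("power must be 4-D (trials, channels, freqs, times)")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def copy(self) -> "TimeFreqPower":
        return replace(self, power=self.power.copy(), trials=self.trials.copy())


@dataclass
class HFBResponse:
    """Band-averaged high-frequency broadband power per trial.

    ``course`` is trials x channels x times on the 10 ms grid; the per-trial
    scalar (mean over the tuning window) is recomputed from the stored course
    so the two can never disagree.  ``kept`` is a per-trial, per-channel keep
    mask: trial QC operates electrode-wise.
    """

    course: np.ndarray  # (n_trials, n_channels, n_times)
    times: np.ndarray
    band_hz: tuple[float, float]
    tuning_window_s: tuple[float, float]
    trials: pd.DataFrame
    channels: pd.DataFrame
    kept: np.ndarray = field(default=None)  # (n_trials, n_channels) bool
    normalized: bool = False
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        if self.course.ndim != 3:
            raise ValueError("course must be 3-D (trials, channels, times)")
        if self.kept is None:
            keep = np.asarray(self.trials["keep"], dtype=bool)
            self.kept = np.repeat(keep[:, None], self.course.shape[1], axis=1)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.kept.shape != self.course.shape[:2]:
            raise ValueError("kept mask must be (n_trials, n_channels)")

    @property
    def n_trials(self) -> int:
        return self.course.shape[0]

    @property
    def n_channels(self) -> int:
        return self.course.shape[1]

    def window_mask(self) -> np.ndarray:
        lo, hi = self.tuning_window_s
        return (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)

    @property
    def scalar(self) -> np.ndarray:
        """Per-trial mean over the tuning window, shape (n_trials, n_channels)."""
        mask = self.window_mask()
        if not mask.any():
            raise ValueError("tuning window contains no time points")
        return self.course[:, :, mask].mean(axis=2)

    def copy(self) -> "HFBResponse":
        return replace(
            self,
            course=self.course.copy(),
            trials=self.trials.copy(),
            kept=self.kept.copy(),
        )
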