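"""Independent oracles and small fixture builders shared across tests.

The oracles here are deliberately naive re-derivations (explicit-loop DFT,
textbook pooled two-sample t) kept independent of the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from numecog.containers import EpochSet, HFBResponse, default_channels


def naive_sliding_power(epochs: EpochSet, window_s: float,
                        freqs_hz: np.ndarray, times_s: np.ndarray) -> np.ndarray:
    """Direct-sum tapered DFT power, one explicit loop per quantity.

    Matches the documented conventions: window length round(window_s * fs)
    samples, symmetric Hanning taper, windows centred on round(t * fs) with
    half-open extent, Fourier coefficient evaluated at exactly f.
    """
    fs = epochs.sfreq
    n_win = int(np.sign(window_s * fs) * np.floor(abs(window_s * fs) + 0.5))
    # symmetric Hanning written out rather than taken from scipy
    k = np.arange(n_win)
    taper = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n_win - 1)))
    first = int(round(epochs.times[0] * fs))
    out = np.empty((epochs.n_trials, epochs.n_channels, len(freqs_hz), len(times_s)))
    for tr in range(epochs.n_trials):
        for ch in range(epochs.n_channels):
            for ti, t in enumerate(times_s):
                centre = int(np.sign(t * fs) * np.floor(abs(t * fs) + 0.5))
                start = centre - n_win // 2 - first
                seg = epochs.data[tr, ch, start: start + n_win] * taper
                for fi, f in enumerate(freqs_hz):
                    arg = -2.0 * np.pi * f * k / fs
                    re = float(np.sum(seg * np.cos(arg)))
                    im = float(np.sum(seg * np.sin(arg)))
                    out[tr, ch, fi, ti] = re * re + im * im
    return out


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook pooled-variance two-sample t for mean(b) - mean(a)."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def make_epochs(data: np.ndarray, sfreq: float, t_start: float,
                conditions=None) -> EpochSet:
    """Wrap a (trials, channels, times) array into an EpochSet."""
    n_tr, n_ch, n_t = data.shape
    first = int(round(t_start * sfreq))
    times = np.arange(first, first + n_t) / sfreq
    if conditions is None:
        conditions = ["1"] * n_tr
    trials = pd.DataFrame(
        {
            "onset": np.arange(n_tr, dtype=float),
            "duration": 0.25,
            "trial_type": [str(c) for c in conditions],
            "block_index": 0,
            "within_block_index": np.arange(n_tr),
            "is_oddball": False,
            "keep": True,
        }
    )
    return EpochSet(
        data=np.asarray(data, dtype=float),
        times=times,
        sfreq=sfreq,
        channels=default_channels([f"ch{i}" for i in range(n_ch)]),
        trials=trials,
    )


def make_hfb(course: np.ndarray, times: np.ndarray, conditions=None,
             normalized: bool = True, tuning_window=(0.100, 0.350)) -> HFBResponse:
    """Wrap a (trials, channels, times) band course into an HFBResponse."""
    n_tr, n_ch, _ = course.shape
    if conditions is None:
        conditions = ["1"] * n_tr
    trials = pd.DataFrame(
        {
            "onset": np.arange(n_tr, dtype=float),
            "duration": 0.25,
            "trial_type": [str(c) for c in conditions],
            "block_index": 0,
            "within_block_index": np.arange(n_tr),
            "is_oddball": False,
            "keep": True,
        }
    )
    return HFBResponse(
        course=np.asarray(course, dtype=float),
        times=np.asarray(times, dtype=float),
        band_hz=(60.0, 120.0),
        tuning_window_s=tuning_window,
        trials=trials,
        channels=default_channels([f"ch{i}" for i in range(n_ch)]),
        normalized=normalized,
    )
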