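"""Preprocessing: line-noise notch filtering, common-average referencing,
and stimulus-locked epoching.

The notch is a zero-phase (forward-backward) IIR band-stop at each line
frequency (default 50, 100, 150 Hz) with a 3 Hz total stop width centred on
the line.  The common-average reference subtracts, at every sample, the mean
over the *included* channels from each included channel; excluded channels
pass through untouched.  Epoching is content-preserving slicing: onset times
are converted to sample indices by rounding half away from zero, and epoch
extents are inclusive of both endpoint samples.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, iirnotch

from .containers import EpochSet, RawRecording


def round_half_away(x: float | np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (the onset-index rule)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def notch_filter(recording: RawRecording,
                 line_freqs_hz: Sequence[float] = (50.0, 100.0, 150.0),
                 width_hz: float = 3.0) -> RawRecording:
    """Zero-phase band-stop at each line frequency.

    ``width_hz`` is the total -3 dB stop width per line (the notch quality
    factor is f/width).  Output length equals input length; the passband is
    preserved to within a fraction of a dB.
    """
    nyq = recording.sfreq / 2.0
    bad = [f for f in line_freqs_hz if f >= nyq]
    if bad:
        raise ValueError(
            f"line frequencies {bad} are at or above the Nyquist frequency {nyq} Hz"
        )
    data = recording.data.copy()
    for f in line_freqs_hz:
        b, a = iirnotch(w0=f, Q=f / width_hz, fs=recording.sfreq)
        data = filtfilt(b, a, data, axis=-1)
    out = recording.copy()
    out.data = data
    out.notched = True
    return out


def common_average_reference(recording: RawRecording,
                             selection: Sequence[str] | None = None) -> RawRecording:
    """Re-reference included channels to their instantaneous common average.

    ``selection`` defaults to the channels flagged ``include`` in the
    recording's channel table.  With a single included channel the result is
    identically zero (a warning is emitted).
    """
    if selection is None:
        selection = recording.included_names
    selection = list(selection)
    if not selection:
        raise ValueError("common-average reference requires a nonempty selection")
    names = recording.ch_names
    unknown = [s for s in selection if s not in names]
    if unknown:
        raise ValueError(f"selection names not in recording: {unknown}")
    if len(selection) == 1:
        warnings.warn(
            "common-average reference over a single channel zeroes it",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = np.array([names.index(s) for s in selection])
    out = recording.copy()
    car = out.data[idx].mean(axis=0)
    out.data[idx] -= car
    out.rereferenced = True
    out.reference = f"common average of {len(idx)} channels"
    return out


def epoch_data(recording: RawRecording, events: pd.DataFrame,
               window_s: tuple[float, float] = (-0.500, 1.000),
               trigger_offset_s: float = 0.0) -> EpochSet:
    """Slice the recording around each retained event.

    One trial per event with ``keep=True`` (the retention filter runs
    beforehand).  The onset sample is ``round_half_away(onset * sfreq) +
    round_half_away(trigger_offset_s * sfreq)`` — the trigger offset is a
    fixed hardware delay, so it is rounded once and shifts every epoch by
    the same integer number of samples.  The epoch spans sample offsets
    ``round_half_away(w0 * sfreq)`` to ``round_half_away(w1 * sfreq)``
    inclusive, so the default numerosity window (-0.5 to +1.0 s at 2048 Hz)
    yields 3073 samples.  Events whose window falls outside the recording
    raise with the offending rows listed.
    """
    fs = recording.sfreq
    retained = events.loc[events["keep"].astype(bool)].reset_index(drop=True)
    shift = int(round_half_away(trigger_offset_s * fs))
    onset_idx = round_half_away(retained["onset"].to_numpy() * fs) + shift
    lo = int(round_half_away(window_s[0] * fs))
    hi = int(round_half_away(window_s[1] * fs))
    starts = onset_idx + lo
    stops = onset_idx + hi  # inclusive
    out_of_bounds = np.flatnonzero((starts < 0) | (stops >= recording.n_samples))
    if out_of_bounds.size:
        rows = retained.iloc[out_of_bounds][["onset", "trial_type"]]
        raise ValueError(
            f"epoch window {window_s} exceeds recording bounds for "
            f"{out_of_bounds.size} event(s):\n{rows.to_string()}"
        )
    n_t = hi - lo + 1
    data = np.empty((len(retained), recording.n_channels, n_t))
    for i, s in enumerate(starts):
        data[i] = recording.data[:, s: s + n_t]
    times = np.arange(lo, hi + 1) / fs
    return EpochSet(
        data=data,
        times=times,
        sfreq=fs,
        channels=recording.channels.copy(),
        trials=retained,
        notched=recording.notched,
        rereferenced=recording.rereferenced,
    )
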