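"""Optional matplotlib panels: per-condition spectrograms, HFB time courses
and tuning curves.  Requires the ``plot`` extra; the core pipeline never
imports this module."""

from __future__ import annotations

import numpy as np

from .containers import HFBResponse, TimeFreqPower
from .stats import TuningFit


def _mpl():
    import matplotlib.pyplot as plt

    return plt


def plot_spectrogram(tfp: TimeFreqPower, channel: int = 0,
                     condition: str | None = None, ax=None):
    """Trial-average time-frequency power for one channel (one condition or
    all trials)."""
    plt = _mpl()
    ax = ax or plt.subplots()[1]
    sel = np.ones(tfp.n_trials, dtype=bool)
    if condition is not None:
        sel = tfp.trials["trial_type"].to_numpy() == str(condition)
    img = tfp.power[sel, channel].mean(axis=0)
    mesh = ax.pcolormesh(tfp.times, tfp.freqs, img, shading="nearest", cmap="magma")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(mesh, ax=ax, label="power")
    return ax


def plot_hfb_courses(hfb: HFBResponse, channel: int = 0, ax=None):
    """Mean ± SEM high-frequency band course per condition."""
    plt = _mpl()
    ax = ax or plt.subplots()[1]
    conds = hfb.trials["trial_type"].to_numpy()
    for cond in sorted(set(conds), key=lambda c: (len(c), c)):
        sel = (conds == cond) & hfb.kept[:, channel]
        if not sel.any():
            continue
        m = hfb.course[sel, channel].mean(axis=0)
        sem = hfb.course[sel, channel].std(axis=0, ddof=1) / np.sqrt(sel.sum())
        ax.plot(hfb.times, m, label=cond)
        ax.fill_between(hfb.times, m - sem, m + sem, alpha=0.2)
    ax.axvspan(0.0, float(hfb.trials["duration"].iloc[0]), color="0.8", alpha=0.5)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel(f"normalized power {hfb.band_hz[0]:g}-{hfb.band_hz[1]:g} Hz")
    ax.legend(title="numerosity", fontsize="small")
    return ax


def plot_tuning_curve(fit: TuningFit, ax=None):
    """Condition means ± SEM with the preferred condition highlighted."""
    plt = _mpl()
    ax = ax or plt.subplots()[1]
    x = np.arange(len(fit.summary))
    ax.errorbar(x, fit.summary["mean"], yerr=fit.summary["sem"], fmt="o-", capsize=3)
    pref = fit.summary.index[fit.summary["condition"] == fit.preferred][0]
    ax.plot(pref, fit.summary["mean"].iloc[pref], "r*", ms=14)
    ax.set_xticks(x, fit.summary["condition"])
    ax.set_xlabel("numerosity")
    ax.set_ylabel("mean HFB response")
    if fit.label:
        ax.set_title(fit.label)
    return ax
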