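"""Synthetic multichannel iEEG with known ground truth.

The generator emulates a clinical acquisition (2048 Hz sampling, 0.15-536 Hz
acquisition band) so the full pipeline can be validated by parameter
recovery.  Each channel is one of four response archetypes:

* ``tuned`` — broadband 60-120 Hz bursts whose amplitude follows a
  log-Gaussian tuning curve ``A_max * exp(-(ln n - ln n_pref)^2 /
  (2 sigma_log^2))`` around a preferred numerosity;
* ``energy`` — bursts growing monotonically with numerosity,
  ``A_max * (n / 20)^gamma`` (a contrast-energy response);
* ``flat`` — equal-amplitude bursts for every numerosity;
* ``silent`` — background only.

Background is Gaussian noise spectrally shaped to 1/f^chi within the
acquisition band, mixed with a shared common-mode series, plus sinusoidal
line noise at 50/100/150 Hz.  Each presentation adds a deterministic
per-condition evoked waveform (identical across trials of a condition,
scaled per channel) and a broadband burst: band-limited 60-120 Hz noise —
not a sinusoid, so the power gain is broadband like real high-frequency
activity — amplitude-modulated by a trapezoidal envelope and scaled by the
archetype's tuning amplitude with lognormal per-trial jitter (unit median).
Burst amplitudes are expressed in units of the background standard
deviation.

All randomness flows from a single seed through named substreams, so the
same plan and seed reproduce identical sample matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import RawRecording, default_channels
from .stim import CATEGORY_LEVELS, NUMEROSITY_LEVELS, StimulusPlan

ARCHETYPES = ("tuned", "energy", "flat", "silent")


@dataclass(frozen=True)
class ChannelSpec:
    """One synthetic channel: name, response archetype and (if tuned) the
    preferred numerosity."""

    name: str
    archetype: str = "silent"
    n_pref: int | None = None
    anatomical_label: str = "other"

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "tuned" and self.n_pref is None:
            raise ValueError(f"tuned channel {self.name!r} needs n_pref")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.  Amplitudes are in background-SD units."""

    sample_rate_hz: float = 2048.0
    acq_band_hz: tuple[float, float] = (0.15, 536.0)
    background_sd_uv: float = 15.0
    chi: float = 1.0  # background spectral exponent (power ~ 1/f^chi)
    common_mode_fraction: float = 0.3
    line_amplitudes: tuple[float, float, float] = (2.0, 0.5, 0.25)  # 50/100/150 Hz
    # tuned-archetype response model
    a_max: float = 2.5
    sigma_log: float = 0.25
    gamma: float = 1.0  # energy-archetype exponent
    amplitude_jitter_sigma: float = 0.15  # lognormal, unit median
    # burst envelope (seconds relative to stimulus onset)
    burst_latency_s: float = 0.150
    burst_rise_s: float = 0.050
    burst_duration_s: float = 0.300
    burst_band_hz: tuple[float, float] = (60.0, 120.0)
    # evoked component
    evoked_amplitude: float = 1.5  # background-SD units
    evoked_freq_hz: float = 8.0
    evoked_decay_s: float = 0.120
    evoked_duration_s: float = 0.500
    # per-archetype response gain on visual-category trials (tuned channels
    # are numerosity-only; energy/flat channels respond to any contrast)
    category_gain: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 0.0)
    # artifact injection
    artifact_amplitude: float = 40.0  # background-SD units
    artifact_broadband_fraction: float = 0.3
    max_duration_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if not 0 <= self.common_mode_fraction <= 1:
            raise ValueError("common_mode_fraction must lie in [0, 1]")
        for name in ("a_max", "background_sd_uv", "artifact_amplitude",
                     "evoked_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator injected: per-channel archetype/preference, the
    per-trial burst amplitude actually applied, and per-trial artifact flags."""

    channels: pd.DataFrame  # name, archetype, n_pref
    amplitudes: np.ndarray  # (n_events, n_channels), background-SD units
    artifact: np.ndarray  # (n_events,) bool

    def copy(self) -> "GroundTruth":
        return GroundTruth(self.channels.copy(), self.amplitudes.copy(),
                           self.artifact.copy())


def tuning_amplitude(n, config: SynthConfig, archetype: str,
                     n_pref: int | None = None) -> float:
    """Burst amplitude (background-SD units) for numerosity ``n``."""
    if archetype == "silent":
        return 0.0
    if archetype == "flat":
        return config.a_max
    if archetype == "energy":
        return config.a_max * (float(n) / 20.0) ** config.gamma
    if archetype == "tuned":
        if n_pref is None:
            raise ValueError("tuned amplitude needs n_pref")
        z = (np.log(float(n)) - np.log(float(n_pref))) / config.sigma_log
        return config.a_max * float(np.exp(-0.5 * z * z))
    raise ValueError(f"unknown archetype {archetype!r}")


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, chi: float,
                  band: tuple[float, float]) -> np.ndarray:
    """Unit-SD Gaussian noise with amplitude spectrum ~ f^(-chi/2) inside the
    acquisition band (raised-cosine edges outside it)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    pos = f > 0
    shape[pos] = np.maximum(f[pos], band[0]) ** (-chi / 2.0)
    shape[0] = 0.0  # no DC
    lo, hi = band
    shape[f < lo] *= 0.5 * (1 - np.cos(np.pi * np.clip(f[f < lo] / max(lo, 1e-6), 0, 1)))
    edge = np.clip((f - hi) / (0.1 * hi), 0, 1)
    shape *= 0.5 * (1 + np.cos(np.pi * edge))
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to ``band`` (hard FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def _burst_envelope(config: SynthConfig, fs: float) -> np.ndarray:
    """Trapezoid: rise over burst_rise_s, plateau, fall; peak 1."""
    n = int(round(config.burst_duration_s * fs))
    t = np.arange(n) / fs
    rise = config.burst_rise_s
    env = np.ones(n)
    env = np.minimum(env, t / rise)
    env = np.minimum(env, (config.burst_duration_s - t) / rise)
    return np.clip(env, 0.0, 1.0)


def _evoked_waveform(config: SynthConfig, fs: float, scale: float) -> np.ndarray:
    n = int(round(config.evoked_duration_s * fs))
    t = np.arange(n) / fs
    return (
        scale
        * config.evoked_amplitude
        * np.sin(2 * np.pi * config.evoked_freq_hz * t)
        * np.exp(-t / config.evoked_decay_s)
    )


def _condition_rank(trial_type: str) -> int:
    levels = [str(v) for v in NUMEROSITY_LEVELS] + list(CATEGORY_LEVELS)
    return levels.index(trial_type) if trial_type in levels else len(levels)


def simulate_run(plan: StimulusPlan, config: SynthConfig,
                 channels: list[ChannelSpec]) -> tuple[RawRecording, pd.DataFrame, GroundTruth]:
    """Simulate one run for the given channel archetypes.

    Returns the raw recording (microvolts), a copy of the plan's event table
    and the injected ground truth.  Fully reproducible from ``config.seed``.
    """
    if plan.total_duration_s > config.max_duration_s:
        raise ValueError(
            f"plan duration {plan.total_duration_s:.1f} s exceeds the maximum "
            f"{config.max_duration_s:.1f} s"
        )
    fs = config.sample_rate_hz
    n_samp = int(round(plan.total_duration_s * fs))
    n_ch = len(channels)
    events = plan.events
    n_ev = len(events)

    root = np.random.SeedSequence(config.seed)
    ss_common, ss_chan, ss_burst, ss_gain = root.spawn(4)
    rng_common = np.random.default_rng(ss_common)
    chan_rngs = [np.random.default_rng(s) for s in ss_chan.spawn(max(n_ch, 1))]
    rng_burst = np.random.default_rng(ss_burst)
    rng_gain = np.random.default_rng(ss_gain)

    sd = config.background_sd_uv
    common = _shaped_noise(rng_common, n_samp, fs, config.chi, config.acq_band_hz)
    t = np.arange(n_samp) / fs
    line = np.zeros(n_samp)
    for amp, f0 in zip(config.line_amplitudes, (50.0, 100.0, 150.0)):
        line += amp * np.sin(2 * np.pi * f0 * t + rng_common.uniform(0, 2 * np.pi))

    c = config.common_mode_fraction
    data = np.empty((n_ch, n_samp))
    for i, rng in enumerate(chan_rngs[:n_ch]):
        own = _shaped_noise(rng, n_samp, fs, config.chi, config.acq_band_hz)
        data[i] = sd * (np.sqrt(1 - c) * own + np.sqrt(c) * common + line)

    # deterministic per-condition evoked waveforms, per-channel gain
    evoked_gains = rng_gain.uniform(0.5, 1.5, size=n_ch)
    onsets_idx = np.rint(events["onset"].to_numpy() * fs).astype(int)
    is_category = events["trial_type"].isin(CATEGORY_LEVELS).to_numpy()
    cond_scale = {
        tt: 0.5 + 0.1 * _condition_rank(tt)
        for tt in events["trial_type"].unique()
    }
    for i in range(n_ch):
        for tt, s0 in cond_scale.items():
            w = _evoked_waveform(config, fs, s0 * evoked_gains[i]) * sd
            for j in np.flatnonzero(events["trial_type"].to_numpy() == tt):
                k = onsets_idx[j]
                seg = w[: max(0, min(len(w), n_samp - k))]
                data[i, k: k + len(seg)] += seg

    # broadband bursts
    env = _burst_envelope(config, fs)
    lat = int(round(config.burst_latency_s * fs))
    cat_gain = dict(zip(ARCHETYPES, config.category_gain))
    amplitudes = np.zeros((n_ev, n_ch))
    for i, spec in enumerate(channels):
        for j in range(n_ev):
            tt = events["trial_type"].iloc[j]
            if is_category[j]:
                amp = cat_gain[spec.archetype] * config.a_max
            else:
                amp = tuning_amplitude(int(tt), config, spec.archetype, spec.n_pref)
            if amp <= 0:
                continue
            jit = float(
                np.exp(config.amplitude_jitter_sigma * rng_burst.standard_normal())
            )
            a = amp * jit
            carrier = _bandlimited_noise(rng_burst, env.size, fs, config.burst_band_hz)
            k = onsets_idx[j] + lat
            seg = (a * sd) * env * carrier
            seg = seg[: max(0, min(env.size, n_samp - k))]
            data[i, k: k + len(seg)] += seg
            amplitudes[j, i] = a

    ch_table = default_channels([s.name for s in channels], kind="seeg")
    ch_table["anatomical_label"] = [s.anatomical_label for s in channels]
    truth = GroundTruth(
        channels=pd.DataFrame(
            {
                "name": [s.name for s in channels],
                "archetype": [s.archetype for s in channels],
                "n_pref": [s.n_pref for s in channels],
            }
        ),
        amplitudes=amplitudes,
        artifact=np.zeros(n_ev, dtype=bool),
    )
    rec = RawRecording(
        data=data,
        sfreq=fs,
        channels=ch_table,
        reference="synthetic common reference",
        acq_band_hz=config.acq_band_hz,
    )
    return rec, events.copy(), truth


def inject_artifact_trials(recording: RawRecording, events: pd.DataFrame,
                           fraction: float, seed: int,
                           config: SynthConfig | None = None) -> tuple[RawRecording, np.ndarray]:
    """Add large pre-stimulus artifacts to a seeded subset of trials.

    Exactly ``round(fraction * n_events)`` trials receive, over the 400 ms
    before onset, a slow half-sine drift plus a proportional broadband
    component (movement-like artifacts are broadband; a purely slow drift
    carries no 60-120 Hz power and would evade a high-frequency QC screen).
    Amplitudes are chosen to exceed the default QC thresholds by
    construction.  Returns the modified recording and per-trial flags.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    config = config or SynthConfig()
    n_ev = len(events)
    n_flag = int(round(fraction * n_ev))
    flags = np.zeros(n_ev, dtype=bool)
    if n_flag == 0:
        return recording, flags
    rng = np.random.default_rng(seed)
    flags[rng.choice(n_ev, size=n_flag, replace=False)] = True

    fs = recording.sfreq
    out = recording.copy()
    sd = config.background_sd_uv
    amp = config.artifact_amplitude * sd
    span = int(round(0.400 * fs))
    gap = int(round(0.050 * fs))
    tt = np.arange(span) / fs
    drift = np.sin(np.pi * tt / tt[-1])  # one slow half-cycle
    for j in np.flatnonzero(flags):
        onset = int(np.rint(events["onset"].iloc[j] * fs))
        k = onset - gap - span
        if k < 0:
            k = 0
        seg = slice(k, k + span)
        noise = rng.standard_normal((out.n_channels, span))
        out.data[:, seg] += amp * (
            drift[None, :] + config.artifact_broadband_fraction * noise
        )
    return out, flags


def tuned_channel_set(n_channels: int, n_pref: int, prefix: str = "T") -> list[ChannelSpec]:
    return [
        ChannelSpec(f"{prefix}{n_pref}_{i:03d}", "tuned", n_pref, "parietal")
        for i in range(n_channels)
    ]


def silent_channel_set(n_channels: int, prefix: str = "S") -> list[ChannelSpec]:
    return [ChannelSpec(f"{prefix}{i:03d}", "silent", None) for i in range(n_channels)]
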