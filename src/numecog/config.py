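"""Run configuration: dataclasses with validation and YAML loading.

One configuration object drives the whole pipeline.  Defaults reproduce the
standard analysis: 50/100/150 Hz notch of width 3 Hz, common-average
reference, epochs -0.5..+1.0 s, 2-122 Hz spectral grid in 2 Hz steps with a
300 ms Hanning sliding window stepped every 10 ms from -0.2 to +0.7 s,
per-frequency normalization, window-mode baseline over [-0.2, -0.05] s, a
60-120 Hz high-frequency band, and a 0.100-0.350 s tuning window.

"Participant-1 mode" models a recording whose trigger channel carried a
fixed unknown delay (~100 ms): the analysis window becomes 0-0.250 s, the
baseline is the single point at -0.200 s, and a trigger offset is carried
through epoching.  These three switches are coupled; setting them
inconsistently is a validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """A configuration value violates its contract; message carries the key path."""


@dataclass
class PreprocConfig:
    line_freqs_hz: tuple[float, ...] = (50.0, 100.0, 150.0)
    notch_width_hz: float = 3.0
    epoch_window_s: tuple[float, float] = (-0.500, 1.000)
    category_epoch_window_s: tuple[float, float] = (-0.200, 1.250)

    def validate(self, path: str = "preproc") -> None:
        if self.notch_width_hz <= 0:
            raise ConfigError(f"{path}.notch_width_hz must be > 0")
        for name in ("epoch_window_s", "category_epoch_window_s"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ConfigError(f"{path}.{name}: window start must precede end")


@dataclass
class SpectralConfig:
    freq_range_hz: tuple[float, float] = (2.0, 122.0)
    freq_step_hz: float = 2.0
    window_s: float = 0.300
    taper: str = "hanning"
    time_range_s: tuple[float, float] = (-0.200, 0.700)
    time_step_s: float = 0.010
    category_time_range_s: tuple[float, float] = (-0.050, 1.100)
    hfb_band_hz: tuple[float, float] = (60.0, 120.0)
    normalization_scope: str = "per_run"  # or 'per_session'

    def validate(self, path: str = "spectral") -> None:
        lo, hi = self.freq_range_hz
        if not 0 < lo <= hi:
            raise ConfigError(f"{path}.freq_range_hz must satisfy 0 < lo <= hi")
        blo, bhi = self.hfb_band_hz
        if not blo <= bhi:
            raise ConfigError(f"{path}.hfb_band_hz: band reversed ({blo} > {bhi})")
        if not (lo <= blo and bhi <= hi):
            raise ConfigError(f"{path}.hfb_band_hz must lie inside freq_range_hz")
        if self.window_s <= 0 or self.freq_step_hz <= 0 or self.time_step_s <= 0:
            raise ConfigError(f"{path}: window_s, freq_step_hz, time_step_s must be > 0")
        if self.taper not in ("hanning",):
            raise ConfigError(f"{path}.taper: unknown taper {self.taper!r}")
        if self.normalization_scope not in ("per_run", "per_session"):
            raise ConfigError(f"{path}.normalization_scope must be per_run|per_session")


@dataclass
class QCConfig:
    prestim_threshold: float = 0.5  # normalized-power units
    prestim_stat: str = "sd"  # 'sd' (default) or 'range'
    baseline_sd_threshold: float = 3.0
    prestim_window_s: tuple[float, float] = (-0.200, 0.0)  # half-open [lo, hi)
    baseline_window_s: tuple[float, float] = (-0.200, -0.050)  # closed

    def validate(self, path: str = "qc") -> None:
        if self.prestim_threshold <= 0 or self.baseline_sd_threshold <= 0:
            raise ConfigError(f"{path}: thresholds must be > 0")
        if self.prestim_stat not in ("sd", "range"):
            raise ConfigError(f"{path}.prestim_stat must be 'sd' or 'range'")
        for name in ("prestim_window_s", "baseline_window_s"):
            lo, hi = getattr(self, name)
            if lo >= hi or hi > 0:
                raise ConfigError(f"{path}.{name} must be pre-onset with lo < hi")


@dataclass
class AnalysisConfig:
    participant1_mode: bool = False
    tuning_window_s: tuple[float, float] | None = None  # resolved in validate()
    category_window_s: tuple[float, float] = (0.100, 0.350)
    baseline_mode: str | None = None  # 'window' | 'point'; resolved in validate()
    baseline_window_s: tuple[float, float] = (-0.200, -0.050)
    baseline_point_s: float = -0.200
    category_baseline_window_s: tuple[float, float] = (-0.050, 0.0)
    trigger_offset_s: float = 0.0
    alpha: float = 0.05
    multiple_comparison: str = "none"  # 'none' | 'bonferroni' | 'holm'
    min_significant_lower: int = 3
    spearman_min: float = 0.8
    pool_all_numerosities_vs_categories: bool = False

    P1_WINDOW = (0.0, 0.250)
    STANDARD_WINDOW = (0.100, 0.350)

    def validate(self, path: str = "analysis") -> None:
        # A 0-250 ms window is the delayed-trigger analysis; selecting it
        # selects participant-1 mode, and the coupled switches must agree.
        if self.tuning_window_s is not None:
            tw = tuple(self.tuning_window_s)
            if tw == self.P1_WINDOW and not self.participant1_mode:
                self.participant1_mode = True
        if self.participant1_mode:
            if self.baseline_mode == "window":
                raise ConfigError(
                    f"{path}: participant1_mode couples a point-mode baseline "
                    "with the 0-250 ms window; baseline_mode='window' conflicts"
                )
            if self.tuning_window_s is not None and tuple(self.tuning_window_s) != self.P1_WINDOW:
                raise ConfigError(
                    f"{path}: participant1_mode requires tuning_window_s "
                    f"{self.P1_WINDOW}, got {tuple(self.tuning_window_s)}"
                )
            self.baseline_mode = "point"
            self.tuning_window_s = self.P1_WINDOW
        else:
            if self.baseline_mode is None:
                self.baseline_mode = "window"
            if self.tuning_window_s is None:
                self.tuning_window_s = self.STANDARD_WINDOW
        if self.baseline_mode not in ("window", "point"):
            raise ConfigError(f"{path}.baseline_mode must be 'window' or 'point'")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"{path}.alpha must lie in (0, 1)")
        if self.multiple_comparison not in ("none", "bonferroni", "holm"):
            raise ConfigError(f"{path}.multiple_comparison: unknown method")
        lo, hi = self.tuning_window_s
        if lo >= hi:
            raise ConfigError(f"{path}.tuning_window_s must have lo < hi")


@dataclass
class PipelineConfig:
    """Top-level configuration; one file drives the whole pipeline."""

    mode: str = "synthesize"  # 'synthesize' | 'analyze'
    seed: int | None = None
    raw_path: str | None = None
    events_path: str | None = None
    channels_path: str | None = None
    output_dir: str = "results"
    log_level: str = "INFO"
    run_kind: str = "sequential"
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    synth: dict = field(default_factory=dict)  # forwarded to synth.SynthConfig
    stim: dict = field(default_factory=dict)  # forwarded to stim.StimParams

    def validate(self) -> None:
        if self.mode not in ("synthesize", "analyze"):
            raise ConfigError("mode must be 'synthesize' or 'analyze'")
        if self.run_kind not in ("sequential", "randomized", "category"):
            raise ConfigError(f"run_kind: unknown kind {self.run_kind!r}")
        self.preproc.validate()
        self.spectral.validate()
        self.qc.validate()
        self.analysis.validate()

    def resolved_parameters(self) -> dict[str, Any]:
        """Flat key-path -> value map of every resolved parameter (for the run log)."""
        out: dict[str, Any] = {}

        def walk(prefix: str, obj: Any) -> None:
            if is_dataclass(obj) and not isinstance(obj, type):
                for f in fields(obj):
                    walk(f"{prefix}{f.name}.", getattr(obj, f.name))
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}{k}.", v)
            else:
                out[prefix[:-1]] = obj

        walk("", self)
        return out


def _coerce_section(cls, data: dict, path: str):
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown configuration key: {path}.{key}")
        f = valid[key]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(data: dict | None) -> PipelineConfig:
    """Build and validate a :class:`PipelineConfig` from a nested mapping."""
    data = dict(data or {})
    sections = {"preproc": PreprocConfig, "spectral": SpectralConfig,
                "qc": QCConfig, "analysis": AnalysisConfig}
    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        sub = data.pop(name, None)
        if sub is not None:
            if not isinstance(sub, dict):
                raise ConfigError(f"{name}: expected a mapping")
            kwargs[name] = _coerce_section(cls, sub, name)
    top_fields = {f.name for f in fields(PipelineConfig)}
    for key, value in data.items():
        if key not in top_fields:
            raise ConfigError(f"unknown configuration key: {key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML configuration file; an empty file yields all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
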