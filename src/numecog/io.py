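"""Readers and writers for every external artifact.

Raw recordings travel as European Data Format (EDF) files — the clinical
interchange standard for this class of data — with voltages in microvolts
and 16-bit quantization over a configurable physical range (default
±3276.7 µV, i.e. 0.1 µV resolution).  Events and channel metadata travel as
tab-separated tables with BIDS-iEEG-style columns; configuration as YAML
(see :mod:`numecog.config`).

The EDF codec here implements the published fixed-layout header (256 bytes
plus 256 per signal) and int16 little-endian data records directly; a
round-trip is lossy only through quantization.  Third-party readers (e.g.
MNE) parse the files produced here.
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from .config import load_config  # noqa: F401  (re-exported module surface)
from .containers import CHANNEL_COLUMNS, RawRecording, default_channels

EDF_DIG_MIN = -32768
EDF_DIG_MAX = 32767
DEFAULT_PHYSICAL_RANGE = (-3276.7, 3276.7)

_REQUIRED_EVENT_COLUMNS = ("onset", "duration", "trial_type")


class EdfError(IOError):
    """Malformed or unsupported EDF content."""


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _num(value, width: int) -> bytes:
    s = f"{value:.{width - 1}g}"
    if len(s) > width:
        s = f"{value:.{width - 3}g}"
    return _ascii(s, width)


def write_raw_edf(recording: RawRecording, path: str | Path,
                  physical_range: tuple[float, float] = DEFAULT_PHYSICAL_RANGE) -> None:
    """Write a recording as a standard EDF file.

    Raises if samples are non-finite or exceed the physical range (no silent
    clipping).  The final partial data record, if any, is padded with
    physical zero; padding only ever extends the read-back length.
    """
    data = np.asarray(recording.data, dtype=float)
    if data.shape[0] == 0:
        raise EdfError("cannot write an EDF file with no channels")
    if not np.isfinite(data).all():
        raise EdfError("recording contains non-finite samples")
    pmin, pmax = physical_range
    if data.min() < pmin or data.max() > pmax:
        raise EdfError(
            f"samples span [{data.min():.1f}, {data.max():.1f}] µV, outside "
            f"the physical range [{pmin}, {pmax}]; widen physical_range"
        )
    sfreq = recording.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise EdfError("only integer sampling rates are supported for EDF export")
    spr = int(round(sfreq))  # one-second data records
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / spr))

    scale = (EDF_DIG_MAX - EDF_DIG_MIN) / (pmax - pmin)
    dig = np.rint((data - pmin) * scale + EDF_DIG_MIN).astype("<i2")
    pad_value = np.int16(round((0.0 - pmin) * scale + EDF_DIG_MIN))
    padded = np.full((n_ch, n_rec * spr), pad_value, dtype="<i2")
    padded[:, :n_samp] = dig

    names = recording.ch_names
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _num(256 * (n_ch + 1), 8),
        _ascii("", 44),
        _num(n_rec, 8),
        _num(1, 8),
        _num(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(nm, 16) for nm in names),
        b"".join(_ascii("", 80) for _ in names),
        b"".join(_ascii("uV", 8) for _ in names),
        b"".join(_num(pmin, 8) for _ in names),
        b"".join(_num(pmax, 8) for _ in names),
        b"".join(_num(EDF_DIG_MIN, 8) for _ in names),
        b"".join(_num(EDF_DIG_MAX, 8) for _ in names),
        b"".join(
            _ascii(f"BP:{recording.acq_band_hz[0]}-{recording.acq_band_hz[1]}Hz", 80)
            for _ in names
        ),
        b"".join(_num(spr, 8) for _ in names),
        b"".join(_ascii("", 32) for _ in names),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-interleaved layout: all samples of signal 0, then 1, ... per record
        records = padded.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(records).tobytes())


def _read_field(buf: bytes, offset: int, width: int, count: int = 1) -> list[str]:
    return [
        buf[offset + i * width: offset + (i + 1) * width].decode("ascii").strip()
        for i in range(count)
    ]


def read_raw_edf(path: str | Path, resample: bool = False,
                 channels: pd.DataFrame | None = None) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (microvolts).

    Channels stored at a lower per-record sample count than the fastest
    channel raise an error naming the channel, unless ``resample=True`` in
    which case they are polyphase-resampled to the fastest rate.  Optional
    ``channels`` metadata (name, anatomical_label, include, kind) replaces
    the defaults.
    """
    from scipy.signal import resample_poly

    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfError(f"{path}: file too short for an EDF header")
    try:
        n_rec = int(_read_field(raw, 236, 8)[0])
        rec_dur = float(_read_field(raw, 244, 8)[0])
        n_sig = int(_read_field(raw, 252, 4)[0])
    except ValueError as exc:
        raise EdfError(f"{path}: malformed EDF header") from exc
    if n_sig <= 0 or rec_dur <= 0:
        raise EdfError(f"{path}: malformed EDF header (ns={n_sig}, dur={rec_dur})")
    hdr_len = 256 + 256 * n_sig
    if len(raw) < hdr_len:
        raise EdfError(f"{path}: truncated signal header")
    off = 256
    labels = _read_field(raw, off, 16, n_sig); off += 16 * n_sig
    off += 80 * n_sig  # transducer
    off += 8 * n_sig  # physical dimension
    pmins = [float(v) for v in _read_field(raw, off, 8, n_sig)]; off += 8 * n_sig
    pmaxs = [float(v) for v in _read_field(raw, off, 8, n_sig)]; off += 8 * n_sig
    dmins = [int(float(v)) for v in _read_field(raw, off, 8, n_sig)]; off += 8 * n_sig
    dmaxs = [int(float(v)) for v in _read_field(raw, off, 8, n_sig)]; off += 8 * n_sig
    off += 80 * n_sig  # prefiltering
    sprs = [int(float(v)) for v in _read_field(raw, off, 8, n_sig)]

    rec_len = sum(sprs)
    body = np.frombuffer(raw, dtype="<i2", offset=hdr_len)
    if n_rec < 0:  # unknown record count: infer from file size
        n_rec = body.size // rec_len
    if body.size < n_rec * rec_len:
        raise EdfError(f"{path}: data section shorter than header promises")
    body = body[: n_rec * rec_len].reshape(n_rec, rec_len)

    spr_max = max(sprs)
    mixed = [labels[i] for i in range(n_sig) if sprs[i] != spr_max]
    if mixed and not resample:
        raise EdfError(
            f"{path}: channels {mixed} have a different sampling rate than the "
            "fastest channel; pass resample=True to resample them"
        )
    sfreq = spr_max / rec_dur

    data = np.empty((n_sig, n_rec * spr_max))
    start = 0
    for i in range(n_sig):
        sig = body[:, start: start + sprs[i]].reshape(-1).astype(float)
        start += sprs[i]
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (sig - dmins[i]) * gain + pmins[i]
        if sprs[i] != spr_max:
            phys = resample_poly(phys, spr_max, sprs[i])
        data[i] = phys
    if not np.isfinite(data).all():
        raise EdfError(f"{path}: non-finite samples after scaling")

    if channels is None:
        channels = default_channels(labels)
    else:
        channels = channels.reset_index(drop=True)
        if list(channels["name"]) != labels:
            raise EdfError(
                f"{path}: channel metadata names do not match EDF labels"
            )
    return RawRecording(data=data, sfreq=sfreq, channels=channels)


# --- events / channels tables -------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an events table as tab-separated text (onset/duration in s)."""
    missing = [c for c in _REQUIRED_EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table is missing required column(s): {missing}")
    out = events.copy()
    for col in ("is_oddball", "keep"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read an events table; validates columns and onset monotonicity."""
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    events["trial_type"] = events["trial_type"].astype(str)
    for col in ("is_oddball", "keep"):
        if col in events.columns:
            events[col] = events[col].astype(bool)
    if len(events) > 1 and not np.all(np.diff(events["onset"].to_numpy()) > 0):
        raise ValueError(f"{path}: event onsets must be strictly increasing")
    return events


def write_channels_tsv(channels: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise ValueError(f"channels table is missing column(s): {missing}")
    out = channels.copy()
    out["include"] = out["include"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_channels_tsv(path: str | Path) -> pd.DataFrame:
    channels = pd.read_csv(path, sep="\t")
    missing = [c for c in CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {missing}")
    channels["include"] = channels["include"].astype(bool)
    return channels


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy results table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def channel_selection(channels: pd.DataFrame) -> list[str]:
    """Included channel names; the analysis selection is always an input."""
    names = list(channels.loc[channels["include"], "name"])
    if not names:
        raise ValueError("channel selection is empty: no channel has include=True")
    return names
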