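"""Recording container and file I/O: EDF signals, hypnogram and result CSVs.

Recordings are paired EEG/EMG sample streams at a fixed rate (500 Hz in the
telemetry setup this package targets). On disk they are exchanged as plain
EDF (European Data Format, 16-bit): a self-contained reader/writer for the
classic two-channel case is implemented here, with 1-s data records and
per-channel physical scaling, so round trips preserve samples to within one
quantization step of the stored physical range.

Hypnograms travel as CSV with header ``epoch_index,start_s,state,artifact``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import STATES, Hypnogram
from .stimulus import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "read_edf",
    "write_edf",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
]


@dataclass
class Recording:
    """Paired EEG/EMG streams at a fixed sampling rate.

    ``start_time_s`` is seconds since lights-on (ZT0); ``protocol`` optionally
    records the stimulation the recording was made under.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = 500.0
    start_time_s: float = 0.0
    subject_id: str = ""
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D arrays of equal length")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# EDF (16-bit, classic): fixed 256-byte main header + 256 bytes per signal,
# then int16 little-endian data records of 1 s each.
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _phys_range(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:  # widen a flat channel so the gain is non-zero
        lo, hi = lo - 1.0, hi + 1.0
    return lo, hi


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a two-channel (EEG, EMG) 16-bit EDF file.

    Uses 1-s data records, so the sampling rate must be a whole number of
    samples per second and the recording a whole number of seconds. The
    recording's ZT start time is stored in the EDF start-time field
    (seconds-of-day resolution), so it must be an integer number of seconds.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs_i = int(round(fs))
    n = recording.n_samples
    if n % fs_i != 0:
        raise ValueError(
            f"recording must span whole seconds: {n} samples at {fs_i} Hz"
        )
    if abs(recording.start_time_s - round(recording.start_time_s)) > 1e-9:
        raise ValueError("start_time_s must be an integer number of seconds for EDF")
    n_records = n // fs_i

    start = int(round(recording.start_time_s))
    days, rem = divmod(start, 86400)
    hh, rem = divmod(rem, 3600)
    mm, ss = divmod(rem, 60)

    channels = [("EEG", recording.eeg), ("EMG", recording.emg)]
    ns = len(channels)
    header_bytes = 256 * (1 + ns)

    buf = bytearray()
    buf += _fmt("0", 8)  # version
    buf += _fmt(recording.subject_id or "X", 80)  # patient id
    buf += _fmt("slowwave recording", 80)  # recording id
    buf += _fmt(f"{1 + days:02d}.01.00", 8)  # start date (day offset encodes ZT days)
    buf += _fmt(f"{hh:02d}.{mm:02d}.{ss:02d}", 8)  # start time
    buf += _fmt(header_bytes, 8)
    buf += _fmt("", 44)  # reserved
    buf += _fmt(n_records, 8)
    buf += _fmt(1, 8)  # record duration (s)
    buf += _fmt(ns, 4)

    ranges = [_phys_range(x) for _, x in channels]
    for (label, _), _rng in zip(channels, ranges):
        buf += _fmt(label, 16)
    for _ in channels:
        buf += _fmt("", 80)  # transducer
    for _ in channels:
        buf += _fmt("uV", 8)  # physical dimension
    for lo, hi in ranges:
        buf += _fmt(f"{lo:.6g}", 8)
    for lo, hi in ranges:
        buf += _fmt(f"{hi:.6g}", 8)
    for _ in channels:
        buf += _fmt(_DIG_MIN, 8)
    for _ in channels:
        buf += _fmt(_DIG_MAX, 8)
    for _ in channels:
        buf += _fmt("", 80)  # prefiltering
    for _ in channels:
        buf += _fmt(fs_i, 8)  # samples per record
    for _ in channels:
        buf += _fmt("", 32)  # reserved

    digital = []
    for (_, x), (lo, hi) in zip(channels, ranges):
        gain = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        d = np.round((x - lo) / gain).astype(np.int64) + _DIG_MIN
        digital.append(np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(bytes(buf))
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * fs_i : (r + 1) * fs_i].tobytes())


def _read_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> Recording:
    """Read a two-channel EDF file with channels labelled EEG and EMG.

    Channel matching is case-insensitive on the label prefix. Both channels
    must share the sampling rate. Physical values are reconstructed from the
    stored 16-bit data and per-channel scaling.
    """
    with open(path, "rb") as fh:
        fh.read(8)  # version
        fh.read(80)  # patient
        fh.read(80)  # recording
        date = _read_field(fh, 8)
        time_ = _read_field(fh, 8)
        fh.read(8)  # header bytes
        fh.read(44)
        n_records = int(_read_field(fh, 8))
        record_dur = float(_read_field(fh, 8))
        ns = int(_read_field(fh, 4))

        labels = [_read_field(fh, 16) for _ in range(ns)]
        fh.read(80 * ns)  # transducer
        fh.read(8 * ns)  # dimension
        phys_min = [float(_read_field(fh, 8)) for _ in range(ns)]
        phys_max = [float(_read_field(fh, 8)) for _ in range(ns)]
        dig_min = [int(_read_field(fh, 8)) for _ in range(ns)]
        dig_max = [int(_read_field(fh, 8)) for _ in range(ns)]
        fh.read(80 * ns)  # prefiltering
        spr = [int(_read_field(fh, 8)) for _ in range(ns)]
        fh.read(32 * ns)

        raw = np.frombuffer(fh.read(), dtype="<i2")

    def find(prefix: str) -> int:
        for i, lab in enumerate(labels):
            if lab.upper().startswith(prefix):
                return i
        raise ValueError(
            f"EDF file has no channel labelled {prefix}; available: {labels}"
        )

    i_eeg, i_emg = find("EEG"), find("EMG")
    if spr[i_eeg] != spr[i_emg]:
        raise ValueError(
            f"EEG/EMG sampling rates differ: {spr[i_eeg]} vs {spr[i_emg]} per record"
        )
    fs = spr[i_eeg] / record_dur

    per_record = sum(spr)
    raw = raw[: n_records * per_record].reshape(n_records, per_record)
    offsets = np.cumsum([0] + spr)

    def channel(i: int) -> np.ndarray:
        d = raw[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        return phys_min[i] + (d - dig_min[i]) * gain

    hh, mm, ss = (int(p) for p in time_.split("."))
    day = int(date.split(".")[0])
    start_s = (day - 1) * 86400 + hh * 3600 + mm * 60 + ss

    return Recording(
        eeg=channel(i_eeg),
        emg=channel(i_emg),
        fs=fs,
        start_time_s=float(start_s),
    )


# ---------------------------------------------------------------------------
# Hypnogram CSV dialect: epoch_index,start_s,state,artifact
# ---------------------------------------------------------------------------


def write_hypnogram_csv(hypnogram: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "start_s": hypnogram.start_time_s
            + np.arange(hypnogram.n_epochs) * hypnogram.epoch_len_s,
            "state": hypnogram.states,
            "artifact": hypnogram.artifact_flags.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    required = {"epoch_index", "start_s", "state", "artifact"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"hypnogram CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise ValueError(f"unknown state labels in {path}: {sorted(bad)}")
    if len(df) > 1:
        epoch_len = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
    else:
        epoch_len = 5.0
    return Hypnogram(
        states=df["state"].to_numpy(dtype=object),
        artifact_flags=df["artifact"].to_numpy(dtype=bool),
        epoch_len_s=epoch_len,
        start_time_s=float(df["start_s"].iloc[0]),
    )
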