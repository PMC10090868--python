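"""Recording and hypnogram I/O, epoch segmentation and scheme merging.

Recordings are read from plain two-column CSV (``time_s,ppg``) or from EDF
(via :mod:`mne`, if installed).  Hypnograms are CSV with rows
``epoch_index,stage``; stage tokens are translated through a configurable
alias table (AASM N1/N2 -> LS, N3 -> DS, W -> WAKE, R -> REM by default).
Epochs are 30 s, non-overlapping, 0-based with half-open sample windows;
a trailing partial epoch is discarded.
"""

from __future__ import annotations

import csv
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .stages import DEFAULT_ALIASES, merge_stages  # noqa: F401  (re-export)

EPOCH_S = 30.0


@dataclass
class PPGRecording:
    """A raw PPG waveform with its sampling rate."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    start_time: object = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Epoch:
    """One 30 s labelled segment of a recording."""

    samples: np.ndarray
    fs: float
    index: int
    label: str
    valid: bool = True


def write_recording_csv(rec: PPGRecording, path: str | Path) -> None:
    """Write a recording as ``time_s,ppg`` CSV (full float precision)."""
    n = len(rec.samples)
    t = np.arange(n) / rec.fs
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "ppg"])
        for ti, xi in zip(t, rec.samples):
            w.writerow([repr(float(ti)), repr(float(xi))])


def _read_recording_csv(path: str | Path) -> PPGRecording:
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.size < 2 or "time_s" not in (data.dtype.names or ()):
        raise ValueError(f"unparseable recording CSV: {path}")
    t = np.asarray(data["time_s"], dtype=float)
    x = np.asarray(data["ppg"], dtype=float)
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError(f"non-increasing time column in {path}")
    fs = float(np.round(1.0 / dt, 6))
    return PPGRecording(samples=x, fs=fs)


def _read_recording_edf(path: str | Path, channel: str) -> PPGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not found in {path}; available: {raw.ch_names}")
    picked = raw.copy().pick([channel])
    return PPGRecording(samples=picked.get_data()[0], fs=float(picked.info["sfreq"]))


def read_recording(path: str | Path, format: str | None = None,
                   channel: str = "PPG") -> PPGRecording:
    """Read a PPG recording from CSV or EDF.

    ``format`` is inferred from the file suffix when omitted.  For EDF the
    named channel must exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_recording_csv(path)
    if format == "edf":
        return _read_recording_edf(path, channel)
    raise ValueError(f"unknown recording format {format!r}")


def write_hypnogram_csv(labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "stage"])
        for i, lab in enumerate(labels):
            w.writerow([i, lab])


def read_hypnogram(path: str | Path,
                   aliases: Mapping[str, str] | None = None) -> list[str]:
    """Read a hypnogram CSV into four-class stage labels.

    Accepts either ``epoch_index,stage`` rows or a single stage column;
    a header row is detected and skipped.  Unknown tokens raise an error
    naming the row and token.
    """
    aliases = dict(DEFAULT_ALIASES if aliases is None else aliases)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels: list[str] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty hypnogram file: {path}")
    start = 0
    head = [c.strip().lower() for c in rows[0]]
    if "stage" in head or "epoch_index" in head:
        start = 1
    if start == len(rows):
        raise ValueError(f"hypnogram {path} contains a header but no rows")
    for i, row in enumerate(rows[start:], start=start):
        token = row[-1].strip().upper()
        if token not in aliases:
            raise ValueError(f"row {i}: unknown stage token {row[-1]!r}")
        labels.append(aliases[token])
    return labels


def segment_epochs(rec: PPGRecording, labels: Sequence[str]) -> list[Epoch]:
    """Slice a recording into labelled 30 s non-overlapping epochs.

    Epoch ``i`` covers samples ``[i*30*fs, (i+1)*30*fs)``; trailing samples
    not filling a whole epoch are discarded.  There must be at least one
    full epoch per label.
    """
    spe = int(round(EPOCH_S * rec.fs))
    n_full = len(rec.samples) // spe
    if len(labels) > n_full:
        raise ValueError(
            f"{len(labels)} labels but only {n_full} full 30 s epochs available")
    return [Epoch(samples=rec.samples[i * spe:(i + 1) * spe], fs=rec.fs,
                  index=i, label=lab)
            for i, lab in enumerate(labels)]


# --- minimal EDF export -----------------------------------------------------
# EDF writing has no counterpart in the installed readers, so the simulator
# ships a minimal single-channel EDF writer (16-bit, 1 s data records).

def write_edf(rec: PPGRecording, path: str | Path, channel: str = "PPG") -> None:
    """Write a single-channel EDF file readable by standard EDF readers."""
    fs_int = int(round(rec.fs))
    if not math.isclose(fs_int, rec.fs, rel_tol=1e-9):
        raise ValueError("EDF export requires an integer sampling rate")
    x = np.asarray(rec.samples, dtype=float)
    n_rec = int(math.ceil(len(x) / fs_int))
    pad = n_rec * fs_int - len(x)
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1] if len(x) else 0.0)])
    pmin, pmax = float(np.min(x)), float(np.max(x))
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def f(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    hdr = b"".join([
        f("0", 8), f(rec.subject_id or "X", 80), f("X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(str(256 + 256), 8),
        f("", 44), f(str(n_rec), 8), f("1", 8), f("1", 4),
    ])
    sig = b"".join([
        f(channel, 16), f("synthetic PPG", 80), f("au", 8),
        f(f"{pmin:.6g}", 8), f(f"{pmax:.6g}", 8),
        f(str(dmin), 8), f(str(dmax), 8), f("", 80), f(str(fs_int), 8),
        f("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        fh.write(struct.pack(f"<{len(digital)}h", *digital.tolist()))
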