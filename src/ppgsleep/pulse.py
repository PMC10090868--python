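"""Pulse detection, fiducial points and beat-indexed series.

From a preprocessed epoch this module finds systolic peaks, delineates each
beat (onset, systolic peak, systolic/diastolic inflection, end), integrates
the systolic and diastolic areas (A1, A2) and their ratios (IPAR = A2/A1,
IPTR = T2/T1), and builds the beat-indexed series used by the
cardio-respiratory features: the peak-to-peak interval series (PPI, ms),
the respiratory-induced amplitude modulation series (RIAM, peak-minus-onset
amplitude) and the instantaneous beat frequency series (RIFM = 1000/PPI Hz).

Peak detection runs on a 0.5-8 Hz band-passed copy with an adaptive
prominence threshold (half the 75th percentile of candidate prominences)
and a 300 ms refractory period; each detection is then snapped to the
maximum of the original epoch within +/-100 ms.  Physiologically
implausible intervals (outside 300-2000 ms, or jumping more than 30% from
the 5-beat running median) are masked out of the PPI-derived features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

PPI_MIN_MS = 300.0
PPI_MAX_MS = 2000.0
PPI_JUMP_FRAC = 0.30
MIN_BEATS = 4


@dataclass(frozen=True)
class BeatFiducials:
    """Fiducial sample indices and morphology of one complete beat."""

    onset_idx: int
    peak_idx: int
    inflection_idx: int
    end_idx: int
    A1: float  # systolic area (onset -> inflection), units * s
    A2: float  # diastolic area (inflection -> end), units * s
    T1: float  # systolic time, s
    T2: float  # diastolic time, s

    @property
    def A(self) -> float:
        return self.A1 + self.A2

    @property
    def IPAR(self) -> float:
        return self.A2 / self.A1 if self.A1 > 0 else np.nan

    @property
    def IPTR(self) -> float:
        return self.T2 / self.T1 if self.T1 > 0 else np.nan


@dataclass
class PulseSeries:
    """Beat-indexed series of one epoch.

    ``ppi``/``rifm``/``valid_mask`` have one entry per successive peak
    pair; ``riam`` has one entry per detected peak.
    """

    beat_times: np.ndarray  # s, systolic peak times
    ppi: np.ndarray         # ms
    riam: np.ndarray        # amplitude units, per peak
    rifm: np.ndarray        # Hz
    valid_mask: np.ndarray  # bool, per interval

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def valid_ppi(self) -> np.ndarray:
        return self.ppi[self.valid_mask]


def detect_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Detect systolic peak sample indices in a (preprocessed) epoch."""
    x = np.asarray(x, dtype=float)
    if len(x) < int(fs):
        return np.array([], dtype=int)
    high = min(8.0, 0.45 * fs)
    sos = signal.butter(2, [0.5, high], "bandpass", fs=fs, output="sos")
    det = signal.sosfiltfilt(sos, x)
    min_dist = max(1, int(round(0.3 * fs)))
    cand, props = signal.find_peaks(det, distance=min_dist, prominence=1e-12)
    if len(cand) == 0:
        return np.array([], dtype=int)
    thr = 0.5 * np.percentile(props["prominences"], 75)
    cand = cand[props["prominences"] >= thr]

    # snap to the maximum of the raw epoch within +/-100 ms
    r = max(1, int(round(0.1 * fs)))
    snapped = []
    for p in cand:
        lo, hi = max(0, p - r), min(len(x), p + r + 1)
        snapped.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(snapped)

    # keep strict local maxima of the epoch only
    keep = []
    for p in peaks:
        if 0 < p < len(x) - 1 and x[p] >= x[p - 1] and x[p] >= x[p + 1]:
            keep.append(p)
    peaks = np.array(keep, dtype=int)

    # enforce the refractory spacing, dropping the smaller of close pairs
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < min_dist:
            if x[p] > x[out[-1]]:
                out[-1] = int(p)
        else:
            out.append(int(p))
    return np.array(out, dtype=int)


def _find_inflection(x: np.ndarray, peak: int, end: int) -> int | None:
    """Systolic/diastolic boundary (dicrotic-notch surrogate).

    Preferred: the deepest interior local minimum of the signal between the
    systolic peak and beat end that is followed by a rise (a visible
    dicrotic notch before the diastolic lobe).  When the notch is only a
    shoulder, the largest interior maximum of the second derivative whose
    curvature turns negative again before the beat end is used.  Returns
    None when neither exists (single-lobe beat)."""
    if end - peak < 4:
        return None
    seg = np.arange(peak + 1, end - 1)
    if len(seg) < 3:
        return None
    interior = seg[1:-1]
    is_min = (x[interior] <= x[interior - 1]) & (x[interior] <= x[interior + 1])
    # a genuine notch must be followed by a diastolic rise of at least 5%
    # of the beat amplitude, not a numerical ripple in a flat tail
    amp = x[peak] - np.min(x[peak:end + 1])
    notches = [c for c in interior[is_min]
               if np.max(x[c + 1:end]) - x[c] >= 0.05 * amp]
    if notches:
        return int(min(notches, key=lambda c: x[c]))
    d2 = np.gradient(np.gradient(x))
    vals = d2[seg]
    locmax = seg[1:-1][(vals[1:-1] >= vals[:-2]) & (vals[1:-1] >= vals[2:])]
    for c in locmax[np.argsort(d2[locmax])[::-1]] if len(locmax) else []:
        if np.any(d2[c + 1:end - 1] < 0):
            return int(c)
    return None


def locate_fiducials(x: np.ndarray, peaks: np.ndarray,
                     fs: float) -> list[BeatFiducials]:
    """Delineate complete beats between successive onsets.

    The onset of a beat is the signal minimum between the previous and the
    current systolic peak; a beat is complete when its onset and the next
    onset both lie in the epoch.  Areas are trapezoidal integrals of the
    beat segment above its own minimum, so A1, A2 >= 0 and A = A1 + A2.
    When no inflection qualifies, the beat is split at one third of its
    duration past onset (clipped past the peak).
    """
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < 2:
        return []
    onsets = np.array([p0 + int(np.argmin(x[p0:p1 + 1]))
                       for p0, p1 in zip(peaks[:-1], peaks[1:])], dtype=int)
    beats: list[BeatFiducials] = []
    # beat k: onset[k-1] -> onset[k], peak = peaks[k] (k = 1..len(peaks)-2)
    for k in range(1, len(peaks) - 1):
        onset, end, peak = int(onsets[k - 1]), int(onsets[k]), int(peaks[k])
        if not onset < peak < end:
            continue
        infl = _find_inflection(x, peak, end)
        if infl is None:
            infl = onset + max(1, (end - onset) // 3)
            infl = min(max(infl, peak + 1), end - 1)
        if not peak < infl < end:
            continue
        y = x[onset:end + 1] - np.min(x[onset:end + 1])
        i = infl - onset
        a1 = float(np.trapezoid(y[:i + 1])) / fs
        a2 = float(np.trapezoid(y[i:])) / fs
        beats.append(BeatFiducials(
            onset_idx=onset, peak_idx=peak, inflection_idx=infl, end_idx=end,
            A1=a1, A2=a2, T1=(infl - onset) / fs, T2=(end - infl) / fs))
    return beats


class InvalidEpochError(ValueError):
    """Raised when an epoch has too few detectable beats to analyse."""


def build_pulse_series(peaks: np.ndarray, x: np.ndarray,
                       fs: float) -> PulseSeries:
    """Build the PPI / RIAM / RIFM series from detected peaks.

    Raises :class:`InvalidEpochError` with fewer than 4 peaks.  The RIAM of
    peak k is the epoch value at the peak minus the value at the beat onset
    (the preceding minimum); for the first peak the onset of the following
    beat pattern is unavailable, so the preceding local minimum within the
    epoch start is used.
    """
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < MIN_BEATS:
        raise InvalidEpochError(
            f"only {len(peaks)} peaks detected; need >= {MIN_BEATS}")
    beat_times = peaks / fs
    ppi = np.diff(peaks) / fs * 1000.0
    rifm = 1000.0 / ppi

    riam = np.empty(len(peaks))
    prev = 0
    for i, p in enumerate(peaks):
        onset = prev + int(np.argmin(x[prev:p + 1])) if p > prev else p
        riam[i] = x[p] - x[onset]
        prev = p

    valid = (ppi >= PPI_MIN_MS) & (ppi <= PPI_MAX_MS)
    if len(ppi) >= 2:
        med = _running_median(ppi, 5)
        valid &= np.abs(ppi - med) <= PPI_JUMP_FRAC * med
    return PulseSeries(beat_times=beat_times, ppi=ppi, riam=riam,
                       rifm=rifm, valid_mask=valid)


def _running_median(x: np.ndarray, w: int) -> np.ndarray:
    half = w // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out
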