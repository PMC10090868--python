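"""Per-epoch PPG conditioning: baseline removal, smoothing, z-scoring.

The chain is fixed: baseline-wander removal, then Savitzky-Golay smoothing
(order 3, frame 9 samples), then z-score normalisation to zero mean and
unit variance.  After the full chain the output is invariant to scale and
offset of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal


@dataclass(frozen=True)
class PreprocessConfig:
    sg_order: int = 3
    sg_frame: int = 9
    baseline_method: str = "moving_median"  # or "highpass"
    baseline_windows_s: Sequence[float] = (0.6, 1.2)
    highpass_cutoff: float = 0.1  # Hz, for baseline_method="highpass"
    zscore: bool = True

    def validate(self) -> None:
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_order:
            raise ValueError("sg_frame must be odd and > sg_order")
        if any(w <= 0 for w in self.baseline_windows_s):
            raise ValueError("baseline windows must be > 0")
        if self.baseline_method not in ("moving_median", "highpass"):
            raise ValueError(f"unknown baseline_method {self.baseline_method!r}")


def remove_baseline(x: np.ndarray, fs: float,
                    config: PreprocessConfig | None = None) -> np.ndarray:
    """Subtract the slow baseline-wander component from an epoch.

    Default estimator is a two-stage moving median (0.6 s then 1.2 s
    windows), which tracks drift far below the pulse band while leaving the
    respiratory-band amplitude modulation of the pulses intact; a zero-phase
    4th-order Butterworth high-pass is selectable instead.
    """
    config = config or PreprocessConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    if config.baseline_method == "highpass":
        sos = signal.butter(4, config.highpass_cutoff, "highpass",
                            fs=fs, output="sos")
        return signal.sosfiltfilt(sos, x)
    baseline = x
    for w_s in config.baseline_windows_s:
        w = int(round(w_s * fs))
        w += (w + 1) % 2  # odd window
        if w > len(x):
            raise ValueError(
                f"baseline window {w} samples exceeds epoch length {len(x)}")
        baseline = ndimage.median_filter(baseline, size=w, mode="nearest")
    return x - baseline


def savgol_smooth(x: np.ndarray, order: int = 3, frame: int = 9) -> np.ndarray:
    """Savitzky-Golay FIR smoothing (local least-squares polynomial fit).

    Edges are handled by fitting the polynomial on the truncated terminal
    window, so a degree-<=order polynomial passes through unchanged
    everywhere.
    """
    if frame % 2 == 0 or frame <= order:
        raise ValueError("frame must be odd and > order")
    x = np.asarray(x, dtype=float)
    if len(x) < frame:
        raise ValueError(f"epoch length {len(x)} < frame {frame}")
    return signal.savgol_filter(x, frame, order, mode="interp")


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sample-variance normalisation (n-1 denominator).

    A constant epoch maps to all zeros.  Idempotent.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to z-score")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def preprocess_epoch(x: np.ndarray, fs: float,
                     config: PreprocessConfig | None = None) -> np.ndarray:
    """Full conditioning chain: baseline -> Savitzky-Golay -> z-score."""
    config = config or PreprocessConfig()
    y = remove_baseline(x, fs, config)
    y = savgol_smooth(y, config.sg_order, config.sg_frame)
    if config.zscore:
        y = zscore_normalize(y)
    return y
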