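"""The 79-feature bank computed per 30 s epoch.

Four families:

* 14 morphological arterial-pressure surrogates — mean and sample s.d. of
  the per-beat systolic/diastolic areas and times and their ratios
  (A1, A2, A, T1, T2, IPAR, IPTR);
* 18 cardio-respiratory features — mean / s.d. / s.d. of successive
  differences / RMS of successive differences of the PPI, RIAM and RIFM
  series, pPP50, the standard error of the mean PPI, and the VLF / LF / HF
  band powers of pulse-rate variability plus the LF/HF ratio;
* 25 statistical nonlinear-dynamical features of the PPG waveform —
  15 distribution statistics, 4 Poincare descriptors (SD1, SD2, SD1/SD2,
  CCM), 3 Hjorth parameters, Higuchi and Katz fractal dimensions and a
  largest-Lyapunov-exponent estimate;
* 22 of the same statistics on the PPI series (without the fractal and
  Lyapunov measures).

All standard deviations use the sample (n-1) denominator, kurtosis is
non-excess (a normal series gives 3), and the geometric/harmonic means are
computed on |x| + 1e-12 because z-scored signals contain non-positive
values.  Spectral band powers come from a Lomb-Scargle periodogram of the
unevenly sampled PPI series; within a single 30 s epoch the VLF band
(0.003-0.04 Hz) is below the resolvable frequency range and its power is
reported for completeness but carries little information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, spatial, stats

from .pulse import BeatFiducials, PulseSeries

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

_GM_EPS = 1e-12

_BASIC_STAT_NAMES = ("avgAD", "stdAD", "MAD", "IQR", "nCM", "avgE", "SF",
                     "avgCL", "avgTE", "GM", "HaM", "TM25", "TM50",
                     "Skew", "Kurt")
_POINCARE_NAMES = ("SD1", "SD2", "RSD1SD2", "CCM")
_HJORTH_NAMES = ("HA", "HM", "HC")


@dataclass(frozen=True)
class CatalogEntry:
    index: int  # 1-based position in the canonical feature vector
    name: str
    family: str  # BP | CR | SND-PPG | SND-PPI
    units: str


def _build_catalog() -> tuple[CatalogEntry, ...]:
    entries: list[CatalogEntry] = []

    def add(name: str, family: str, units: str) -> None:
        entries.append(CatalogEntry(len(entries) + 1, name, family, units))

    morph = (("A1", "au*s"), ("A2", "au*s"), ("A", "au*s"),
             ("T1", "s"), ("T2", "s"), ("IPAR", "1"), ("IPTR", "1"))
    for sym, u in morph:
        add(f"mean{sym}", "BP", u)
    for sym, u in morph:
        add(f"sd{sym}", "BP", u)

    for prefix, units_of in (("avg", {"PPI": "ms", "RIAM": "au", "RIFM": "Hz"}),
                             ("sd", {"PPI": "ms", "RIAM": "au", "RIFM": "Hz"}),
                             ("sdsd", {"PPI": "ms", "RIAM": "au", "RIFM": "Hz"}),
                             ("rmssd", {"PPI": "ms", "RIAM": "au", "RIFM": "Hz"})):
        for series in ("PPI", "RIAM", "RIFM"):
            add(f"{prefix}{series}", "CR", units_of[series])
    add("pPP50", "CR", "%")
    add("SEM", "CR", "ms")
    for name in ("VLF", "LF", "HF"):
        add(name, "CR", "ms^2")
    add("LFHF", "CR", "1")

    for name in _BASIC_STAT_NAMES + _POINCARE_NAMES + _HJORTH_NAMES:
        add(f"{name}_PPG", "SND-PPG", "1")
    for name in ("HFD", "LC", "KFD"):
        add(f"{name}_PPG", "SND-PPG", "1")
    for name in _BASIC_STAT_NAMES + _POINCARE_NAMES + _HJORTH_NAMES:
        add(f"{name}_PPI", "SND-PPI", "ms")
    return tuple(entries)


#: Canonical ordered catalog of the 79 features.
FEATURE_CATALOG: tuple[CatalogEntry, ...] = _build_catalog()
FEATURE_NAMES: tuple[str, ...] = tuple(e.name for e in FEATURE_CATALOG)
FAMILY_OF: dict[str, str] = {e.name: e.family for e in FEATURE_CATALOG}


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) >= 2 else np.nan


# --- morphological (arterial-pressure surrogate) features -------------------

def morph_features(beats: Sequence[BeatFiducials]) -> dict[str, float]:
    """Mean and sample s.d. of A1, A2, A, T1, T2, IPAR, IPTR over beats."""
    if len(beats) < 2:
        return {n: np.nan for n in FEATURE_NAMES if FAMILY_OF[n] == "BP"}
    cols = {
        "A1": np.array([b.A1 for b in beats]),
        "A2": np.array([b.A2 for b in beats]),
        "A": np.array([b.A for b in beats]),
        "T1": np.array([b.T1 for b in beats]),
        "T2": np.array([b.T2 for b in beats]),
        "IPAR": np.array([b.IPAR for b in beats]),
        "IPTR": np.array([b.IPTR for b in beats]),
    }
    out: dict[str, float] = {}
    for sym, v in cols.items():
        out[f"mean{sym}"] = float(np.mean(v))
    for sym, v in cols.items():
        out[f"sd{sym}"] = _sd(v)
    return out


# --- cardio-respiratory features --------------------------------------------

def cardioresp_features(ps: PulseSeries) -> dict[str, float]:
    """Time-domain PPI/RIAM/RIFM statistics, pPP50 and the s.e.m. of PPI.

    pPP50 is the percentage of successive-PPI differences exceeding 50 ms.
    Masked (implausible) intervals are excluded from the PPI and RIFM
    statistics.
    """
    ppi = ps.valid_ppi()
    rifm = ps.rifm[ps.valid_mask]
    riam = ps.riam
    if len(ppi) < MIN_VALID_INTERVALS:
        names = [n for n in FEATURE_NAMES
                 if FAMILY_OF[n] == "CR" and n not in ("VLF", "LF", "HF", "LFHF")]
        return {n: np.nan for n in names}
    out: dict[str, float] = {}
    for name, x in (("PPI", ppi), ("RIAM", riam), ("RIFM", rifm)):
        dx = np.diff(x)
        out[f"avg{name}"] = float(np.mean(x))
        out[f"sd{name}"] = _sd(x)
        out[f"sdsd{name}"] = _sd(dx)
        out[f"rmssd{name}"] = float(np.sqrt(np.mean(dx ** 2))) if len(dx) else np.nan
    dppi = np.diff(ppi)
    out["pPP50"] = 100.0 * float(np.mean(np.abs(dppi) > 50.0)) if len(dppi) else np.nan
    out["SEM"] = _sd(ppi) / np.sqrt(len(ppi))
    return out


MIN_VALID_INTERVALS = 3


def spectral_features(ps: PulseSeries) -> dict[str, float]:
    """Pulse-rate-variability band powers via Lomb-Scargle on (t, PPI).

    Powers are integrals of the periodogram over the VLF (0.003-0.04 Hz),
    LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands; LFHF = LF/HF (non-finite
    when HF is zero).
    """
    ppi = ps.valid_ppi()
    t = ps.beat_times[1:][ps.valid_mask]
    if len(ppi) < MIN_VALID_INTERVALS + 1:
        return {"VLF": np.nan, "LF": np.nan, "HF": np.nan, "LFHF": np.nan}
    y = ppi - np.mean(ppi)
    if np.allclose(y, 0):
        return {"VLF": 0.0, "LF": 0.0, "HF": 0.0, "LFHF": np.nan}
    out: dict[str, float] = {}
    for name, (f_lo, f_hi) in (("VLF", VLF_BAND), ("LF", LF_BAND), ("HF", HF_BAND)):
        freqs = np.linspace(f_lo, f_hi, 64)
        pgram = signal.lombscargle(t, y, 2.0 * np.pi * freqs, normalize=False)
        # one-sided PSD scaling: lombscargle returns A^2 * n / 4-ish units;
        # band power = integral of 2 * P / n over f
        psd = 2.0 * pgram / len(y)
        out[name] = float(np.trapezoid(psd, freqs))
    out["LFHF"] = out["LF"] / out["HF"] if out["HF"] > 0 else np.nan
    return out


# --- distribution statistics -------------------------------------------------

def basic_stats(x: np.ndarray, n_moment: int = 3) -> dict[str, float]:
    """The 15 distribution statistics of one series.

    avgAD/stdAD: mean and s.d. of |x - mean|; MAD: median |x - median|;
    IQR; nCM: the n-th central moment (default n=3); avgE: mean energy;
    SF: RMS / mean|x|; avgCL: mean absolute first difference; avgTE: mean
    Teager energy x_i^2 - x_{i-1} x_{i+1}; GM/HaM on |x| + eps; TM25/TM50:
    means after symmetrically discarding 25% / 50% of the mass; Skew/Kurt:
    standardised third and fourth moments (kurtosis non-excess).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        return {n: np.nan for n in _BASIC_STAT_NAMES}
    ad = np.abs(x - np.mean(x))
    absx = np.abs(x)
    mean_abs = float(np.mean(absx))
    rms = float(np.sqrt(np.mean(x ** 2)))
    te = x[1:-1] ** 2 - x[:-2] * x[2:]
    out = {
        "avgAD": float(np.mean(ad)),
        "stdAD": _sd(ad),
        "MAD": float(np.median(np.abs(x - np.median(x)))),
        "IQR": float(stats.iqr(x)),
        "nCM": float(np.mean((x - np.mean(x)) ** n_moment)),
        "avgE": float(np.mean(x ** 2)),
        "SF": rms / mean_abs if mean_abs > 0 else np.nan,
        "avgCL": float(np.mean(np.abs(np.diff(x)))),
        "avgTE": float(np.mean(te)),
        "GM": float(stats.gmean(absx + _GM_EPS)),
        "HaM": float(stats.hmean(absx + _GM_EPS)),
        "TM25": float(stats.trim_mean(x, 0.125)),
        "TM50": float(stats.trim_mean(x, 0.25)),
        "Skew": float(stats.skew(x, bias=True)),
        "Kurt": float(stats.kurtosis(x, fisher=False, bias=True)),
    }
    return out


def poincare(x: np.ndarray, m: int = 1) -> dict[str, float]:
    """Poincare descriptors SD1, SD2, their ratio, and CCM at lag ``m``.

    SD1/SD2 are the sample s.d. of the lag-m return map perpendicular to /
    along the line of identity.  CCM is the mean signed area of the
    triangles formed by consecutive point triplets of the return map,
    normalised by pi * SD1 * SD2 (0 by convention when SD1*SD2 = 0).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 3:
        return {n: np.nan for n in _POINCARE_NAMES}
    a = x[:-m]
    b = x[m:]
    sd1 = float(np.std((a - b) / np.sqrt(2.0), ddof=1))
    sd2 = float(np.std((a + b) / np.sqrt(2.0), ddof=1))
    if sd1 * sd2 == 0:
        ccm = 0.0
    else:
        # signed area of triangle (P_i, P_{i+1}, P_{i+2}) with P_i=(a_i, b_i)
        ax, ay = a[:-2], b[:-2]
        bx, by = a[1:-1], b[1:-1]
        cx, cy = a[2:], b[2:]
        areas = 0.5 * ((bx - ax) * (cy - ay) - (cx - ax) * (by - ay))
        ccm = float(np.mean(areas) / (np.pi * sd1 * sd2))
    return {"SD1": sd1, "SD2": sd2,
            "RSD1SD2": sd1 / sd2 if sd2 > 0 else np.nan, "CCM": ccm}


def hjorth(x: np.ndarray) -> dict[str, float]:
    """Hjorth activity (variance), mobility and complexity.

    Derivatives are first differences; mobility = sqrt(var(dx)/var(x)),
    complexity = mobility(dx)/mobility(x).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return {n: np.nan for n in _HJORTH_NAMES}
    dx = np.diff(x)
    ddx = np.diff(dx)
    v0, v1, v2 = np.var(x, ddof=1), np.var(dx, ddof=1), np.var(ddx, ddof=1)
    ha = float(v0)
    if v0 == 0 or v1 == 0:
        return {"HA": ha, "HM": np.nan, "HC": np.nan}
    hm = float(np.sqrt(v1 / v0))
    hc = float(np.sqrt(v2 / v1) / hm)
    return {"HA": ha, "HM": hm, "HC": hc}


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension via subsampled curve lengths.

    The mean normalised curve length L(k) over the k offset phases is
    regressed on log(1/k); the slope is the dimension estimate (1 for a
    smooth line, 2 for white noise).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 * kmax:
        raise ValueError(f"series length {n} < 4*kmax = {4 * kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(np.sum(np.abs(np.diff(x[idx]))) * norm / k)
        lk[k - 1] = np.mean(lengths)
    if np.any(lk <= 0):
        return 1.0
    ks = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of a sampled waveform.

    KFD = log10(n) / (log10(n) + log10(d/L)) with L the total path length
    (sum of absolute successive differences), d the maximum absolute
    excursion from the first sample and n the number of steps.  Amplitude
    distances only are used, which makes the measure scale-invariant;
    a monotone line has d = L and KFD = 1, and a constant (d = 0) series
    is 1.0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    L = float(np.sum(np.abs(np.diff(x))))
    d = float(np.max(np.abs(x - x[0])))
    if d == 0 or L == 0:
        return 1.0
    n = len(x) - 1
    denom = np.log10(n) + np.log10(d / L)
    if denom == 0:
        return 1.0
    return float(np.log10(n) / denom)


def lyapunov_coeff(x: np.ndarray, emb_dim: int = 5, delay: int = 4,
                   n_steps: int = 10, theiler: int | None = None) -> float:
    """Largest-Lyapunov-exponent estimate (Rosenstein's method).

    The series is delay-embedded, each point is paired with its nearest
    neighbour outside a Theiler exclusion window, and the slope of the mean
    log-divergence over the first ``n_steps`` steps is returned (per step).
    Near zero for periodic signals, positive for stochastic/chaotic ones.
    Deterministic given the input.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 200:
        raise ValueError(f"series length {len(x)} < 200")
    if np.std(x) == 0:
        return 0.0
    n_vec = len(x) - (emb_dim - 1) * delay
    emb = np.empty((n_vec, emb_dim))
    for j in range(emb_dim):
        emb[:, j] = x[j * delay:j * delay + n_vec]
    theiler = theiler if theiler is not None else (emb_dim - 1) * delay + 1
    tree = spatial.cKDTree(emb)
    k = min(2 * theiler + 5, n_vec)
    dist, idx = tree.query(emb, k=k)
    nn = np.full(n_vec, -1, dtype=int)
    for i in range(n_vec):
        for j in range(1, k):
            if abs(idx[i, j] - i) > theiler:
                nn[i] = idx[i, j]
                break
    usable = np.where((nn >= 0) & (np.arange(n_vec) < n_vec - n_steps)
                      & (nn < n_vec - n_steps))[0]
    if len(usable) < 10:
        return np.nan
    logd = np.zeros(n_steps + 1)
    counts = np.zeros(n_steps + 1)
    for i in usable:
        j = nn[i]
        d = np.linalg.norm(emb[i:i + n_steps + 1] - emb[j:j + n_steps + 1], axis=1)
        ok = d > 0
        logd[ok] += np.log(d[ok])
        counts[ok] += 1
    ok = counts > 0
    if ok.sum() < 2:
        return np.nan
    steps = np.arange(n_steps + 1)[ok]
    slope = np.polyfit(steps, logd[ok] / counts[ok], 1)[0]
    return float(slope)


# --- full vector -------------------------------------------------------------

def _snd_block(x: np.ndarray, suffix: str, fractal: bool) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, v in basic_stats(x).items():
        out[f"{name}_{suffix}"] = v
    for name, v in poincare(x).items():
        out[f"{name}_{suffix}"] = v
    for name, v in hjorth(x).items():
        out[f"{name}_{suffix}"] = v
    if fractal:
        try:
            out[f"HFD_{suffix}"] = higuchi_fd(x)
        except ValueError:
            out[f"HFD_{suffix}"] = np.nan
        try:
            out[f"LC_{suffix}"] = lyapunov_coeff(x)
        except ValueError:
            out[f"LC_{suffix}"] = np.nan
        try:
            out[f"KFD_{suffix}"] = katz_fd(x)
        except ValueError:
            out[f"KFD_{suffix}"] = np.nan
    return out


def extract_features(epoch: np.ndarray, beats: Sequence[BeatFiducials],
                     ps: PulseSeries) -> np.ndarray:
    """The canonical 79-value feature vector of one preprocessed epoch.

    Values follow :data:`FEATURE_CATALOG` order.  Inputs come from
    :func:`ppgsleep.pulse.locate_fiducials` and
    :func:`ppgsleep.pulse.build_pulse_series` on the same epoch.
    """
    values: dict[str, float] = {}
    values.update(morph_features(beats))
    values.update(cardioresp_features(ps))
    values.update(spectral_features(ps))
    values.update(_snd_block(np.asarray(epoch, dtype=float), "PPG", fractal=True))
    values.update(_snd_block(ps.valid_ppi(), "PPI", fractal=False))
    return np.array([values[name] for name in FEATURE_NAMES])
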