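"""Stage-structured synthetic overnight PPG generator.

Produces finger-PPG-like waveforms whose beat-level physiology is known
exactly, so the downstream pulse analysis, feature bank and classifiers can
be tested without any recorded data.  Each sleep stage is parameterised by
its mean pulse rate and beat-to-beat variability, a respiratory rate that
modulates both beat amplitude (RIAM) and instantaneous beat frequency
(RIFM), a target diastolic/systolic area ratio (the morphology surrogate
for arterial pressure), and additive noise.

Each beat is the sum of two log-normal-shaped lobes — a systolic lobe and a
delayed, smaller diastolic lobe — whose closed-form areas are set so the
diastolic/systolic area ratio equals ``ipar_target`` exactly.  Beats are
laid down continuously across the night with parameters switched at 30 s
epoch boundaries, so epoch edges carry no discontinuity artifacts.  Baseline
wander (a slow sinusoid plus a smoothed random walk) and white noise are
added on top.

The generator emulates stage-conditioned cardio-respiratory statistics and
gross pulse morphology only; it makes no claim of hemodynamic realism (no
apneas, arousals, motion artifacts or multi-night variability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .stages import DS, FOUR_CLASS, LS, REM, WAKE

EPOCH_S = 30.0

# Lobe timing/width constants (fractions of the beat interval / log-widths).
_SYS_MU = 0.20
_SYS_SIGMA = 0.30
_DIA_MU = 0.58
_DIA_SIGMA = 0.25


@dataclass(frozen=True)
class StageParams:
    """Generative physiology of one sleep stage.

    hr_mean/hr_sd are in beats/min (hr_sd is the beat-to-beat spread),
    resp_rate in Hz, riam_depth and rifm_depth are modulation depths as
    fractions of the pulse amplitude and of the mean beat frequency,
    ipar_target is the unitless diastolic/systolic area ratio and noise_sd
    the white-noise level as a fraction of the unit pulse amplitude.
    """

    stage: str
    hr_mean: float
    hr_sd: float
    resp_rate: float
    riam_depth: float
    rifm_depth: float
    ipar_target: float
    noise_sd: float

    def validate(self) -> None:
        if self.stage not in FOUR_CLASS:
            raise ValueError(f"stage: {self.stage!r} is not a four-class stage")
        if not 30.0 <= self.hr_mean <= 180.0:
            raise ValueError(f"hr_mean: {self.hr_mean} outside [30, 180] bpm")
        if self.hr_sd < 0:
            raise ValueError(f"hr_sd: {self.hr_sd} must be >= 0")
        if not 0.1 <= self.resp_rate <= 0.5:
            raise ValueError(f"resp_rate: {self.resp_rate} outside [0.1, 0.5] Hz")
        for name in ("riam_depth", "rifm_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: {v} outside [0, 1]")
        if self.ipar_target <= 0:
            raise ValueError(f"ipar_target: {self.ipar_target} must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: {self.noise_sd} must be >= 0")


def default_stage_params() -> dict[str, StageParams]:
    """Stage presets with separable physiology.

    Orderings follow sleep physiology: wake has the highest pulse rate,
    deep sleep the lowest beat-to-beat variability and the strongest,
    slowest respiratory modulation; REM has the most irregular breathing
    (highest frequency-modulation depth).
    """
    return {
        WAKE: StageParams(WAKE, hr_mean=72.0, hr_sd=4.0, resp_rate=0.28,
                          riam_depth=0.10, rifm_depth=0.03,
                          ipar_target=0.45, noise_sd=0.02),
        LS: StageParams(LS, hr_mean=62.0, hr_sd=2.5, resp_rate=0.25,
                        riam_depth=0.15, rifm_depth=0.05,
                        ipar_target=0.55, noise_sd=0.02),
        DS: StageParams(DS, hr_mean=55.0, hr_sd=1.0, resp_rate=0.22,
                        riam_depth=0.25, rifm_depth=0.04,
                        ipar_target=0.65, noise_sd=0.02),
        REM: StageParams(REM, hr_mean=66.0, hr_sd=3.5, resp_rate=0.30,
                         riam_depth=0.12, rifm_depth=0.08,
                         ipar_target=0.50, noise_sd=0.02),
    }


@dataclass(frozen=True)
class SyntheticNightConfig:
    """Configuration of one synthetic night.

    ``hypnogram`` holds one four-class stage label per 30 s epoch.  The
    same seed always reproduces the identical waveform.
    """

    hypnogram: Sequence[str]
    params: Mapping[str, StageParams] = field(default_factory=default_stage_params)
    fs: float = 128.0
    baseline_amp: float = 0.3
    baseline_freq: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if len(self.hypnogram) == 0:
            raise ValueError("hypnogram: must be non-empty")
        if self.fs <= 0:
            raise ValueError(f"fs: {self.fs} must be > 0")
        for lab in self.hypnogram:
            if lab not in self.params:
                raise ValueError(f"hypnogram: unknown stage label {lab!r}")
        for p in self.params.values():
            p.validate()


@dataclass(frozen=True)
class BeatSchedule:
    """Ground-truth per-beat bookkeeping of a generated waveform."""

    onset_times: np.ndarray   # s, beat window start
    ibis: np.ndarray          # s, interval to the next beat
    amplitudes: np.ndarray    # unitless systolic amplitude factor
    ipar: np.ndarray          # designed diastolic/systolic area ratio
    stage_idx: np.ndarray     # epoch index of each beat


def _lognorm_lobe(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(-0.5 * (np.log(t[pos] / mu) / sigma) ** 2)
    return out


def _lobe_area(mu: float, sigma: float) -> float:
    # closed form of the time integral of exp(-(ln(t/mu))^2 / (2 sigma^2))
    return mu * sigma * math.sqrt(2.0 * math.pi) * math.exp(sigma * sigma / 2.0)


def _schedule_beats(stage_of_epoch: Sequence[StageParams], duration: float,
                    rng: np.random.Generator) -> BeatSchedule:
    """Draw the beat sequence continuously across the whole night.

    The respiratory phase is accumulated beat to beat so it stays
    continuous across stage switches.
    """
    onsets, ibis, amps, ipars, stages = [], [], [], [], []
    t = 0.0
    resp_phase = 0.0
    n_epochs = len(stage_of_epoch)
    while t < duration:
        ep = min(int(t / EPOCH_S), n_epochs - 1)
        p = stage_of_epoch[ep]
        f0 = p.hr_mean / 60.0  # Hz
        inst_f = f0 * (1.0 + p.rifm_depth * math.sin(resp_phase))
        sd_ibi = p.hr_sd * 60.0 / (p.hr_mean ** 2)  # linearised bpm -> s
        ibi = 1.0 / inst_f + (rng.normal(0.0, sd_ibi) if sd_ibi > 0 else 0.0)
        ibi = max(ibi, 0.3)
        amp = 1.0 + p.riam_depth * math.sin(resp_phase)
        onsets.append(t)
        ibis.append(ibi)
        amps.append(amp)
        ipars.append(p.ipar_target)
        stages.append(ep)
        resp_phase += 2.0 * math.pi * p.resp_rate * ibi
        t += ibi
    return BeatSchedule(np.asarray(onsets), np.asarray(ibis),
                        np.asarray(amps), np.asarray(ipars),
                        np.asarray(stages, dtype=int))


def _render(schedule: BeatSchedule, n_samples: int, fs: float) -> np.ndarray:
    """Overlap-add the two-lobe pulse of every beat onto the sample grid."""
    x = np.zeros(n_samples)
    for t0, d, amp, ipar in zip(schedule.onset_times, schedule.ibis,
                                schedule.amplitudes, schedule.ipar):
        i0 = int(math.ceil(t0 * fs))
        i1 = min(n_samples, int(math.ceil((t0 + 1.6 * d) * fs)))
        if i0 >= i1:
            continue
        t_rel = np.arange(i0, i1) / fs - t0
        sys_lobe = _lognorm_lobe(t_rel, _SYS_MU * d, _SYS_SIGMA)
        dia_lobe = _lognorm_lobe(t_rel, _DIA_MU * d, _DIA_SIGMA)
        r = ipar * _lobe_area(_SYS_MU * d, _SYS_SIGMA) / _lobe_area(_DIA_MU * d, _DIA_SIGMA)
        x[i0:i1] += amp * (sys_lobe + r * dia_lobe)
    return x


def generate_pulse_train(params: StageParams, duration: float, fs: float,
                         seed: int, return_beats: bool = False):
    """Generate a single-stage pulse train of ``duration`` seconds.

    With hr_sd=0 and zero modulation depths the beats are exactly
    equidistant at 60/hr_mean seconds.  Returns the waveform, or
    ``(waveform, BeatSchedule)`` when ``return_beats`` is set.
    """
    params.validate()
    if duration < 30.0:
        raise ValueError(f"duration: {duration} must be >= 30 s")
    if fs < 32.0:
        raise ValueError(f"fs: {fs} must be >= 32 samples/s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_ep = max(1, int(math.ceil(duration / EPOCH_S)))
    schedule = _schedule_beats([params] * n_ep, duration, rng)
    x = _render(schedule, n, fs)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
    if return_beats:
        return x, schedule
    return x


def generate_night(config: SyntheticNightConfig, return_beats: bool = False):
    """Generate a full synthetic night from a hypnogram.

    Returns ``(recording, hypnogram)`` where the recording spans exactly
    30 s per hypnogram epoch; the label sequence is passed through
    unchanged.  With ``return_beats`` a BeatSchedule is appended.
    """
    from .io import PPGRecording  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = list(config.hypnogram)
    duration = EPOCH_S * len(labels)
    n = int(round(duration * config.fs))
    stage_of_epoch = [config.params[lab] for lab in labels]
    schedule = _schedule_beats(stage_of_epoch, duration, rng)
    x = _render(schedule, n, config.fs)

    t = np.arange(n) / config.fs
    phase = rng.uniform(0.0, 2.0 * math.pi)
    baseline = config.baseline_amp * np.sin(2.0 * math.pi * config.baseline_freq * t + phase)
    if config.baseline_amp > 0:
        walk = np.cumsum(rng.normal(0.0, 1.0, n))
        walk -= np.linspace(walk[0], walk[-1], n)  # remove gross trend
        scale = np.std(walk)
        if scale > 0:
            baseline = baseline + 0.3 * config.baseline_amp * walk / scale
    x = x + baseline

    noise_sd = np.empty(n)
    samples_per_epoch = int(round(EPOCH_S * config.fs))
    for i, p in enumerate(stage_of_epoch):
        noise_sd[i * samples_per_epoch:(i + 1) * samples_per_epoch] = p.noise_sd
    if np.any(noise_sd > 0):
        x = x + rng.normal(0.0, 1.0, n) * noise_sd

    rec = PPGRecording(samples=x, fs=config.fs)
    if return_beats:
        return rec, labels, schedule
    return rec, labels


def random_hypnogram(n_epochs: int, seed: int, min_run: int = 4,
                     max_run: int = 12) -> list[str]:
    """Bout-structured random hypnogram with roughly balanced stages.

    Stages appear in shuffled cycles of all four labels with uniformly
    drawn run lengths, mimicking the bout structure of real hypnograms
    while guaranteeing every stage is represented.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n_epochs:
        order = list(FOUR_CLASS)
        rng.shuffle(order)
        for stage in order:
            run = int(rng.integers(min_run, max_run + 1))
            out.extend([stage] * run)
    return out[:n_epochs]


def simulate_corpus(n_subjects: int, epochs_per_subject: int, seed: int,
                    params: Mapping[str, StageParams] | None = None,
                    fs: float = 128.0):
    """Generate a multi-subject corpus of (recording, hypnogram) pairs.

    Returns a list of ``(subject_id, PPGRecording, labels)`` with
    independent per-subject seeds derived from ``seed``.
    """
    params = dict(params) if params is not None else default_stage_params()
    out = []
    for s in range(n_subjects):
        sub_seed = (seed * 1000 + s) % (2 ** 31)
        hyp = random_hypnogram(epochs_per_subject, seed=sub_seed + 7)
        cfg = SyntheticNightConfig(hypnogram=hyp, params=params, fs=fs,
                                   seed=sub_seed)
        rec, labels = generate_night(cfg)
        rec = replace(rec, subject_id=f"S{s:02d}")
        out.append((f"S{s:02d}", rec, labels))
    return out
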