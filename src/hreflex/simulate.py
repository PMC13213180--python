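"""Synthetic recruitment-curve EMG runs with known ground truth.

A recruitment-curve run ramps tibial-nerve stimulation intensity in predefined
steps (a few trials per step, ~1 Hz stimulation with jittered inter-stimulus
interval, capped at 50 mA) while recording soleus surface EMG. Each trial
contains, post-trigger: a short biphasic stimulus artifact with an exponential
decay tail, a direct M-wave (~6-20 ms), an H-reflex (~28-45 ms, main positive
and negative peaks ~5 ms apart), and band-limited background EMG noise.

The ground-truth recruitment functions are a logistic of intensity for the
M-wave and a "hill" curve (product of a rising and a falling sigmoid) for the
H-reflex. Templates are scaled so that, with zero noise, the mean rectified
value (MRV) inside the canonical response window equals the ground-truth
amplitude exactly at the generation rate — every downstream stage can then be
checked against known truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.special import expit

from .bands import H_WINDOW_MS, M_WINDOW_MS

__all__ = [
    "RecruitmentTruth",
    "SweepProtocol",
    "WaveformSpec",
    "GatingSpec",
    "Trial",
    "SweepRun",
    "true_m_amplitude",
    "true_h_amplitude",
    "generate_trial",
    "generate_run",
    "generate_cohort",
    "draw_truth",
    "simulate_gating",
]


@dataclass(frozen=True)
class RecruitmentTruth:
    """Ground-truth recruitment functions.

    H-reflex: ``h_scale * sigma(h_rise_slope*(s-h_rise_center))
    * sigma(-h_fall_slope*(s-h_fall_center))`` — bell-shaped in intensity s.
    M-wave: ``m_max / (1 + exp(-m_slope*(s-m_center)))`` — saturating sigmoid.

    Amplitudes in µV (MRV scale), centers in mA, slopes in 1/mA.
    """

    h_scale: float = 150.0
    h_rise_center: float = 12.0
    h_rise_slope: float = 0.8
    h_fall_center: float = 24.0
    h_fall_slope: float = 0.5
    m_max: float = 300.0
    m_center: float = 22.0
    m_slope: float = 0.6

    def __post_init__(self) -> None:
        if self.h_scale <= 0 or self.m_max <= 0:
            raise ValueError("amplitudes must be positive")
        if min(self.h_rise_slope, self.h_fall_slope, self.m_slope) <= 0:
            raise ValueError("slopes must be positive")
        if not self.h_rise_center < self.h_fall_center:
            raise ValueError(
                "h_rise_center must lie below h_fall_center "
                "(bell-shaped H-reflex recruitment)"
            )


@dataclass(frozen=True)
class SweepProtocol:
    """Intensity ramp: `trials_per_step` trials at each step up to the cap."""

    start_intensity: float = 6.0
    step: float = 1.0
    trials_per_step: int = 4
    max_intensity: float = 50.0
    isi_mean: float = 1.0
    isi_jitter_frac: float = 0.10
    fs: int = 3200

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_intensity > 50.0:
            raise ValueError("max_intensity exceeds the 50 mA safety cap")
        if self.trials_per_step < 1:
            raise ValueError("trials_per_step must be >= 1")


@dataclass(frozen=True)
class WaveformSpec:
    """Per-trial waveform building blocks (times in ms, amplitudes in µV)."""

    artifact_amp: float = 500.0
    artifact_width: float = 1.0
    decay_amp: float = 120.0
    decay_tau: float = 1.2
    m_latency: float = 7.0
    m_peak_separation: float = 4.0
    h_latency: float = 30.0
    h_peak_separation: float = 5.0
    noise_rms: float = 5.0
    trial_cv: float = 0.15

    @property
    def m_duration(self) -> float:
        return 2.0 * self.m_peak_separation

    def __post_init__(self) -> None:
        if self.m_latency + self.m_duration >= self.h_latency:
            raise ValueError("M-wave must end before the H-reflex begins")
        if self.h_peak_separation <= 0 or self.m_peak_separation <= 0:
            raise ValueError("peak separations must be positive")


@dataclass(frozen=True)
class GatingSpec:
    """Background-EMG gate: trigger only after a quiet-standing hold.

    5–18 µV is the soleus background band observed during normal standing;
    triggering requires the rectified background to stay at or below the upper
    limit for `hold_duration` seconds.
    """

    background_limit_low: float = 5.0
    background_limit_high: float = 18.0
    hold_duration: float = 2.0

    def __post_init__(self) -> None:
        if not self.background_limit_low < self.background_limit_high:
            raise ValueError("background limits must satisfy low < high")
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be positive")


@dataclass(frozen=True)
class Trial:
    intensity: float
    samples: np.ndarray
    trigger_index: int
    isi: float = 1.0
    trigger_residual_s: float = 0.0  # sub-sample offset lost to decimation

    def __post_init__(self) -> None:
        if not 0 <= self.trigger_index < len(self.samples):
            raise ValueError("trigger_index outside the sample series")


@dataclass(frozen=True)
class SweepRun:
    fs: int
    trials: tuple[Trial, ...]
    subject_id: str = "S00"
    truth: RecruitmentTruth | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def true_m_amplitude(s, truth: RecruitmentTruth):
    """Ground-truth M-wave MRV (µV) at intensity `s` (mA): saturating logistic."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("stimulation intensity must be non-negative")
    out = truth.m_max * expit(truth.m_slope * (s - truth.m_center))
    return float(out) if out.ndim == 0 else out


def true_h_amplitude(s, truth: RecruitmentTruth):
    """Ground-truth H-reflex MRV (µV) at `s` (mA): product of two sigmoids."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("stimulation intensity must be non-negative")
    rise = expit(truth.h_rise_slope * (s - truth.h_rise_center))
    fall = expit(-truth.h_fall_slope * (s - truth.h_fall_center))
    out = truth.h_scale * rise * fall
    return float(out) if out.ndim == 0 else out


def _band_limited_noise(n: int, fs: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the surface-EMG band."""
    white = rng.standard_normal(n)
    lo, hi = 10.0, min(500.0, 0.45 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _m_template(t_ms: np.ndarray, wspec: WaveformSpec) -> np.ndarray:
    """Gaussian-tapered one-cycle sinusoid: a sharp biphasic compound action
    potential with main peaks `m_peak_separation` apart."""
    t0, dur = wspec.m_latency, wspec.m_duration
    center = t0 + dur / 2.0
    phase = 2.0 * np.pi * (t_ms - t0) / dur
    window = np.exp(-0.5 * ((t_ms - center) / (dur / 3.0)) ** 2)
    tpl = np.sin(phase) * window
    tpl[(t_ms < t0) | (t_ms >= t0 + dur)] = 0.0
    return tpl


def _h_template(t_ms: np.ndarray, wspec: WaveformSpec) -> np.ndarray:
    """One-cycle sinusoid whose half-period equals the H peak separation.

    A 5 ms positive-to-negative peak separation gives a 10 ms period, i.e. the
    ~100 Hz fundamental characteristic of the soleus H-reflex.
    """
    t0 = wspec.h_latency
    period = 2.0 * wspec.h_peak_separation
    phase = 2.0 * np.pi * (t_ms - t0) / period
    tpl = np.sin(phase)
    tpl[(t_ms < t0) | (t_ms >= t0 + period)] = 0.0
    return tpl


def _lognormal_factor(cv: float, rng: np.random.Generator) -> float:
    """Unit-mean multiplicative variability with coefficient of variation cv."""
    z = rng.standard_normal()  # drawn even for cv=0 to keep streams aligned
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(np.exp(np.sqrt(sigma2) * z - sigma2 / 2.0))


def _assemble_trial(
    s: float,
    truth: RecruitmentTruth,
    wspec: WaveformSpec,
    fs: int,
    jitter_ms: float,
    eps_m: float,
    eps_h: float,
    unit_noise: np.ndarray,
    pre_ms: float,
    m_window: tuple[float, float],
    h_window: tuple[float, float],
) -> Trial:
    """Deterministic trial assembly from pre-drawn randomness."""
    n = len(unit_noise)
    trig = int(round((pre_ms + jitter_ms) * fs / 1000.0))
    t_ms = (np.arange(n) - trig) * 1000.0 / fs

    x = np.zeros(n)
    # biphasic stimulus pulse artifact
    half = wspec.artifact_width / 2.0
    x[(t_ms >= 0) & (t_ms < half)] += wspec.artifact_amp
    x[(t_ms >= half) & (t_ms < wspec.artifact_width)] -= wspec.artifact_amp
    # electrode-interface decay tail
    post = t_ms >= 0
    x[post] += wspec.decay_amp * np.exp(-t_ms[post] / wspec.decay_tau)

    tpl_m = _m_template(t_ms, wspec)
    mask_m = (t_ms >= m_window[0]) & (t_ms < m_window[1])
    norm_m = np.abs(tpl_m[mask_m]).mean()
    x += tpl_m / norm_m * true_m_amplitude(s, truth) * eps_m

    tpl_h = _h_template(t_ms, wspec)
    mask_h = (t_ms >= h_window[0]) & (t_ms < h_window[1])
    norm_h = np.abs(tpl_h[mask_h]).mean()
    x += tpl_h / norm_h * true_h_amplitude(s, truth) * eps_h

    x += wspec.noise_rms * unit_noise
    return Trial(intensity=float(s), samples=x, trigger_index=trig)


def _check_trial_args(s: float, fs: int) -> int:
    if float(fs) != int(fs):
        raise ValueError("sampling rate fs must be an integer number of Hz")
    fs = int(fs)
    if fs < 320:
        raise ValueError("fs below 320 Hz is not supported")
    if s < 0:
        raise ValueError("stimulation intensity must be non-negative")
    return fs


def generate_trial(
    s: float,
    truth: RecruitmentTruth,
    wspec: WaveformSpec,
    fs: int,
    rng: np.random.Generator,
    *,
    pre_ms: float = 250.0,
    post_ms: float = 450.0,
    trigger_jitter_ms: float = 12.5,
    m_window: tuple[float, float] = M_WINDOW_MS,
    h_window: tuple[float, float] = H_WINDOW_MS,
) -> Trial:
    """Synthesize one stimulation trial at intensity `s`.

    The trigger position is jittered by up to `trigger_jitter_ms` within the
    record so that integer decimation later produces the realistic trial-to-
    trial trigger-quantization jitter of a lower-rate acquisition system.
    """
    fs = _check_trial_args(s, fs)
    jitter = rng.uniform(0.0, trigger_jitter_ms)
    n = int(round((pre_ms + post_ms + trigger_jitter_ms) * fs / 1000.0))
    eps_m = _lognormal_factor(wspec.trial_cv, rng)
    eps_h = _lognormal_factor(wspec.trial_cv, rng)
    noise = _band_limited_noise(n, fs, rng)
    return _assemble_trial(
        s, truth, wspec, fs, jitter, eps_m, eps_h, noise, pre_ms, m_window, h_window
    )


def _ramp_intensities(
    protocol: SweepProtocol, truth: RecruitmentTruth
) -> np.ndarray:
    """Intensity per step; stops early once the M-wave has plateaued.

    The ramp ends after the true M amplitude exceeds 99 % of its asymptote for
    two consecutive steps, or at the safety cap, whichever comes first.
    """
    steps = []
    s = protocol.start_intensity
    consecutive = 0
    while s <= protocol.max_intensity + 1e-9:
        steps.append(s)
        if true_m_amplitude(s, truth) >= 0.99 * truth.m_max:
            consecutive += 1
            if consecutive >= 2:
                break
        else:
            consecutive = 0
        s += protocol.step
    if not steps:
        raise ValueError("empty ramp: start_intensity exceeds max_intensity")
    return np.array(steps)


def _subject_seed_sequence(seed: int, subject_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), zlib.crc32(subject_id.encode())])


def generate_run(
    truth: RecruitmentTruth,
    protocol: SweepProtocol,
    wspec: WaveformSpec,
    subject_id: str = "S00",
    seed: int = 0,
) -> SweepRun:
    """Generate a full recruitment-curve run (deterministic for a given seed)."""
    rng = np.random.default_rng(_subject_seed_sequence(seed, subject_id))
    fs = _check_trial_args(0.0, protocol.fs)
    pre_ms, post_ms, jit_ms = 250.0, 450.0, 12.5
    n = int(round((pre_ms + post_ms + jit_ms) * fs / 1000.0))

    # draw all per-trial randomness in presentation order, then band-limit the
    # noise for the whole run in one filter pass
    draws = []
    whites = []
    for s in _ramp_intensities(protocol, truth):
        for _ in range(protocol.trials_per_step):
            isi = protocol.isi_mean * (
                1.0
                + rng.uniform(-protocol.isi_jitter_frac, protocol.isi_jitter_frac)
            )
            jitter = rng.uniform(0.0, jit_ms)
            eps_m = _lognormal_factor(wspec.trial_cv, rng)
            eps_h = _lognormal_factor(wspec.trial_cv, rng)
            whites.append(rng.standard_normal(n))
            draws.append((float(s), isi, jitter, eps_m, eps_h))
    lo, hi = 10.0, min(500.0, 0.45 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    unit = signal.sosfiltfilt(sos, np.stack(whites), axis=-1)
    unit /= unit.std(axis=-1, keepdims=True)

    trials: list[Trial] = []
    for (s, isi, jitter, eps_m, eps_h), noise in zip(draws, unit):
        trial = _assemble_trial(
            s, truth, wspec, fs, jitter, eps_m, eps_h, noise,
            pre_ms, M_WINDOW_MS, H_WINDOW_MS,
        )
        trials.append(replace(trial, isi=float(isi)))
    return SweepRun(
        fs=protocol.fs,
        trials=tuple(trials),
        subject_id=subject_id,
        truth=truth,
        seed=seed,
    )


# Uniform ranges for cohort heterogeneity. Centers are tied so that the
# H-reflex rises well before the M-wave and falls near/after the M midpoint,
# the usual soleus arrangement at popliteal-fossa stimulation.
_TRUTH_RANGES = {
    "m_max": (200.0, 400.0),
    "m_center": (18.0, 30.0),
    "m_slope": (0.4, 0.8),
    "h_scale": (100.0, 250.0),
    "h_rise_offset": (7.0, 10.0),   # m_center - h_rise_center
    "h_rise_slope": (0.6, 1.0),
    "h_fall_offset": (0.0, 4.0),    # h_fall_center - m_center
    "h_fall_slope": (0.35, 0.6),
}


def draw_truth(rng: np.random.Generator) -> RecruitmentTruth:
    """Draw one subject's recruitment truth from the documented uniform ranges."""
    r = _TRUTH_RANGES
    m_center = rng.uniform(*r["m_center"])
    return RecruitmentTruth(
        m_max=rng.uniform(*r["m_max"]),
        m_center=m_center,
        m_slope=rng.uniform(*r["m_slope"]),
        h_scale=rng.uniform(*r["h_scale"]),
        h_rise_center=m_center - rng.uniform(*r["h_rise_offset"]),
        h_rise_slope=rng.uniform(*r["h_rise_slope"]),
        h_fall_center=m_center + rng.uniform(*r["h_fall_offset"]),
        h_fall_slope=rng.uniform(*r["h_fall_slope"]),
    )


def generate_cohort(
    n_subjects: int,
    master_seed: int,
    protocol: SweepProtocol | None = None,
    wspec: WaveformSpec | None = None,
) -> list[SweepRun]:
    """Generate a cohort of runs with heterogeneous, reproducible truths.

    Per-subject seeds derive from the master seed by spawn-key indexing, so
    growing the cohort never perturbs earlier subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = protocol or SweepProtocol(start_intensity=4.0)
    wspec = wspec or WaveformSpec()
    runs = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence(master_seed, spawn_key=(i,))
        truth_rng = np.random.default_rng(ss)
        truth = draw_truth(truth_rng)
        subject_seed = int(ss.generate_state(1)[0] % (2**31))
        runs.append(
            generate_run(truth, protocol, wspec, subject_id=f"S{i:02d}", seed=subject_seed)
        )
    return runs


def simulate_gating(
    background: np.ndarray,
    gspec: GatingSpec,
    fs: int,
    smooth_ms: float = 0.0,
) -> np.ndarray:
    """Trigger-permission flags for a background-EMG series.

    A sample is trigger-permitted iff the rectified (optionally smoothed)
    background stayed at or below `background_limit_high` for the entire
    preceding `hold_duration`.
    """
    background = np.asarray(background, dtype=float)
    hold = int(round(gspec.hold_duration * fs))
    if len(background) < hold:
        raise ValueError("background series shorter than the hold duration")
    rect = np.abs(background)
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms * fs / 1000.0)))
        rect = np.convolve(rect, np.ones(w) / w, mode="same")
    quiet = (rect <= gspec.background_limit_high).astype(int)
    csum = np.concatenate([[0], np.cumsum(quiet)])
    permitted = np.zeros(len(background), dtype=bool)
    idx = np.arange(hold - 1, len(background))
    permitted[idx] = (csum[idx + 1] - csum[idx + 1 - hold]) == hold
    return permitted
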