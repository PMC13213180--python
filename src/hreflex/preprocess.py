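"""Filtering, integer downsampling with trigger quantization, and epoching.

This is the pseudo-online degradation path: a high-rate recording (3200 Hz) is
anti-alias low-pass filtered and decimated to emulate acquisition at a lower
rate. The trigger index is mapped by floor division, which deliberately keeps
the trigger-onset quantization jitter a lower-rate system would suffer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .simulate import SweepRun, Trial

__all__ = [
    "FilterSpec",
    "EpochSpec",
    "Epoch",
    "butterworth_filter",
    "antialias_cutoff",
    "downsample_run",
    "epoch_run",
    "align_to_artifact",
]

#: Anti-alias cutoff as a fraction of the target rate. Reproduces the
#: 200 Hz @ 640 Hz and 100 Hz @ 320 Hz low-pass/decimation pairs and
#: generalizes to interim rates (1600 -> 500, 800 -> 250, 400 -> 125 Hz).
ANTIALIAS_CUTOFF_FRACTION = 0.3125


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "highpass" | "lowpass"
    cutoff: float
    order: int = 2
    phase: str = "causal"  # "causal" | "zero-phase"

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.phase not in ("causal", "zero-phase"):
            raise ValueError(f"unknown filter phase {self.phase!r}")


@dataclass(frozen=True)
class EpochSpec:
    """600 ms analysis epoch around the stimulation trigger."""

    t_start: float = -200.0
    t_end: float = 400.0

    def __post_init__(self) -> None:
        if not self.t_start < 0 < self.t_end:
            raise ValueError("epoch must straddle the trigger (t_start < 0 < t_end)")

    @property
    def span_ms(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Epoch:
    samples: np.ndarray
    fs: int
    intensity: float
    t0_index: int


def butterworth_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth filter; zero-phase mode runs it forward-backward."""
    if spec.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz is not below the Nyquist frequency "
            f"{fs / 2} Hz at fs={fs} Hz"
        )
    sos = signal.butter(spec.order, spec.cutoff, btype=spec.kind, fs=fs, output="sos")
    if spec.phase == "zero-phase":
        return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))
    return signal.sosfilt(sos, np.asarray(x, dtype=float))


def antialias_cutoff(target_fs: float) -> float:
    """Anti-alias low-pass cutoff (Hz) used before decimating to `target_fs`."""
    return ANTIALIAS_CUTOFF_FRACTION * target_fs


def downsample_run(
    run: SweepRun,
    target_fs: int,
    *,
    antialias_phase: str = "zero-phase",
) -> SweepRun:
    """Anti-alias filter and decimate a run to `target_fs`.

    The source rate must be an integer multiple of the target. The trigger
    index maps by floor division — the residual sub-sample offset is recorded
    per trial, modelling the trigger quantization of a lower-rate system.
    """
    if target_fs == run.fs:
        return run
    if run.fs % target_fs != 0:
        raise ValueError(
            f"source rate {run.fs} Hz is not an integer multiple of "
            f"target rate {target_fs} Hz"
        )
    if target_fs < 320:
        warnings.warn(
            f"target rate {target_fs} Hz is below the 320 Hz considered minimum "
            "for H-reflex measurement",
            stacklevel=2,
        )
    k = run.fs // target_fs
    spec = FilterSpec("lowpass", antialias_cutoff(target_fs), 2, antialias_phase)
    lengths = {len(tr.samples) for tr in run.trials}
    if len(lengths) == 1:
        stacked = np.stack([tr.samples for tr in run.trials])
        sos = signal.butter(spec.order, spec.cutoff, btype="lowpass", fs=run.fs,
                            output="sos")
        if spec.phase == "zero-phase":
            filtered = signal.sosfiltfilt(sos, stacked, axis=-1)
        else:
            filtered = signal.sosfilt(sos, stacked, axis=-1)
    else:
        filtered = [butterworth_filter(tr.samples, run.fs, spec) for tr in run.trials]
    new_trials = []
    for tr, y_full in zip(run.trials, filtered):
        y = y_full[::k]
        new_trig = tr.trigger_index // k
        residual = (tr.trigger_index - new_trig * k) / run.fs
        new_trials.append(
            Trial(
                intensity=tr.intensity,
                samples=y,
                trigger_index=new_trig,
                isi=tr.isi,
                trigger_residual_s=residual,
            )
        )
    meta = dict(run.meta)
    meta["antialias"] = {
        "cutoff_hz": spec.cutoff,
        "order": spec.order,
        "phase": spec.phase,
        "decimation_factor": k,
        "source_fs_hz": run.fs,
    }
    return replace(run, fs=target_fs, trials=tuple(new_trials), meta=meta)


def epoch_run(run: SweepRun, espec: EpochSpec = EpochSpec()) -> list[Epoch]:
    """Cut one epoch per trial, half-open at the right edge."""
    fs = run.fs
    n_pre = int(round(-espec.t_start * fs / 1000.0))
    n_total = int(round(espec.span_ms * fs / 1000.0))
    epochs = []
    for i, tr in enumerate(run.trials):
        i0 = tr.trigger_index - n_pre
        i1 = i0 + n_total
        if i0 < 0 or i1 > len(tr.samples):
            raise ValueError(
                f"trial {i}: samples do not cover the epoch span "
                f"[{espec.t_start}, {espec.t_end}) ms around the trigger"
            )
        epochs.append(
            Epoch(
                samples=tr.samples[i0:i1].copy(),
                fs=fs,
                intensity=tr.intensity,
                t0_index=n_pre,
            )
        )
    return epochs


def align_to_artifact(
    epoch: Epoch, search_ms: float = 3.0, snr_factor: float = 5.0
) -> tuple[Epoch, bool]:
    """Re-anchor the trigger to the stimulus-artifact peak.

    Looks for the maximum absolute sample within `search_ms` after the nominal
    trigger; alignment is applied only when that peak exceeds `snr_factor`
    times the pre-trigger RMS, otherwise the epoch is returned unchanged with
    an ``aligned=False`` flag.
    """
    t0 = epoch.t0_index
    n_search = max(1, int(round(search_ms * epoch.fs / 1000.0)))
    window = np.abs(epoch.samples[t0 : t0 + n_search])
    if len(window) == 0:
        return epoch, False
    pre = epoch.samples[:t0]
    pre_rms = float(np.sqrt(np.mean(pre**2))) if len(pre) else 0.0
    peak_rel = int(np.argmax(window))
    if window[peak_rel] <= snr_factor * pre_rms:
        return epoch, False
    return replace(epoch, t0_index=t0 + peak_rel), True
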