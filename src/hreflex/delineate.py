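"""Per-trial response measurement and response-window delineation.

The per-trial measure is the mean rectified value (MRV) of the EMG inside a
fixed post-stimulus window, after blanking the stimulus artifact and
subtracting its exponential decay tail. Windows come either from the
investigator ("manual" mode: fixed configurable windows) or from an automated
whole-run procedure that classifies 1 ms latency bins by which recruitment
model — logistic (M-wave-like) or hill (H-reflex-like) — explains the bin
amplitude's dependence on stimulation intensity.

The automated procedure here is a reconstruction in the spirit of published
delineation algorithms: every knob (bin width, latency range, the
model-comparison threshold) is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bands import H_WINDOW_MS, M_WINDOW_MS
from .fit import HillRecruitment, LogisticRecruitment
from .preprocess import Epoch, EpochSpec, epoch_run
from .simulate import SweepRun

__all__ = [
    "ResponseWindows",
    "mean_rectified_value",
    "blank_artifact",
    "remove_decay",
    "fit_decay_pooled",
    "subtract_decay",
    "delineate_auto",
    "measure_run",
    "manual_windows",
]


@dataclass(frozen=True)
class ResponseWindows:
    """Fixed M and H measurement windows (ms post-trigger), one pair per run."""

    m_window: tuple[float, float]
    h_window: tuple[float, float]
    method: str = "manual"

    def __post_init__(self) -> None:
        for name, (a, b) in (("m_window", self.m_window), ("h_window", self.h_window)):
            if not (0.0 < a < b <= 400.0):
                raise ValueError(f"{name} must lie within (0, 400] ms with start < end")
            if b - a < 3.0:
                raise ValueError(f"{name} must be at least 3 ms wide")
        if self.m_window[1] > self.h_window[0]:
            raise ValueError("M window must precede (and not overlap) the H window")


def manual_windows(
    m_window: tuple[float, float] = M_WINDOW_MS,
    h_window: tuple[float, float] = H_WINDOW_MS,
) -> ResponseWindows:
    """Investigator-style fixed windows (defaults: canonical soleus bands)."""
    return ResponseWindows(m_window=m_window, h_window=h_window, method="manual")


def _window_mask(epoch: Epoch, window: tuple[float, float]) -> np.ndarray:
    t_ms = (np.arange(len(epoch.samples)) - epoch.t0_index) * 1000.0 / epoch.fs
    return (t_ms >= window[0]) & (t_ms < window[1])


def mean_rectified_value(epoch: Epoch, window: tuple[float, float]) -> float:
    """Mean of |EMG| over post-trigger times in [start, end) ms."""
    mask = _window_mask(epoch, window)
    if not mask.any():
        raise ValueError(
            f"window {window} ms contains no samples at fs={epoch.fs} Hz"
        )
    return float(np.abs(epoch.samples[mask]).mean())


def blank_artifact(epoch: Epoch, blank_ms: float = 3.0) -> Epoch:
    """Zero the samples in [0, blank_ms) ms post-trigger."""
    if blank_ms <= 0:
        raise ValueError("blank_ms must be positive")
    x = epoch.samples.copy()
    x[_window_mask(epoch, (0.0, blank_ms))] = 0.0
    return replace(epoch, samples=x)


def _decay_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _decay_jac(t, a, tau, c):
    e = np.exp(-t / tau)
    return np.column_stack([e, a * e * t / tau**2, np.ones_like(t)])


def _fit_decay(t_ms: np.ndarray, y: np.ndarray):
    a0 = y[0] - y[-1]
    c0 = y[-1]
    popt, _ = curve_fit(
        _decay_model,
        t_ms,
        y,
        p0=[a0, 2.0, c0],
        bounds=([-np.inf, 0.1, -np.inf], [np.inf, 50.0, np.inf]),
        jac=_decay_jac,
        maxfev=5000,
    )
    return popt


def remove_decay(
    epoch: Epoch, fit_window: tuple[float, float] = (3.0, 15.0)
) -> tuple[Epoch, dict]:
    """Fit a·exp(-t/τ)+c over `fit_window` and subtract a·exp(-t/τ) post-trigger.

    Returns the corrected epoch and an audit dict with the fitted (a, τ, c)
    and a convergence flag; a non-convergent fit falls back to no subtraction.
    """
    mask = _window_mask(epoch, fit_window)
    t_ms = (np.arange(len(epoch.samples)) - epoch.t0_index) * 1000.0 / epoch.fs
    if mask.sum() < 3:
        return epoch, {"converged": False, "reason": "too few samples in fit window"}
    try:
        a, tau, c = _fit_decay(t_ms[mask], epoch.samples[mask])
    except (RuntimeError, ValueError) as exc:
        return epoch, {"converged": False, "reason": str(exc)}
    corrected = subtract_decay(epoch, a, tau)
    return corrected, {"converged": True, "a": float(a), "tau_ms": float(tau), "c": float(c)}


def subtract_decay(epoch: Epoch, a: float, tau: float) -> Epoch:
    """Subtract a·exp(-t/τ) from all post-trigger samples."""
    t_ms = (np.arange(len(epoch.samples)) - epoch.t0_index) * 1000.0 / epoch.fs
    x = epoch.samples.copy()
    post = t_ms >= 0
    x[post] -= a * np.exp(-t_ms[post] / tau)
    return replace(epoch, samples=x)


def fit_decay_pooled(
    epochs: list[Epoch], fit_window: tuple[float, float] = (3.0, 15.0)
) -> dict:
    """Fit the decay on the average of sub-threshold epochs.

    Averages the epochs at the lowest stimulation intensity present — below
    the recruitment thresholds their post-artifact signal is decay plus noise
    only — and fits the exponential there. Falls back to a per-epoch fit when
    fewer than 4 such epochs exist.
    """
    lo = min(ep.intensity for ep in epochs)
    subthr = [ep for ep in epochs if ep.intensity == lo]
    if len(subthr) >= 4:
        pooled = replace(subthr[0], samples=np.mean([ep.samples for ep in subthr], axis=0))
        _, audit = remove_decay(pooled, fit_window)
        audit["pooled_n"] = len(subthr)
        return audit
    _, audit = remove_decay(subthr[0], fit_window)
    audit["pooled_n"] = 1
    return audit


def _preprocess_epochs(
    run: SweepRun,
    *,
    blank_ms: float,
    decay_removal: bool,
    decay_fit_window: tuple[float, float],
    espec: EpochSpec,
) -> tuple[list[Epoch], dict]:
    epochs = [blank_artifact(ep, blank_ms) for ep in epoch_run(run, espec)]
    audit: dict = {"blank_ms": blank_ms, "decay": None}
    if decay_removal:
        decay = fit_decay_pooled(epochs, decay_fit_window)
        audit["decay"] = decay
        if decay.get("converged"):
            epochs = [subtract_decay(ep, decay["a"], decay["tau_ms"]) for ep in epochs]
    return epochs, audit


def measure_run(
    run: SweepRun,
    windows: ResponseWindows,
    *,
    blank_ms: float = 3.0,
    decay_removal: bool = True,
    baseline_window: tuple[float, float] = (-150.0, -50.0),
    baseline_subtract: bool = True,
    espec: EpochSpec = EpochSpec(),
) -> pd.DataFrame:
    """Per-trial recruitment data: (intensity_mA, mrv_m_uV, mrv_h_uV).

    Each trial's pre-stimulus background MRV (over `baseline_window`) is
    subtracted from the response MRVs, so the noise floor — which differs
    between sampling rates after anti-alias filtering — does not masquerade
    as response amplitude. The corrected values are deliberately not clipped
    at zero: clipping would re-introduce a rate-dependent positive bias at
    sub-threshold intensities (the clip bias grows as samples-per-window
    shrink).
    """
    epochs, _ = _preprocess_epochs(
        run,
        blank_ms=blank_ms,
        decay_removal=decay_removal,
        decay_fit_window=(blank_ms, 15.0),
        espec=espec,
    )
    rows = []
    for ep in epochs:
        mrv_m = mean_rectified_value(ep, windows.m_window)
        mrv_h = mean_rectified_value(ep, windows.h_window)
        if baseline_subtract:
            base = _baseline_mrv(ep, baseline_window)
            mrv_m -= base
            mrv_h -= base
        rows.append((ep.intensity, mrv_m, mrv_h))
    return pd.DataFrame(rows, columns=["intensity_mA", "mrv_m_uV", "mrv_h_uV"])


def _baseline_mrv(epoch: Epoch, baseline_window: tuple[float, float]) -> float:
    t_ms = (np.arange(len(epoch.samples)) - epoch.t0_index) * 1000.0 / epoch.fs
    mask = (t_ms >= baseline_window[0]) & (t_ms < baseline_window[1])
    if not mask.any():
        return 0.0
    return float(np.abs(epoch.samples[mask]).mean())


def _classify_bin(
    s: np.ndarray, v: np.ndarray, mse_reduction: float, n_starts: int
) -> str:
    """Label one latency bin M / H / none by recruitment-model comparison.

    The hill model nests a monotone rise (fall pushed beyond the data) and has
    two parameters more than the logistic, so on an M-like bin it always edges
    the logistic out slightly. The H label therefore requires a decisive
    improvement — hill residual at most half the logistic residual — together
    with a genuinely bell-shaped fit (an interior peak that has fallen to
    below 75 % of its maximum by the top of the ramp).
    """
    mse_const = float(np.var(v))
    if mse_const <= 0:
        return "none"
    # bin fits need classification accuracy, not parameter accuracy
    tol, maxfev = 1e-4, 400
    try:
        log = LogisticRecruitment(n_starts=n_starts, tol=tol, maxfev=maxfev).fit(s, v)
        mse_log = log.sse_ / len(s)
    except RuntimeError:
        mse_log = np.inf
    try:
        hill = HillRecruitment(n_starts=n_starts, tol=tol, maxfev=maxfev).fit(s, v)
        mse_hill = hill.sse_ / len(s)
        grid = np.linspace(s.min(), s.max(), 200)
        pred = hill.predict(grid)
        ipk = int(np.argmax(pred))
        bell_shaped = 0 < ipk < len(grid) - 1 and pred[-1] < 0.75 * pred[ipk]
    except RuntimeError:
        mse_hill, bell_shaped = np.inf, False

    log_ok = mse_log <= (1.0 - mse_reduction) * mse_const
    hill_ok = (
        mse_hill <= (1.0 - mse_reduction) * mse_const
        and bell_shaped
        and mse_hill <= 0.5 * mse_log
    )
    if hill_ok:
        return "H"
    if log_ok:
        return "M"
    return "none"


def _longest_run(labels: list[str], want: str, start: int = 0) -> tuple[int, int] | None:
    """Longest contiguous run of `want` within labels[start:], as (i0, i1)."""
    best = None
    i = start
    n = len(labels)
    while i < n:
        if labels[i] == want:
            j = i
            while j < n and labels[j] == want:
                j += 1
            if best is None or j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def delineate_auto(
    run: SweepRun,
    *,
    bin_ms: float = 1.0,
    latency_range: tuple[float, float] = (3.0, 60.0),
    mse_reduction: float = 0.20,
    n_starts: int = 3,
    blank_ms: float = 3.0,
    decay_removal: bool = True,
    baseline_subtract: bool = True,
    min_run_bins: int = 2,
) -> ResponseWindows:
    """Automated whole-run response-window delineation.

    Every epoch is blanked and decay-corrected; the 3-60 ms post-trigger range
    is divided into 1 ms bins (widening to one sample per bin at rates where a
    bin would otherwise be empty); each bin's rectified-mean amplitude across
    trials is regressed on stimulation intensity with a logistic and a hill
    model; bins where a model beats a constant fit by at least `mse_reduction`
    are labelled M or H by the better model; the windows are the longest
    contiguous M run and the longest contiguous H run after it.
    """
    epochs, _ = _preprocess_epochs(
        run,
        blank_ms=blank_ms,
        decay_removal=decay_removal,
        decay_fit_window=(blank_ms, 15.0),
        espec=EpochSpec(),
    )
    width = max(bin_ms, 1000.0 / run.fs)
    edges = np.arange(latency_range[0], latency_range[1] + width / 2, width)
    if len(edges) < 2:
        raise ValueError("latency range too narrow for the bin width")
    s = np.array([ep.intensity for ep in epochs])
    base = np.array(
        [_baseline_mrv(ep, (-150.0, -50.0)) for ep in epochs]
        if baseline_subtract
        else [0.0] * len(epochs)
    )

    # classify on per-step mean amplitudes: same information for the
    # model comparison, far fewer points for the nonlinear fits
    su, inv = np.unique(s, return_inverse=True)
    counts = np.bincount(inv)
    labels = []
    for a, b in zip(edges[:-1], edges[1:]):
        v = np.empty(len(epochs))
        for i, ep in enumerate(epochs):
            mask = _window_mask(ep, (a, b))
            v[i] = np.abs(ep.samples[mask]).mean() - base[i] if mask.any() else 0.0
        vm = np.bincount(inv, weights=v) / counts
        labels.append(_classify_bin(su, vm, mse_reduction, n_starts))

    # single stray bins are noise, not responses
    m_run = _longest_run(labels, "M")
    if m_run is None or m_run[1] - m_run[0] < min_run_bins:
        raise ValueError("M-wave not delineated: no contiguous logistic-like bins")
    h_run = _longest_run(labels, "H", start=m_run[1])
    if h_run is None or h_run[1] - h_run[0] < min_run_bins:
        raise ValueError("H-reflex not delineated")

    def bins_to_ms(i0: int, i1: int) -> tuple[float, float]:
        lo, hi = float(edges[i0]), float(edges[i1])
        if hi - lo < 3.0:  # enforce the minimum window width symmetrically
            pad = (3.0 - (hi - lo)) / 2.0
            lo, hi = lo - pad, hi + pad
        return lo, hi

    m_window = bins_to_ms(*m_run)
    h_window = bins_to_ms(*h_run)
    if m_window[1] > h_window[0]:  # shrink at the shared boundary
        mid = (m_window[1] + h_window[0]) / 2.0
        m_window = (m_window[0], mid)
        h_window = (mid, h_window[1])
    return ResponseWindows(m_window=m_window, h_window=h_window, method="automated")
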