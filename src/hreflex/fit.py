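"""Recruitment-curve fitting and curve-parameter extraction.

The M-wave recruitment curve is a saturating logistic of stimulation
intensity; the H-reflex curve is a "hill" curve, the product of a rising and a
falling sigmoid. Both are fitted by bounded nonlinear least squares with a
small set of deterministic data-derived starts, and the best final residual is
kept — the fit is therefore deterministic given the data.

Six curve parameters are extracted for cross-rate comparison: the normalized
residual MSE of each curve, H_max and M_max, and the stimulation intensities
at H_max and at M_threshold. The target stimulation intensity is the smallest
intensity where the fitted M-wave reaches 10 % of M_max, with an advisory flag
when the fitted H-reflex there falls below 75 % of H_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "LogisticRecruitment",
    "HillRecruitment",
    "FittedCurves",
    "CurveParams",
    "fit_recruitment",
    "extract_params",
    "target_intensity",
]


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("intensity input must be 1-d or a single-column 2-d array")
    return x


def _logistic(s, m_max, m_center, m_slope):
    return m_max * expit(m_slope * (s - m_center))


def _logistic_jac(s, m_max, m_center, m_slope):
    sig = expit(m_slope * (s - m_center))
    d = m_max * sig * (1.0 - sig)
    return np.column_stack([sig, -d * m_slope, d * (s - m_center)])


def _hill(s, h_scale, rise_center, rise_slope, fall_center, fall_slope):
    return (
        h_scale
        * expit(rise_slope * (s - rise_center))
        * expit(-fall_slope * (s - fall_center))
    )


def _hill_jac(s, h_scale, rise_center, rise_slope, fall_center, fall_slope):
    sr = expit(rise_slope * (s - rise_center))
    sf = expit(-fall_slope * (s - fall_center))
    dr = h_scale * sf * sr * (1.0 - sr)
    df = h_scale * sr * sf * (1.0 - sf)
    return np.column_stack([
        sr * sf,
        -dr * rise_slope,
        dr * (s - rise_center),
        df * fall_slope,
        -df * (s - fall_center),
    ])


_JACOBIANS = {_logistic: _logistic_jac, _hill: _hill_jac}


def _step_means(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean response per distinct intensity, sorted by intensity."""
    order = np.argsort(s, kind="stable")
    su, inv = np.unique(s[order], return_inverse=True)
    sums = np.bincount(inv, weights=y[order])
    counts = np.bincount(inv)
    return su, sums / counts


def _multistart_fit(model, s, y, starts, bounds, tol=None, maxfev=5000):
    best = None
    failures = []
    kwargs = {} if tol is None else {"ftol": tol, "xtol": tol}
    jac = _JACOBIANS.get(model)
    for p0 in starts:
        p0 = np.clip(p0, bounds[0] + 1e-9, bounds[1] - 1e-9)
        try:
            with warnings.catch_warnings(), np.errstate(divide="ignore",
                                                        invalid="ignore"):
                warnings.simplefilter("ignore", OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                popt, _ = curve_fit(model, s, y, p0=p0, bounds=bounds,
                                    maxfev=maxfev, jac=jac, **kwargs)
        except (RuntimeError, ValueError) as exc:
            failures.append((list(p0), str(exc)))
            continue
        sse = float(np.sum((model(s, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError(
            "recruitment-curve fit failed from every start: "
            + "; ".join(f"start={p}: {m}" for p, m in failures)
        )
    return best


class LogisticRecruitment(RegressorMixin, BaseEstimator):
    """Saturating logistic recruitment curve, M_max / (1 + exp(-b (s - c))).

    Parameters
    ----------
    n_starts : number of deterministic multi-start initializations.
    slope_bounds : allowed slope range (1/mA).
    center_margin : how far the fitted center may lie outside the data's
        intensity range, as a fraction of that range.
    """

    def __init__(self, n_starts: int = 5, slope_bounds: tuple = (0.01, 10.0),
                 center_margin: float = 0.5, tol: float | None = None,
                 maxfev: int = 5000):
        self.n_starts = n_starts
        self.slope_bounds = slope_bounds
        self.center_margin = center_margin
        self.tol = tol
        self.maxfev = maxfev

    def fit(self, X, y):
        s = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(s) != len(y):
            raise ValueError("X and y have different lengths")
        su, ym = _step_means(s, y)
        span = max(su[-1] - su[0], 1e-6)
        ymax = max(ym.max(), 1e-9)
        # center start: intensity where the smoothed curve first crosses half-max
        above = np.nonzero(ym >= 0.5 * ymax)[0]
        c0 = su[above[0]] if len(above) else su[len(su) // 2]
        slope_starts = np.geomspace(0.5 / span * 4, 8.0 / span * 4, self.n_starts)
        starts = [np.array([ymax, c0, b]) for b in slope_starts]
        lo = np.array([1e-9, su[0] - self.center_margin * span, self.slope_bounds[0]])
        hi = np.array([3.0 * ymax, su[-1] + self.center_margin * span, self.slope_bounds[1]])
        popt, sse = _multistart_fit(_logistic, s, y, starts, (lo, hi), self.tol, self.maxfev)
        self.m_max_, self.m_center_, self.m_slope_ = map(float, popt)
        self.sse_ = sse
        self.mse_raw_ = sse / len(s)
        self.n_points_ = len(s)
        self.converged_ = True
        return self

    def predict(self, X):
        return _logistic(_as_1d(X), self.m_max_, self.m_center_, self.m_slope_)


class HillRecruitment(RegressorMixin, BaseEstimator):
    """Bell-shaped recruitment curve: product of a rising and a falling sigmoid."""

    def __init__(self, n_starts: int = 5, slope_bounds: tuple = (0.01, 10.0),
                 center_margin: float = 0.5, tol: float | None = None,
                 maxfev: int = 5000):
        self.n_starts = n_starts
        self.slope_bounds = slope_bounds
        self.center_margin = center_margin
        self.tol = tol
        self.maxfev = maxfev

    def fit(self, X, y):
        s = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(s) != len(y):
            raise ValueError("X and y have different lengths")
        su, ym = _step_means(s, y)
        span = max(su[-1] - su[0], 1e-6)
        ymax = max(ym.max(), 1e-9)
        ipk = int(np.argmax(ym))
        # half-amplitude crossings around the smoothed peak
        left = np.nonzero(ym[: ipk + 1] >= 0.5 * ymax)[0]
        rise0 = su[left[0]] if len(left) else su[max(ipk - 1, 0)]
        right = np.nonzero(ym[ipk:] >= 0.5 * ymax)[0]
        fall0 = su[ipk + right[-1]] if len(right) else su[min(ipk + 1, len(su) - 1)]
        if fall0 <= rise0:
            fall0 = rise0 + 0.25 * span
        slope_grid = np.geomspace(1.0 / span * 4, 10.0 / span * 4, self.n_starts)
        starts = [np.array([2.0 * ymax, rise0, b, fall0, b / 2.0]) for b in slope_grid]
        lo = np.array(
            [1e-9, su[0] - self.center_margin * span, self.slope_bounds[0],
             su[0] - self.center_margin * span, self.slope_bounds[0]]
        )
        hi = np.array(
            [6.0 * ymax, su[-1] + self.center_margin * span, self.slope_bounds[1],
             su[-1] + 2.0 * self.center_margin * span, self.slope_bounds[1]]
        )
        popt, sse = _multistart_fit(_hill, s, y, starts, (lo, hi), self.tol, self.maxfev)
        (self.h_scale_, self.h_rise_center_, self.h_rise_slope_,
         self.h_fall_center_, self.h_fall_slope_) = map(float, popt)
        if self.h_rise_center_ > self.h_fall_center_:
            # swap-symmetric parameterization; normalize so rise precedes fall
            self.h_rise_center_, self.h_fall_center_ = (
                self.h_fall_center_, self.h_rise_center_)
            self.h_rise_slope_, self.h_fall_slope_ = (
                self.h_fall_slope_, self.h_rise_slope_)
        self.sse_ = sse
        self.mse_raw_ = sse / len(s)
        self.n_points_ = len(s)
        self.converged_ = True
        return self

    def predict(self, X):
        return _hill(
            _as_1d(X), self.h_scale_, self.h_rise_center_, self.h_rise_slope_,
            self.h_fall_center_, self.h_fall_slope_,
        )


@dataclass
class FittedCurves:
    m: LogisticRecruitment
    h: HillRecruitment
    n_points: int

    @property
    def converged(self) -> dict:
        return {"m": self.m.converged_, "h": self.h.converged_}


@dataclass
class CurveParams:
    """The six cross-rate comparison parameters plus the target intensity."""

    mse_h: float
    mse_m: float
    h_max: float
    m_max: float
    stim_at_hmax: float
    stim_at_mthreshold: float
    target_intensity: float = float("nan")
    mse_h_raw: float = float("nan")
    mse_m_raw: float = float("nan")
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _validate_data(data: pd.DataFrame) -> pd.DataFrame:
    required = {"intensity_mA", "mrv_m_uV", "mrv_h_uV"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"recruitment data is missing columns {sorted(missing)}")
    if data["intensity_mA"].nunique() < 8:
        raise ValueError("need at least 8 distinct stimulation intensities to fit")
    for col, name in (("mrv_m_uV", "M-wave"), ("mrv_h_uV", "H-reflex")):
        if np.allclose(data[col], 0.0):
            raise ValueError(f"{name} response column is degenerate (all zero)")
    return data


def fit_recruitment(data: pd.DataFrame) -> FittedCurves:
    """Fit both recruitment curves to a per-trial (intensity, MRV) table."""
    data = _validate_data(data)
    s = data["intensity_mA"].to_numpy(dtype=float)
    m = LogisticRecruitment().fit(s, data["mrv_m_uV"].to_numpy(dtype=float))
    h = HillRecruitment().fit(s, data["mrv_h_uV"].to_numpy(dtype=float))
    return FittedCurves(m=m, h=h, n_points=len(s))


def _ramp_step(s: np.ndarray) -> float:
    su = np.unique(s)
    if len(su) < 2:
        return 1.0
    return float(np.min(np.diff(su)))


def _intensity_grid(s: np.ndarray, grid_step: float) -> np.ndarray:
    step = _ramp_step(s)
    lo, hi = s.min() - step, s.max() + step
    return np.arange(lo, hi + grid_step / 2, grid_step)


def extract_params(
    curves: FittedCurves,
    data: pd.DataFrame,
    *,
    m_threshold_frac: float = 0.05,
    grid_step: float = 0.01,
) -> CurveParams:
    """Extract the six comparison parameters from fitted curves.

    H_max and its intensity come from a fine grid search over the measured
    intensity range extended by one ramp step. M_threshold is operationalized
    as the smallest intensity where the fitted M-wave reaches
    `m_threshold_frac` of the fitted M_max (5 % by default; recorded in the
    output metadata). MSEs are computed on curves and data normalized by the
    fitted maximum of the respective response, so they are dimensionless and
    comparable across subjects; raw µV² MSEs are also emitted.
    """
    if not (curves.m.converged_ and curves.h.converged_):
        return CurveParams(*([float("nan")] * 6), flags=["not converged"])
    s = data["intensity_mA"].to_numpy(dtype=float)
    grid = _intensity_grid(s, grid_step)

    h_curve = curves.h.predict(grid)
    i_max = int(np.argmax(h_curve))
    h_max = float(h_curve[i_max])
    stim_at_hmax = float(grid[i_max])

    m_max = curves.m.m_max_
    m_curve = curves.m.predict(grid)
    above = np.nonzero(m_curve >= m_threshold_frac * m_max)[0]
    flags: list[str] = []
    if len(above):
        stim_at_mthr = float(grid[above[0]])
    else:
        stim_at_mthr = float("nan")
        flags.append("M-threshold crossing outside measured range")

    y_m = data["mrv_m_uV"].to_numpy(dtype=float)
    y_h = data["mrv_h_uV"].to_numpy(dtype=float)
    fit_m = curves.m.predict(s)
    fit_h = curves.h.predict(s)
    norm_m = m_max if m_max > 0 else 1.0
    norm_h = h_max if h_max > 0 else 1.0
    mse_m = float(np.mean(((y_m - fit_m) / norm_m) ** 2))
    mse_h = float(np.mean(((y_h - fit_h) / norm_h) ** 2))

    return CurveParams(
        mse_h=mse_h,
        mse_m=mse_m,
        h_max=h_max,
        m_max=float(m_max),
        stim_at_hmax=stim_at_hmax,
        stim_at_mthreshold=stim_at_mthr,
        mse_h_raw=float(np.mean((y_h - fit_h) ** 2)),
        mse_m_raw=float(np.mean((y_m - fit_m) ** 2)),
        flags=flags,
        meta={"m_threshold_frac": m_threshold_frac, "grid_step_mA": grid_step},
    )


def target_intensity(
    curves: FittedCurves,
    data: pd.DataFrame,
    *,
    m_frac: float = 0.10,
    h_frac: float = 0.75,
    grid_step: float = 0.01,
) -> tuple[float, list[str]]:
    """Target stimulation intensity: smallest s where fitted M = `m_frac`·M_max.

    Flags "H-criterion unmet" when the fitted H-reflex at that intensity is
    below `h_frac` of H_max — the operating point should keep the H-reflex
    near-maximal while the M-wave is still small.
    """
    if not (curves.m.converged_ and curves.h.converged_):
        raise ValueError("cannot compute a target from non-converged curves")
    s = data["intensity_mA"].to_numpy(dtype=float)
    grid = _intensity_grid(s, grid_step)
    m_curve = curves.m.predict(grid)
    above = np.nonzero(m_curve >= m_frac * curves.m.m_max_)[0]
    if not len(above) or above[0] == 0:
        # crossing above the ramp, or already exceeded at its lower edge
        raise ValueError(
            f"the {m_frac:.0%} M_max crossing lies outside the measured "
            "intensity range"
        )
    s_star = float(grid[above[0]])
    h_curve = curves.h.predict(grid)
    h_max = float(h_curve.max())
    flags = []
    if curves.h.predict([s_star])[0] < h_frac * h_max:
        flags.append("H-criterion unmet")
    return s_star, flags
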