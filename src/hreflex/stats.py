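"""Method-agreement statistics for curve parameters across conditions.

The battery follows standard repeated-measures practice for comparing a
parameter measured under k conditions (sampling rates, or delineation
methods) in the same N subjects:

- Friedman rank test with Kendall's coefficient of concordance
  w = chi2 / (N (k-1)) as the effect size, and Tukey-style post-hoc
  comparisons of mean ranks via the studentized range;
- intraclass correlation (two-way model, absolute agreement, single
  measurement) for method agreement;
- TOST-style equivalence via the 90 % confidence interval of paired
  differences against prespecified bounds (±1 mA for stimulation
  intensities);
- Bland-Altman bias and limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RepeatedMeasures",
    "FriedmanResult",
    "friedman_test",
    "kendalls_w",
    "kendalls_w_label",
    "tukey_posthoc",
    "IccResult",
    "icc_absolute_single",
    "TostResult",
    "tost_equivalence",
    "bland_altman",
]


@dataclass(frozen=True)
class RepeatedMeasures:
    """N subjects x k conditions, complete cases only."""

    values: np.ndarray
    parameter_name: str = ""
    condition_labels: tuple = ()
    n_dropped: int = 0

    @staticmethod
    def from_table(
        df: pd.DataFrame, value: str, subject: str, condition: str,
        parameter_name: str = "",
    ) -> "RepeatedMeasures":
        """Pivot a long table; subjects with any missing cell are dropped listwise."""
        wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="first")
        complete = wide.dropna()
        return RepeatedMeasures(
            values=complete.to_numpy(dtype=float),
            parameter_name=parameter_name or value,
            condition_labels=tuple(wide.columns),
            n_dropped=len(wide) - len(complete),
        )


def _validate_matrix(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("repeated-measures values must be a 2-d matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing cells; drop incomplete subjects first")
    return x


@dataclass
class FriedmanResult:
    chi2: float            # tie-corrected statistic (drives the p value)
    chi2_uncorrected: float
    p: float
    w: float               # Kendall's concordance from the uncorrected chi2
    w_label: str
    n: int
    k: int
    posthoc: list = field(default_factory=list)


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, x)  # mid-ranks for ties


def _exact_friedman_p(ranks: np.ndarray, chi2_obs: float) -> float:
    """Exact permutation p: enumerate within-row rank permutations.

    Each subject's observed (mid-)ranks are permuted across conditions; the
    p value is the fraction of the (k!)^N assignments whose statistic reaches
    the observed one. Feasible only for small N and k.
    """
    from itertools import permutations, product

    n, k = ranks.shape
    if math.factorial(k) ** n > 500_000:
        raise ValueError("matrix too large for the exact permutation null")
    row_perms = [
        [np.array(p) for p in set(permutations(tuple(row)))] for row in ranks
    ]
    coef = 12.0 / (n * k * (k + 1))
    offset = 3.0 * n * (k + 1)
    hits = total = 0
    for assignment in product(*row_perms):
        rsum = np.sum(assignment, axis=0)
        chi2 = coef * float(rsum @ rsum) - offset
        total += 1
        if chi2 >= chi2_obs - 1e-9:
            hits += 1
    return hits / total


def friedman_test(
    rm: RepeatedMeasures | np.ndarray, exact: bool = False
) -> FriedmanResult:
    """Friedman repeated-measures rank test.

    Returns both the tie-uncorrected chi-square (from which Kendall's w is
    computed, keeping w in [0, 1]) and the tie-corrected chi-square that
    determines the p value against the chi-square(k-1) reference. With
    ``exact=True`` the p value comes from the exhaustive within-subject
    permutation null instead (small matrices only).
    """
    x = _validate_matrix(rm.values if isinstance(rm, RepeatedMeasures) else rm)
    n, k = x.shape
    ranks = _rank_matrix(x)
    rsum = ranks.sum(axis=0)
    chi2_un = 12.0 / (n * k * (k + 1)) * np.sum(rsum**2) - 3.0 * n * (k + 1)
    # tie correction: sum over rows of (t^3 - t) across tie groups
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1))
    chi2 = chi2_un / denom if denom > 0 else 0.0
    if exact:
        p = _exact_friedman_p(ranks, float(chi2_un))
    else:
        p = float(sps.chi2.sf(chi2, k - 1)) if denom > 0 else 1.0
    w = kendalls_w(chi2_un, n, k)
    return FriedmanResult(
        chi2=float(chi2),
        chi2_uncorrected=float(chi2_un),
        p=p,
        w=w,
        w_label=kendalls_w_label(w),
        n=n,
        k=k,
    )


def kendalls_w(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance, w = chi2 / (N (k-1))."""
    if n <= 0 or k <= 0:
        raise ValueError("n and k must be positive")
    if k == 1:
        raise ValueError("Kendall's w is undefined for a single condition")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return float(chi2) / (n * (k - 1))


def kendalls_w_label(w: float) -> str:
    """Cohen-style interpretation bands for Kendall's w."""
    if w >= 0.5:
        return "large"
    if w >= 0.3:
        return "moderate"
    if w >= 0.1:
        return "small"
    return "negligible"


def tukey_posthoc(rm: RepeatedMeasures | np.ndarray) -> list[tuple]:
    """All-pairs comparison of Friedman mean ranks via the studentized range.

    The pair statistic is |Rbar_i - Rbar_j| / sqrt(k(k+1)/(12N)), referred to
    the studentized range distribution with k groups and infinite df
    (Tukey-Kramer on ranks). Returns (label_i, label_j, p) triples.
    """
    if isinstance(rm, RepeatedMeasures):
        x = _validate_matrix(rm.values)
        labels = rm.condition_labels or tuple(range(x.shape[1]))
    else:
        x = _validate_matrix(rm)
        labels = tuple(range(x.shape[1]))
    n, k = x.shape
    mean_ranks = _rank_matrix(x).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(sps.studentized_range.sf(q, k, np.inf))
            out.append((labels[i], labels[j], min(max(p, 0.0), 1.0)))
    return out


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    label: str
    defined: bool = True


def _icc_label(icc: float) -> str:
    if icc > 0.9:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def icc_absolute_single(pairs: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC for absolute agreement, two-way model, single measurement (ICC(A,1)).

    Computed from the two-way ANOVA mean squares; the confidence interval
    follows the McGraw-Wong construction with Satterthwaite df.
    """
    x = _validate_matrix(pairs)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for the ICC")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = np.sum((x - grand) ** 2)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if ss_total <= 0 or denom <= 0:
        return IccResult(icc=float("nan"), ci=(float("nan"),) * 2, label="undefined",
                         defined=False)
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1)
    if mse <= 0:
        ci = (icc, icc)
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        fj = msc / mse
        if np.isinf(a) or np.isinf(b):
            ci = (icc, icc)
        else:
            v = (a * fj + b) ** 2 / (
                (a * fj) ** 2 / (k - 1) + b**2 / (n - 1)
            )
            f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower = (
                n * (msr - f_u * mse)
                / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            upper = (
                n * (f_l * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
            )
            ci = (float(lower), float(upper))
    return IccResult(icc=float(icc), ci=ci, label=_icc_label(float(icc)))


@dataclass
class TostResult:
    mean_diff: float
    ci90: tuple[float, float]
    bounds: float
    equivalent: bool
    n: int


def tost_equivalence(diffs: np.ndarray, bounds: float = 1.0,
                     alpha: float = 0.05) -> TostResult:
    """Equivalence via CI inclusion: 90 % CI of the paired mean difference
    must lie strictly inside (-bounds, +bounds).

    Operationally identical to two one-sided t tests at level `alpha`.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        ci = (mean, mean)
    else:
        half = sps.t.ppf(1 - alpha, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    equivalent = (-bounds < ci[0]) and (ci[1] < bounds)
    return TostResult(mean_diff=mean, ci90=ci, bounds=bounds,
                      equivalent=bool(equivalent), n=n)


def bland_altman(pairs: np.ndarray) -> tuple[float, float, float]:
    """Bias and 95 % limits of agreement for an N x 2 pairs matrix."""
    x = _validate_matrix(pairs)
    if x.shape[1] != 2:
        raise ValueError("Bland-Altman requires exactly two conditions")
    d = x[:, 0] - x[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
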