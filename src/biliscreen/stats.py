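"""Screening statistics for channel-intensity bilirubin estimation.

Implements the statistical analysis the study design calls for: Pearson
correlation of channel intensity against total plasma bilirubin (TsB) with a
Student-t p-value, single-pass 3-SD population outlier exclusion,
discrimination-limit classification (test positive when intensity is strictly
above the limit, condition positive when TsB is strictly above the clinical
threshold, default 205 μmol/L), an exhaustive threshold scan, and stepwise
forward multiple linear regression with a partial-F entry criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ConfusionTable",
    "ScreeningResult",
    "ThresholdScan",
    "RegressionModel",
    "StatsError",
    "exclude_outliers",
    "pearson",
    "classify_and_score",
    "threshold_scan",
    "stepwise_forward",
    "DEFAULT_CLINICAL_THRESHOLD",
]

#: TsB warning limit (μmol/L) defining the condition-positive class
DEFAULT_CLINICAL_THRESHOLD = 205.0


class StatsError(ValueError):
    pass


@dataclass
class CorrelationResult:
    channel: Optional[str]
    r: float
    p_value: float
    n: int


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int
    clinical_threshold: float
    discrimination_limit: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ScreeningResult:
    """Sensitivity/specificity of one discrimination limit, in percent.

    A statistic whose denominator is empty (no condition-positives for
    sensitivity, no condition-negatives for specificity) is reported as
    ``None`` and flagged, never coerced to 0 or 100.
    """

    confusion: ConfusionTable
    sensitivity: Optional[float]
    specificity: Optional[float]

    @property
    def sensitivity_defined(self) -> bool:
        return self.sensitivity is not None

    @property
    def specificity_defined(self) -> bool:
        return self.specificity is not None


@dataclass
class ThresholdScan:
    """Per-limit screening results plus the implied limit choice.

    ``best_limit_full_sensitivity`` is the largest scanned limit that still
    catches every condition-positive subject (sensitivity 100%) — the rule a
    screening test wants, maximising specificity subject to missing no one.
    """

    table: pd.DataFrame
    best_limit_full_sensitivity: Optional[float]


@dataclass
class RegressionModel:
    selected_terms: list
    coefficients: dict
    entry_p_values: list
    intercept: float = 0.0


def exclude_outliers(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Indices retained by the single-pass population outlier rule.

    Drops values deviating more than ``k`` population standard deviations
    (denominator n) from the population mean. One pass only — the mean and SD
    are not recomputed after exclusion.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise StatsError("need at least 3 values")
    if k <= 0:
        raise StatsError("k must be positive")
    mean = v.mean()
    sd = v.std()  # population SD
    if sd == 0:
        return np.arange(v.size)
    return np.nonzero(np.abs(v - mean) <= k * sd)[0]


def pearson(
    x: Sequence[float], y: Sequence[float], channel: Optional[str] = None
) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided Student-t p-value.

    p is computed from t = r·sqrt((n-2)/(1-r²)) against t with n-2 degrees of
    freedom; |r| = 1 maps to p = 0.
    """
    xv = np.asarray(x, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise StatsError("x and y must be equal-length 1-D")
    n = xv.size
    if n < 3:
        raise StatsError("need at least 3 observations")
    xd = xv - xv.mean()
    yd = yv - yv.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0 or syy == 0:
        raise StatsError("correlation undefined for constant input")
    r = float(xd @ yd) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(channel=channel, r=r, p_value=p, n=n)


def classify_and_score(
    intensities: Sequence[float],
    tsb: Sequence[float],
    limit: float,
    clinical_threshold: float = DEFAULT_CLINICAL_THRESHOLD,
) -> ScreeningResult:
    """Score one discrimination limit against the clinical threshold.

    Test positive iff intensity > limit (strict); condition positive iff
    TsB > clinical_threshold (strict): subjects exactly on either boundary
    count as negative.
    """
    iv = np.asarray(intensities, dtype=np.float64)
    tv = np.asarray(tsb, dtype=np.float64)
    if iv.shape != tv.shape:
        raise StatsError("intensities and tsb must be equal length")
    if not 0 <= limit <= 255:
        raise StatsError(f"limit {limit} outside [0, 255]")
    test_pos = iv > limit
    cond_pos = tv > clinical_threshold
    tp = int(np.sum(test_pos & cond_pos))
    fp = int(np.sum(test_pos & ~cond_pos))
    tn = int(np.sum(~test_pos & ~cond_pos))
    fn = int(np.sum(~test_pos & cond_pos))
    conf = ConfusionTable(tp, fp, tn, fn, clinical_threshold, limit)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return ScreeningResult(conf, sens, spec)


def threshold_scan(
    intensities: Sequence[float],
    tsb: Sequence[float],
    clinical_threshold: float = DEFAULT_CLINICAL_THRESHOLD,
    limit_grid: Sequence[float] | None = None,
) -> ThresholdScan:
    """Score every candidate discrimination limit (default: all of 0-255).

    Sensitivity is monotone non-increasing and specificity monotone
    non-decreasing in the limit; the scan reports the largest limit with
    sensitivity 100%, which is the most specific limit that misses nobody.
    """
    grid = np.arange(256) if limit_grid is None else np.asarray(limit_grid)
    rows = []
    best = None
    for lim in grid:
        res = classify_and_score(intensities, tsb, float(lim), clinical_threshold)
        c = res.confusion
        rows.append(
            {
                "limit": float(lim),
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
        )
        if res.sensitivity is not None and res.sensitivity == 100.0:
            if best is None or lim > best:
                best = float(lim)
    return ThresholdScan(pd.DataFrame(rows), best)


def _check_collinearity(X: pd.DataFrame, tol: float = 1.0 - 1e-8) -> None:
    cols = list(X.columns)
    if len(cols) < 2:
        return
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) > tol:
                raise StatsError(
                    f"collinear candidates: {cols[i]!r} and {cols[j]!r}"
                )


def stepwise_forward(
    y: Sequence[float],
    candidates: pd.DataFrame,
    entry_alpha: float = 0.05,
) -> RegressionModel:
    """Stepwise forward multiple linear regression (OLS, partial-F entry).

    At each step the remaining candidate with the smallest partial-F p-value
    enters if that p is below ``entry_alpha``; the loop stops when no
    candidate qualifies. Ties break deterministically by column order. The
    partial F for adding one term is (SSR_reduced − SSR_full) / MSE_full on
    (1, n − k − 2) degrees of freedom, equivalent to the squared t of the new
    coefficient.
    """
    yv = np.asarray(y, dtype=np.float64)
    if not isinstance(candidates, pd.DataFrame):
        candidates = pd.DataFrame(np.asarray(candidates))
        candidates.columns = [f"x{i}" for i in range(candidates.shape[1])]
    n, k = candidates.shape
    if yv.size != n:
        raise StatsError("response and candidates must have equal length")
    if n <= k + 2:
        raise StatsError(f"need n > n_candidates + 2 (n={n}, candidates={k})")
    for col in candidates.columns:
        if candidates[col].nunique() <= 1:
            raise StatsError(f"constant candidate column {col!r}")
    _check_collinearity(candidates)

    selected: list[str] = []
    entry_ps: list[float] = []
    remaining = list(candidates.columns)

    def fit_ssr(cols: list[str]) -> tuple[float, int]:
        X = sm.add_constant(candidates[cols], has_constant="add") if cols else (
            pd.DataFrame({"const": np.ones(n)})
        )
        res = sm.OLS(yv, X).fit()
        return float(res.ssr), int(res.df_resid)

    ssr_cur, _ = fit_ssr(selected)
    while remaining:
        best_p, best_col, best_ssr = None, None, None
        for col in remaining:
            ssr_full, df_full = fit_ssr(selected + [col])
            if df_full <= 0:
                continue
            if ssr_full <= 1e-12 * max(ssr_cur, 1.0):
                p = 0.0
            else:
                f_stat = (ssr_cur - ssr_full) / (ssr_full / df_full)
                p = float(sps.f.sf(max(f_stat, 0.0), 1, df_full))
            if best_p is None or p < best_p:  # strict: ties keep column order
                best_p, best_col, best_ssr = p, col, ssr_full
        if best_p is None or best_p >= entry_alpha:
            break
        selected.append(best_col)
        entry_ps.append(best_p)
        remaining.remove(best_col)
        ssr_cur = best_ssr

    if selected:
        X = sm.add_constant(candidates[selected], has_constant="add")
        final = sm.OLS(yv, X).fit()
        coefs = {c: float(final.params[c]) for c in selected}
        intercept = float(final.params["const"])
    else:
        coefs, intercept = {}, float(yv.mean())
    return RegressionModel(
        selected_terms=selected,
        coefficients=coefs,
        entry_p_values=entry_ps,
        intercept=intercept,
    )
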