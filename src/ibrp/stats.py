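"""Statistics for condition comparisons.

Welch's unequal-variance t-test (two-tailed) for pairwise condition
comparisons, ordinary least-squares fits with R^2 for input/output
linearity checks, and small summary helpers.  SDs use the n-1
denominator throughout, matching spreadsheet STDEV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError
from .quantify import AffinityResult

__all__ = [
    "WelchResult",
    "FitResult",
    "welch_ttest",
    "linear_fit",
    "summarize_condition",
    "fold_change",
]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float


def welch_ttest(a, b) -> WelchResult:
    """Welch's t-test with two-tailed p.

    Degrees of freedom follow Welch-Satterthwaite.  Identical samples
    give t = 0, p = 1.  Requires n >= 2 per sample and nonzero variance
    in at least one sample.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateSampleError("each sample needs n >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise DegenerateSampleError(
            "both samples have zero variance and different means"
        )
    sa = va / a.size
    sb = vb / b.size
    se = np.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(min(p, 1.0)))


def linear_fit(x, y) -> FitResult:
    """Ordinary least squares of y on x with R^2 = 1 - SS_res/SS_tot.

    Constant x is an error (the slope is unidentifiable).  Constant y
    with varying x returns slope 0 and, by convention, R^2 = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equally sized samples with n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("x is constant; slope is undefined")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = np.sum((y - ym) ** 2)
    if ss_tot == 0:
        return FitResult(slope=float(slope), intercept=float(intercept),
                         r_squared=0.0)
    ss_res = np.sum((y - (slope * x + intercept)) ** 2)
    return FitResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(1.0 - ss_res / ss_tot),
    )


def summarize_condition(result: AffinityResult) -> dict:
    """Flat report record for one condition (mean, SD, n, relative)."""
    return {
        "condition_id": result.condition_id,
        "affinity_mean": result.affinity_mean,
        "affinity_sd": result.affinity_sd,
        "n": result.n,
        "relative_affinity": result.relative_affinity,
    }


def fold_change(a: AffinityResult, b: AffinityResult) -> float:
    """Ratio of mean affinities, ``a / b``."""
    if b.affinity_mean == 0:
        raise ZeroDivisionError("reference condition has zero mean affinity")
    return a.affinity_mean / b.affinity_mean
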