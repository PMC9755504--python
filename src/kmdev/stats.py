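"""Region averaging and consistency metrics: CV, ICC(A,1), RAD.

Test–retest reliability follows the single-rater, absolute-agreement,
two-way model: with subjects as rows and sessions as columns of a complete
table, the two-way ANOVA mean squares (MSR rows, MSC columns, MSE
residual) give

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with the F-based McGraw–Wong 95% confidence interval.  CV uses the n−1
sample standard deviation; RAD uses the symmetric pair-mean denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .datamodel import ParameterMap, RegionMask

__all__ = [
    "SubjectSessionTable",
    "IccResult",
    "RadResult",
    "region_mean",
    "coefficient_of_variation",
    "icc_a1",
    "relative_absolute_difference",
]


@dataclass(frozen=True)
class SubjectSessionTable:
    """Complete matrix of region-mean values, subjects × sessions."""

    values: np.ndarray
    region: str = ""
    parameter: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (subjects × sessions) matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("table must be complete (no missing values)")
        object.__setattr__(self, "values", v)


class IccResult(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


class RadResult(NamedTuple):
    mean: float
    sd: float
    per_subject: np.ndarray


def region_mean(
    pmap: ParameterMap, mask: RegionMask, label: int, parameter: str = "sws"
) -> tuple[float, int]:
    """Arithmetic mean of a parameter over the valid voxels of one region.

    Returns ``(mean, n_voxels)``; raises if the region does not intersect
    the validity mask (e.g. lies entirely in trimmed slices).
    """
    if mask.labels.shape != pmap.grid.shape:
        raise ValueError("mask is not aligned to the parameter map grid")
    if parameter not in ("sws", "pr"):
        raise ValueError("parameter must be 'sws' or 'pr'")
    volume = pmap.sws if parameter == "sws" else pmap.pr
    sel = mask.region(label) & pmap.valid_mask & np.isfinite(volume)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"region label {label} has no valid voxels (trimmed or zero-weight)"
        )
    return float(volume[sel].mean()), n


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Inter-subject CV in percent: 100·SD(n−1)/mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = (
        np.sum((x - grand) ** 2)
        - k * np.sum((x.mean(axis=1) - grand) ** 2)
        - n * np.sum((x.mean(axis=0) - grand) ** 2)
    )
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(table: SubjectSessionTable, alpha: float = 0.05) -> IccResult:
    """ICC(A,1) with its 95% (or 1−alpha) confidence interval.

    Degenerate tables with zero total variance have perfect agreement by
    convention: ICC = 1 with an undefined (NaN) interval and the
    ``degenerate`` flag set.
    """
    x = table.values
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("ICC(A,1) requires ≥ 3 subjects and ≥ 2 sessions")
    if np.allclose(x, x.flat[0]):
        return IccResult(1.0, np.nan, np.nan, degenerate=True)
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for the absolute-agreement single-rater ICC
    if mse == 0:
        return IccResult(float(icc), np.nan, np.nan, degenerate=True)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isinf(a) or np.isinf(b):
        return IccResult(float(icc), np.nan, np.nan, degenerate=True)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f2 = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return IccResult(float(icc), float(lower), float(upper))


def relative_absolute_difference(
    baseline: Sequence[float], repeat: Sequence[float]
) -> RadResult:
    """Mean relative absolute difference of paired test–retest values, in %.

    Per subject: 100·|x₂ − x₁| / ((x₁ + x₂)/2); mean and SD are taken
    across subjects.  The symmetric pair-mean denominator treats both
    sessions identically (the alternative baseline denominator differs
    only at the third significant digit for ~1% differences).
    """
    x1 = np.asarray(baseline, dtype=np.float64)
    x2 = np.asarray(repeat, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size == 0:
        raise ValueError("baseline and repeat must be equal-length 1-D sequences")
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("RAD requires strictly positive paired values")
    rad = 100.0 * np.abs(x2 - x1) / ((x1 + x2) / 2.0)
    sd = float(rad.std(ddof=1)) if rad.size > 1 else 0.0
    return RadResult(mean=float(rad.mean()), sd=sd, per_subject=rad)
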