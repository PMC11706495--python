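"""Test-retest reliability via the intraclass correlation ICC(A,1).

The study design yields five two-column comparisons per sleep variable:
night 1 vs night 2 within the conventional lab (HSL), night 1 vs 2 within
the mobile lab (MSL), the two labs on night 1, the two labs on night 2, and
the third vs fourth study night pooled over both crossover arms.  Each is
scored with the two-way model, absolute-agreement, single-measurement ICC
(McGraw & Wong's ICC(A,1), the "two-way mixed, absolute agreement, single
measurement" setting of SPSS), with its F-based 95% CI and significance
test, and bucketed into the Koo–Li interpretation categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)

COMPARISONS = ("HSL1-HSL2", "MSL1-MSL2", "HSL1-MSL1", "HSL2-MSL2", "N3-N4")

KOO_LI_THRESHOLDS = (0.5, 0.75, 0.9)
KOO_LI_CATEGORIES = ("poor", "moderate", "good", "excellent")


@dataclass
class PairedMatrix:
    """An n_subjects x 2 matrix of one variable for one comparison."""

    values: np.ndarray
    comparison_label: str = ""
    n_dropped: int = 0

    @classmethod
    def from_columns(cls, a, b, comparison_label: str = "") -> "PairedMatrix":
        m = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
        complete = ~np.isnan(m).any(axis=1)
        dropped = int((~complete).sum())
        if dropped:
            logger.info(
                "%s: dropped %d incomplete pairs (pairwise deletion)",
                comparison_label or "paired matrix", dropped,
            )
        return cls(values=m[complete], comparison_label=comparison_label,
                   n_dropped=dropped)


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    category: str
    n_used: int
    comparison_label: str = ""


def classify_icc(icc: float, boundary: str = "upward") -> str:
    """Koo–Li category for an ICC value.

    The published thresholds overlap at the printed boundaries; by default
    each boundary belongs to the higher category (half-open upward: 0.75 is
    'good', 0.9 is 'excellent').  ``boundary='downward'`` assigns boundaries
    to the lower category instead.
    """
    if not math.isfinite(icc):
        raise ValueError(f"non-finite ICC {icc}")
    if boundary not in ("upward", "downward"):
        raise ValueError(f"unknown boundary convention {boundary!r}")
    thresholds = KOO_LI_THRESHOLDS
    if boundary == "upward":
        idx = sum(icc >= t for t in thresholds)
    else:
        idx = sum(icc > t for t in thresholds)
    return KOO_LI_CATEGORIES[idx]


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way subjects x sessions decomposition."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(m: PairedMatrix | np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    Point estimate from the ANOVA mean squares,

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

    with the standard F-based 95% CI (McGraw & Wong) and the F-test of
    ICC > 0 (F = MSR/MSE on (n−1, (n−1)(k−1)) df).
    """
    if isinstance(m, PairedMatrix):
        label = m.comparison_label
        values = m.values
    else:
        label = ""
        values = np.asarray(m, float)
    n, k = values.shape
    if n < 3:
        raise InsufficientDataError(
            f"ICC needs at least 3 complete pairs, got {n}"
        )
    if np.allclose(values, values.flat[0]):
        raise DegenerateInputError("zero total variance in paired matrix")

    msr, msc, mse = _anova_mean_squares(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateInputError("degenerate ANOVA decomposition")
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1): Satterthwaite df for the mixture
    # a*MSC + b*MSE appearing in the F bounds.
    if mse == 0 and msc == 0:
        ci = (icc, icc)
        p = 0.0
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else math.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else math.inf
        if math.isinf(a) or math.isinf(b):
            ci = (icc, icc)
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = (n * (msr - f_l * mse)) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = (n * (f_u * msr - mse)) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
            ci = (float(lower), float(upper))
        if mse > 0:
            f_obs = msr / mse
            p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
        else:
            p = 0.0

    lo = min(ci[0], icc)
    hi = max(ci[1], icc)
    return IccResult(
        icc=float(icc), ci95=(lo, hi), p=p,
        category=classify_icc(float(icc)), n_used=n, comparison_label=label,
    )


def comparison_columns(study: pd.DataFrame, variable: str, label: str
                       ) -> PairedMatrix:
    """Extract the two paired columns of one comparison from a long table.

    ``study`` must have columns subject, place (HSL/MSL), timepoint (1/2),
    night (1–4) and the variable.  The third-vs-fourth-night comparison
    pools both crossover order arms.
    """
    wide = study.pivot_table(index="subject", columns=["place", "timepoint"],
                             values=variable, aggfunc="first")

    def col(place: str, tp: int) -> pd.Series:
        try:
            return wide[(place, tp)]
        except KeyError:
            return pd.Series(np.nan, index=wide.index)

    if label == "HSL1-HSL2":
        a, b = col("HSL", 1), col("HSL", 2)
    elif label == "MSL1-MSL2":
        a, b = col("MSL", 1), col("MSL", 2)
    elif label == "HSL1-MSL1":
        a, b = col("HSL", 1), col("MSL", 1)
    elif label == "HSL2-MSL2":
        a, b = col("HSL", 2), col("MSL", 2)
    elif label == "N3-N4":
        by_night = study.pivot_table(index="subject", columns="night",
                                     values=variable, aggfunc="first")
        a = by_night[3] if 3 in by_night else pd.Series(np.nan, index=by_night.index)
        b = by_night[4] if 4 in by_night else pd.Series(np.nan, index=by_night.index)
    else:
        raise ValueError(f"unknown comparison label {label!r}")
    a, b = a.align(b)
    return PairedMatrix.from_columns(a.to_numpy(float), b.to_numpy(float), label)


def run_reliability(study: pd.DataFrame, variables: list[str],
                    comparisons: tuple[str, ...] = COMPARISONS) -> pd.DataFrame:
    """One ICC(A,1) per (variable, comparison) over the crossover study.

    Comparisons with fewer than 3 complete pairs, or degenerate data, yield a
    row with missing estimates rather than failing the whole run.
    """
    rows = []
    for var in variables:
        for label in comparisons:
            pm = comparison_columns(study, var, label)
            row = {"variable": var, "comparison": label,
                   "n_used": len(pm.values), "n_dropped": pm.n_dropped}
            try:
                res = icc_a1(pm)
                row.update(icc=res.icc, ci95_lo=res.ci95[0],
                           ci95_hi=res.ci95[1], p=res.p, category=res.category)
            except (InsufficientDataError, DegenerateInputError) as exc:
                logger.warning("ICC %s / %s: %s", var, label, exc)
                row.update(icc=np.nan, ci95_lo=np.nan, ci95_hi=np.nan,
                           p=np.nan, category="missing")
            rows.append(row)
    return pd.DataFrame(rows)
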