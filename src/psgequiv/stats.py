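"""Nonparametric tests, effect sizes, transforms, and environmental summaries.

This module collects the statistical machinery around the core reliability
and equivalence procedures: Friedman tests over the four place x time cells,
Wilcoxon signed-rank tests in the centred (SAS) convention with exact small-
sample p-values, Bonferroni correction, Cohen's d in both its raw-data and
least-squares-means forms, Pearson/Spearman correlations with pairwise
deletion, Box-Cox normalization, and hourly/CV summaries of the bedroom
environment logs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateInputError, InsufficientDataError
from .io import EnvLog

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p: float
    df: float | tuple | None = None
    p_adjusted: float | None = None
    d: float | None = None
    n_used: int = 0
    note: str = ""


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

def _friedman_chi2(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    den = float((ranks ** 2).sum()) - n * k * (k + 1) ** 2 / 4.0
    return num / den if den > 0 else 0.0


def friedman(levels: np.ndarray, exact: bool = False) -> TestResult:
    """Friedman chi-square over k related samples (rows = subjects).

    Midranks within each row; the statistic uses the tie-corrected form

        chi2 = (k−1) · Σ_j (R_j − n(k+1)/2)² / (Σ_ij r_ij² − n·k(k+1)²/4),

    df = k−1, with the asymptotic chi-square p-value.  ``exact=True``
    computes the permutation p instead, enumerating all (k!)^n products of
    within-row column permutations (feasible for n ≤ 5, k ≤ 4).  Rows with
    any missing value are dropped (and logged).
    """
    m = np.asarray(levels, float)
    complete = ~np.isnan(m).any(axis=1)
    if (~complete).sum():
        logger.info("friedman: dropped %d incomplete rows", (~complete).sum())
    m = m[complete]
    n, k = m.shape
    if n < 2:
        raise InsufficientDataError(f"friedman needs >= 2 complete rows, got {n}")
    ranks = np.apply_along_axis(sstats.rankdata, 1, m)
    chi2 = _friedman_chi2(ranks)
    den_zero = float((ranks ** 2).sum()) - n * k * (k + 1) ** 2 / 4.0 == 0
    if den_zero:
        return TestResult("chi2_friedman", 0.0, 1.0, df=k - 1, n_used=n,
                          note="all rows constant")
    if not exact:
        p = float(sstats.chi2.sf(chi2, k - 1))
        return TestResult("chi2_friedman", chi2, p, df=k - 1, n_used=n)

    import itertools
    import math as _math

    if _math.factorial(k) ** n > 2_000_000:
        raise ValueError("exact Friedman enumeration infeasible for this size")
    perms = np.array(list(itertools.permutations(range(k))))
    # enumerate column-sum vectors over products of row permutations
    sums = np.zeros((1, k))
    sq_sum = float((ranks ** 2).sum())  # invariant under permutation
    for row in ranks:
        permuted = row[perms]                       # (k!, k)
        sums = (sums[:, None, :] + permuted[None, :, :]).reshape(-1, k)
    num = (k - 1) * ((sums - n * (k + 1) / 2.0) ** 2).sum(axis=1)
    den = sq_sum - n * k * (k + 1) ** 2 / 4.0
    stats_all = num / den
    p = float(np.mean(stats_all >= chi2 - 1e-9))
    return TestResult("chi2_friedman", chi2, p, df=k - 1, n_used=n,
                      note="exact permutation")


# ---------------------------------------------------------------------------
# Wilcoxon signed rank (centred / SAS convention)
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """Exact two-sided p for the signed-rank sum by sign-flip enumeration.

    ``ranks2`` are doubled midranks (integers even with ties); the null
    distribution of the doubled positive-rank sum is built by dynamic
    programming over the 2^n sign assignments.
    """
    ranks2 = np.rint(ranks2).astype(int)
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    centre = total / 2.0
    dev = abs(w2_obs - centre)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - centre) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, convention: str = "centred",
    exact_max_n: int = 20,
) -> TestResult:
    """Wilcoxon signed-rank test of paired x vs y.

    The default ``centred`` convention reports S = W⁺ − n'(n'+1)/4 over the
    n' nonzero differences, so S ranges over ±n'(n'+1)/4 (at n'=15 the
    extremes are ±60); ``wplus`` reports the plain positive-rank sum.  The
    p-value is exact (sign-flip enumeration, valid with ties) for n' ≤ 20,
    otherwise a normal approximation with midrank tie correction and
    continuity correction.  All-zero differences give S = 0, p = 1.
    """
    if convention not in ("centred", "wplus"):
        raise ValueError(f"unknown convention {convention!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("S", 0.0, 1.0, n_used=0, note="all differences zero")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    centre = n * (n + 1) / 4.0
    s = w_plus - centre

    if n <= exact_max_n:
        p = _signed_rank_exact_p(2 * ranks, 2 * w_plus)
        note = "exact"
    else:
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((counts ** 3 - counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            p, note = 1.0, "degenerate variance"
        else:
            z = (abs(s) - 0.5) / math.sqrt(var)
            p = float(2 * sstats.norm.sf(z))
            note = "normal approximation"
    stat = s if convention == "centred" else w_plus
    return TestResult("S" if convention == "centred" else "W+",
                      float(stat), min(p, 1.0), n_used=n, note=note)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by the number of tests, capping at 1."""
    p_values = list(p_values)
    m = len(p_values) if m is None else m
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# Effect sizes and correlations
# ---------------------------------------------------------------------------

def cohens_d_raw(sample1, sample2) -> float:
    """Cohen's d from raw data: (mean1 − mean2) / pooled SD.

    The pooled SD uses both samples' variances weighted by df; any pairing
    structure is deliberately ignored, as is conventional for reporting.
    """
    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError("need >= 2 observations per sample")
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise DegenerateInputError("zero pooled variance")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def cohens_d_lsmeans(lsm1: float, lsm2: float, se_diff: float, n: int) -> float:
    """Cohen's d from model least-squares means: (LSM1 − LSM2)/(SE_diff·√n).

    ``se_diff`` is the model standard error of the difference and ``n`` the
    number of subjects; SE_diff·√n plays the role of the per-subject SD of
    the contrast.
    """
    if se_diff <= 0:
        raise DegenerateInputError("standard error of difference must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((lsm1 - lsm2) / (se_diff * math.sqrt(n)))


def _pairwise(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.size != x.size or x.size != y.size:
        raise ValueError("x and y must have equal length")
    return x[ok], y[ok]


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with t-based p (pairwise deletion)."""
    x, y = _pairwise(x, y)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in a correlation input")
    r, p = sstats.pearsonr(x, y)
    return TestResult("r", float(r), float(p), df=x.size - 2, n_used=x.size)


def spearman_rs(x, y) -> TestResult:
    """Spearman rank correlation (midranks) with t-approximation p."""
    x, y = _pairwise(x, y)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in a correlation input")
    rs, p = sstats.spearmanr(x, y)
    return TestResult("rs", float(rs), float(p), df=x.size - 2, n_used=x.size)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxResult:
    lam: float
    transformed: np.ndarray
    normality_ok_before: bool
    normality_ok_after: bool


def box_cox(x, alpha: float = 0.05, grid_step: float = 0.01) -> BoxCoxResult:
    """Box-Cox transform with λ chosen by profile likelihood on a fixed grid.

    λ is searched over [−3, 3] in steps of ``grid_step``; the transform is
    (x^λ − 1)/λ, ln x at λ = 0.  Normality (Shapiro–Wilk at ``alpha``) is
    assessed before and after.  Requires all values strictly positive and
    nonconstant.
    """
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise InsufficientDataError("Box-Cox needs >= 3 observations")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires all values > 0")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series cannot be transformed")

    grid = np.arange(-3.0, 3.0 + grid_step / 2, grid_step)
    llf = np.array([sstats.boxcox_llf(l, x) for l in grid])
    lam = float(grid[int(np.argmax(llf))])
    transformed = np.log(x) if lam == 0 else (x ** lam - 1.0) / lam

    before = float(sstats.shapiro(x).pvalue) >= alpha
    after = float(sstats.shapiro(transformed).pvalue) >= alpha
    return BoxCoxResult(lam=lam, transformed=transformed,
                        normality_ok_before=before, normality_ok_after=after)


# ---------------------------------------------------------------------------
# Environmental summaries
# ---------------------------------------------------------------------------

@dataclass
class EnvSummary:
    night_means: dict[str, float]
    cv_pct: dict[str, float]
    hourly_means: dict[str, list[float]]
    n_missing: dict[str, int] = field(default_factory=dict)


def env_summarize(log: EnvLog, lights_off, lights_on) -> EnvSummary:
    """Night mean, CV, and hourly means of each parameter over the sleep window.

    Hourly bins partition [lights_off, lights_on) into whole clock hours
    (eight for the standard 8-h window); CV = SD/mean x 100 over the full
    window.  Missing samples are excluded with per-parameter counts logged.
    """
    lights_off = pd.Timestamp(lights_off)
    lights_on = pd.Timestamp(lights_on)
    df = log.frame
    in_window = (df["timestamp"] >= lights_off) & (df["timestamp"] < lights_on)
    sel = df[in_window]
    if len(sel) == 0:
        raise ValueError("environment log does not overlap the sleep window")
    n_hours = int(round((lights_on - lights_off).total_seconds() / 3600.0))
    hour_idx = (
        (sel["timestamp"] - lights_off).dt.total_seconds() // 3600.0
    ).astype(int)

    night_means, cv_pct, hourly, n_missing = {}, {}, {}, {}
    for param in EnvLog.PARAMETERS:
        series = sel[param]
        missing = int(series.isna().sum())
        if missing:
            logger.info("env %s: %d missing samples excluded", param, missing)
        n_missing[param] = missing
        vals = series.dropna()
        mean = float(vals.mean()) if len(vals) else math.nan
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
        night_means[param] = mean
        cv_pct[param] = (
            sd / abs(mean) * 100.0
            if math.isfinite(mean) and mean != 0 else math.nan
        )
        by_hour = series.groupby(hour_idx).mean()
        hourly[param] = [
            float(by_hour.get(h, math.nan)) for h in range(n_hours)
        ]
    return EnvSummary(night_means=night_means, cv_pct=cv_pct,
                      hourly_means=hourly, n_missing=n_missing)
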