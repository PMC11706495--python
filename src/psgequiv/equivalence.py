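"""CI-inclusion equivalence testing adapted from generic-drug guidelines.

Two measurement conditions are declared equivalent for a sleep variable when
the 90% confidence interval of their within-subject mean difference, taken
as a percentage of a designated reference mean, lies entirely within ±20%.
The five comparisons and their reference means follow the study layout:

=============  ==========================  =========================
label          difference (first − second) reference mean
=============  ==========================  =========================
HSL1-HSL2      HSL night1 − HSL night2     HSL night-1 mean
MSL1-MSL2      MSL night1 − MSL night2     MSL night-1 mean
HSL1-MSL1      HSL night1 − MSL night1     HSL night-1 mean
HSL2-MSL2      HSL night2 − MSL night2     HSL night-2 mean
N3-N4          study night3 − night4       night-3 mean of the
                                           subjects in the HSL arm
=============  ==========================  =========================

The default CI is the paired-t interval, which coincides with the
mixed-model interval for a two-level within-subject contrast under compound
symmetry; a model-based alternative can be plugged in via ``ci_method``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .reliability import COMPARISONS, comparison_columns

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_PCT = 20.0
DEFAULT_CI_LEVEL = 0.90


@dataclass
class EquivalenceResult:
    variable: str
    comparison_label: str
    mean_diff: float
    ci90: tuple[float, float]
    ref_mean: float
    ratio_bounds_pct: tuple[float, float]
    equivalent: bool | None
    n_used: int


def mean_diff_ci90(
    ref: np.ndarray, test: np.ndarray, level: float = DEFAULT_CI_LEVEL
) -> tuple[float, tuple[float, float]]:
    """Within-subject mean difference (ref − test) with a two-sided 90% CI.

    Paired-t construction: d̄ ± t_{(1+level)/2, n−1} · sd(d)/√n.  When every
    difference is zero the CI degenerates to (0, 0).
    """
    ref = np.asarray(ref, float)
    test = np.asarray(test, float)
    ok = ~(np.isnan(ref) | np.isnan(test))
    d = ref[ok] - test[ok]
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return mean, (mean, mean)
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / math.sqrt(n)
    return mean, (mean - half, mean + half)


def _reference_mean(study: pd.DataFrame, variable: str, label: str) -> float:
    """The enumerated reference mean for one comparison."""
    def mean_of(place: str, tp: int) -> float:
        sel = study[(study["place"] == place) & (study["timepoint"] == tp)]
        return float(sel[variable].mean())

    if label in ("HSL1-HSL2", "HSL1-MSL1"):
        return mean_of("HSL", 1)
    if label == "MSL1-MSL2":
        return mean_of("MSL", 1)
    if label == "HSL2-MSL2":
        return mean_of("HSL", 2)
    if label == "N3-N4":
        sel = study[(study["night"] == 3) & (study["place"] == "HSL")]
        return float(sel[variable].mean())
    raise ValueError(f"unknown comparison label {label!r}")


def equivalence_for(
    variable: str,
    comparison_label: str,
    study: pd.DataFrame,
    margin_pct: float = DEFAULT_MARGIN_PCT,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> EquivalenceResult:
    """Equivalence verdict for one variable and one comparison.

    The CI bounds are expressed as a percentage of the reference mean;
    equivalence requires both to lie within ±margin.  A zero reference mean
    leaves the verdict missing; a negative one is used in absolute value
    (with a warning), CI inclusion still required.
    """
    pm = comparison_columns(study, variable, comparison_label)
    mean_diff, ci = mean_diff_ci90(pm.values[:, 0], pm.values[:, 1], ci_level)
    ref = _reference_mean(study, variable, comparison_label)

    if not math.isfinite(ref) or ref == 0:
        logger.warning(
            "%s / %s: reference mean %s; ratio undefined, verdict missing",
            variable, comparison_label, ref,
        )
        return EquivalenceResult(
            variable=variable, comparison_label=comparison_label,
            mean_diff=mean_diff, ci90=ci, ref_mean=ref,
            ratio_bounds_pct=(math.nan, math.nan), equivalent=None,
            n_used=len(pm.values),
        )
    scale = abs(ref)
    if ref < 0:
        logger.warning(
            "%s / %s: negative reference mean %.4g; ratio bounds use |ref|",
            variable, comparison_label, ref,
        )
    bounds = (float(ci[0] / scale * 100.0), float(ci[1] / scale * 100.0))
    verdict = bool(-margin_pct <= bounds[0] and bounds[1] <= margin_pct)
    return EquivalenceResult(
        variable=variable, comparison_label=comparison_label,
        mean_diff=mean_diff, ci90=ci, ref_mean=ref,
        ratio_bounds_pct=bounds, equivalent=verdict, n_used=len(pm.values),
    )


def run_equivalence(
    study: pd.DataFrame,
    variables: list[str],
    comparisons: tuple[str, ...] = COMPARISONS,
    margin_pct: float = DEFAULT_MARGIN_PCT,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> pd.DataFrame:
    """Equivalence table over all variables x comparisons (one row per cell)."""
    rows = []
    for var in variables:
        for label in comparisons:
            try:
                r = equivalence_for(var, label, study, margin_pct, ci_level)
                rows.append({
                    "variable": var, "comparison": label,
                    "mean_diff": r.mean_diff,
                    "ci90_lo": r.ci90[0], "ci90_hi": r.ci90[1],
                    "ref_mean": r.ref_mean,
                    "ratio_lo_pct": r.ratio_bounds_pct[0],
                    "ratio_hi_pct": r.ratio_bounds_pct[1],
                    "equivalent": r.equivalent, "n_used": r.n_used,
                })
            except InsufficientDataError as exc:
                logger.warning("equivalence %s / %s: %s", var, label, exc)
                rows.append({
                    "variable": var, "comparison": label,
                    "mean_diff": np.nan, "ci90_lo": np.nan, "ci90_hi": np.nan,
                    "ref_mean": np.nan, "ratio_lo_pct": np.nan,
                    "ratio_hi_pct": np.nan, "equivalent": None, "n_used": 0,
                })
    return pd.DataFrame(rows)
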