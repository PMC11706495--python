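"""ICC(A,1) against first-principles oracles and its Koo-Li interpretation."""

import numpy as np
import pandas as pd
import pytest

from psgequiv.errors import DegenerateInputError, InsufficientDataError
from psgequiv.reliability import (COMPARISONS, PairedMatrix, classify_icc,
                                  comparison_columns, icc_a1, run_reliability)


def oracle_icc_a1(m: np.ndarray) -> float:
    """Brute-force ICC(A,1) from explicit sums of squares (independent path)."""
    n, k = m.shape
    grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(m[i]) / k for i in range(n)]
    col = [sum(m[:, j]) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum((m[i][j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def oracle_icc_c1(m: np.ndarray) -> float:
    """Consistency ICC (no column-effect penalty), for the contrast test."""
    n, k = m.shape
    grand = m.mean()
    row = m.mean(axis=1)
    col = m.mean(axis=0)
    ssr = k * ((row - grand) ** 2).sum()
    ssc = n * ((col - grand) ** 2).sum()
    sse = ((m - grand) ** 2).sum() - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIccA1:
    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            m = rng.normal(10, 3, size=(10, 2))
            assert icc_a1(m).icc == pytest.approx(oracle_icc_a1(m), abs=1e-10)

    def test_identical_columns_perfect_agreement(self):
        m = np.column_stack([np.arange(8, dtype=float)] * 2)
        assert icc_a1(m).icc == pytest.approx(1.0)

    def test_constant_shift_penalized_vs_consistency(self, rng):
        base = rng.normal(0, 10, 5)
        m = np.column_stack([base, base + 20.0])
        res = icc_a1(m)
        assert res.icc == pytest.approx(oracle_icc_a1(m), abs=1e-10)
        assert res.icc < oracle_icc_c1(m) - 0.2

    def test_independent_columns_near_zero(self, rng):
        m = rng.standard_normal((2000, 2))
        assert abs(icc_a1(m).icc) < 0.05

    def test_shift_of_both_columns_invariant(self, rng):
        m = rng.normal(0, 5, size=(12, 2))
        a = icc_a1(m).icc
        b = icc_a1(m + 100.0).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_row_permutation_invariant(self, rng):
        m = rng.normal(0, 5, size=(12, 2))
        perm = rng.permutation(12)
        assert icc_a1(m).icc == pytest.approx(icc_a1(m[perm]).icc, abs=1e-12)

    def test_ci_brackets_estimate_and_p_small_for_strong_agreement(self, rng):
        subj = rng.normal(0, 10, 15)
        m = np.column_stack([subj + rng.normal(0, 2, 15),
                             subj + rng.normal(0, 2, 15)])
        res = icc_a1(m)
        assert res.ci95[0] <= res.icc <= res.ci95[1]
        assert res.p < 0.01

    def test_pingouin_cross_check(self, rng):
        """Independent library oracle for estimate and CI (ICC2 = two-way
        absolute agreement, single measurement)."""
        pingouin = pytest.importorskip("pingouin")
        m = rng.normal(50, 8, size=(12, 2))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": m.reshape(-1),
        })
        icc_table = pingouin.intraclass_corr(long, targets="subject",
                                             raters="rater", ratings="score")
        ref = icc_table[icc_table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in icc_table.columns else "CI95"
        res = icc_a1(m)
        assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-6)
        assert res.ci95[0] == pytest.approx(ref[ci_col][0], abs=0.02)
        assert res.ci95[1] == pytest.approx(ref[ci_col][1], abs=0.02)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            icc_a1(np.ones((2, 2)))

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            icc_a1(np.full((6, 2), 3.0))


class TestClassify:
    @pytest.mark.parametrize("value,expected", [
        (0.44, "poor"), (0.57, "moderate"), (0.79, "good"), (0.95, "excellent"),
        (0.5, "moderate"), (0.75, "good"), (0.9, "excellent"),  # boundaries up
        (-0.2, "poor"),
    ])
    def test_koo_li_categories(self, value, expected):
        assert classify_icc(value) == expected

    def test_downward_boundary_option(self):
        assert classify_icc(0.75, boundary="downward") == "moderate"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(float("nan"))


def _study_frame(rng, n=15, subject_sd=3.0, noise_sd=2.0):
    rows = []
    for s in range(n):
        u = rng.normal(0, subject_sd)
        order = "HSL_first" if s % 2 == 0 else "MSL_first"
        for night in (1, 2, 3, 4):
            first, second = (("HSL", "MSL") if order == "HSL_first"
                             else ("MSL", "HSL"))
            place = first if night <= 2 else second
            tp = night if night <= 2 else night - 2
            rows.append({"subject": s, "night": night, "place": place,
                         "timepoint": tp, "order": order,
                         "pct_n3": 20 + u + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestRunReliability:
    def test_table_covers_all_cells(self, rng):
        df = _study_frame(rng)
        out = run_reliability(df, ["pct_n3"])
        assert len(out) == len(COMPARISONS)
        assert set(out["comparison"]) == set(COMPARISONS)
        assert out["icc"].notna().all()

    def test_subject_relabeling_leaves_icc_unchanged(self, rng):
        df = _study_frame(rng)
        out1 = run_reliability(df, ["pct_n3"])
        shuffled = df.copy()
        mapping = dict(zip(range(15), rng.permutation(15)))
        shuffled["subject"] = shuffled["subject"].map(mapping)
        out2 = run_reliability(shuffled, ["pct_n3"])
        merged = out1.merge(out2, on="comparison", suffixes=("_a", "_b"))
        assert np.allclose(merged["icc_a"], merged["icc_b"])

    def test_constant_variable_marked_missing(self, rng):
        df = _study_frame(rng)
        df["flat"] = 7.0
        out = run_reliability(df, ["flat"])
        assert (out["category"] == "missing").all()

    def test_third_fourth_night_pools_arms(self, rng):
        df = _study_frame(rng)
        pm = comparison_columns(df, "pct_n3", "N3-N4")
        assert len(pm.values) == 15  # every subject contributes nights 3 and 4

    def test_missing_nights_pairwise_deleted(self, rng):
        df = _study_frame(rng)
        df.loc[(df.subject < 2) & (df.night == 4), "pct_n3"] = np.nan
        pm = comparison_columns(df, "pct_n3", "N3-N4")
        assert len(pm.values) == 13
        assert pm.n_dropped == 2


class TestParameterRecovery:
    def test_mean_estimate_recovers_true_icc(self, rng):
        """True ICC 0.7 by construction; mean estimate over replicates
        within +/-0.05 (n=15 per replicate, 200 replicates)."""
        subject_sd, noise_sd = np.sqrt(0.7), np.sqrt(0.3)
        est = []
        for _ in range(200):
            u = rng.normal(0, subject_sd, 15)
            m = np.column_stack([u + rng.normal(0, noise_sd, 15),
                                 u + rng.normal(0, noise_sd, 15)])
            est.append(icc_a1(m).icc)
        assert np.mean(est) == pytest.approx(0.7, abs=0.05)
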