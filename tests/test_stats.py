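"""Nonparametric tests, effect sizes, Box-Cox, environmental summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from psgequiv.errors import DegenerateInputError, InsufficientDataError
from psgequiv.io import EnvLog
from psgequiv.stats import (bonferroni, box_cox, cohens_d_lsmeans,
                            cohens_d_raw, env_summarize, friedman, pearson_r,
                            spearman_rs, wilcoxon_signed_rank)


class TestFriedman:
    def test_constant_rows_give_zero_statistic(self):
        res = friedman(np.tile([[3.0, 3.0, 3.0, 3.0]], (6, 1)))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_column_permutation_invariant(self, rng):
        m = rng.normal(0, 1, (8, 4))
        a = friedman(m).statistic
        b = friedman(m[:, [2, 0, 3, 1]]).statistic
        assert a == pytest.approx(b)

    def test_monotone_row_transform_invariant(self, rng):
        m = rng.normal(0, 1, (8, 4))
        a = friedman(m).statistic
        b = friedman(np.exp(m)).statistic  # strictly monotone
        assert a == pytest.approx(b)

    def test_agrees_with_scipy_asymptotic(self, rng):
        m = rng.normal(0, 1, (12, 4))
        res = friedman(m)
        ref_stat, ref_p = sstats.friedmanchisquare(*m.T)
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p == pytest.approx(ref_p)

    def test_exact_p_matches_brute_force_enumeration(self):
        """Exhaustive (4!)^4 oracle: enumerate every product of within-row
        permutations with plain Python and compare the tail probability."""
        m = np.array([
            [1.0, 3.0, 2.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 2.0, 3.0, 1.0],
        ])
        res = friedman(m, exact=True)

        n, k = m.shape
        ranks = [tuple(sstats.rankdata(row)) for row in m]
        sq = sum(r ** 2 for row in ranks for r in row)
        den = sq - n * k * (k + 1) ** 2 / 4

        def stat(cols):
            return (k - 1) * sum((c - n * (k + 1) / 2) ** 2 for c in cols) / den

        perms = list(itertools.permutations(range(k)))
        count = total = 0
        obs = stat([sum(r[j] for r in ranks) for j in range(k)])
        for p1 in perms:
            r1 = [ranks[0][i] for i in p1]
            for p2 in perms:
                r2 = [ranks[1][i] for i in p2]
                for p3 in perms:
                    r3 = [ranks[2][i] for i in p3]
                    for p4 in perms:
                        cols = [r1[j] + r2[j] + r3[j] + ranks[3][p4[j]]
                                for j in range(k)]
                        total += 1
                        if stat(cols) >= obs - 1e-9:
                            count += 1
        assert res.statistic == pytest.approx(obs)
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_incomplete_rows_dropped(self, rng):
        m = rng.normal(0, 1, (6, 4))
        m[0, 2] = np.nan
        assert friedman(m).n_used == 5

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            friedman(np.array([[1.0, 2.0, 3.0, 4.0]]))


class TestWilcoxon:
    def test_all_negative_n15_hits_lower_extreme(self):
        """n'=15, every difference negative -> S = -15*16/4 = -60."""
        x = np.zeros(15)
        y = np.arange(1.0, 16.0)
        res = wilcoxon_signed_rank(x, y)
        assert res.statistic == -60.0
        assert res.p < 0.001

    def test_symmetric_differences_give_zero(self):
        x = np.array([0.0, 0.0, 0.0, 0.0])
        y = np.array([2.0, 1.0, -1.0, -2.0])
        assert wilcoxon_signed_rank(x, y).statistic == 0.0

    def test_exact_p_matches_sign_flip_enumeration(self, rng):
        """2^8 brute-force oracle over sign assignments, midranks kept."""
        for _ in range(5):
            d = rng.normal(0.5, 1.0, 8)
            d = d[d != 0]
            res = wilcoxon_signed_rank(d, np.zeros_like(d))
            ranks = sstats.rankdata(np.abs(d))
            total = ranks.sum()
            obs = ranks[d > 0].sum()
            count = 0
            n_all = 0
            for signs in itertools.product([0, 1], repeat=len(d)):
                w = sum(r for s, r in zip(signs, ranks) if s)
                n_all += 1
                if abs(w - total / 2) >= abs(obs - total / 2) - 1e-9:
                    count += 1
            assert res.p == pytest.approx(count / n_all, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        d = rng.normal(0.3, 1.0, 12)
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        ref = sstats.wilcoxon(d, mode="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_statistic_bounds_and_antisymmetry(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            a = wilcoxon_signed_rank(x, y)
            b = wilcoxon_signed_rank(y, x)
            n = a.n_used
            assert abs(a.statistic) <= n * (n + 1) / 4
            assert a.statistic == pytest.approx(-b.statistic)
            assert a.p == pytest.approx(b.p)

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(0.2, 1.0, 60)
        res = wilcoxon_signed_rank(x, np.zeros_like(x))
        ref = sstats.wilcoxon(x, correction=True, mode="approx")
        assert res.note == "normal approximation"
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(5), np.ones(5))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_wplus_convention(self):
        x = np.array([1.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(x, np.zeros(3), convention="wplus")
        assert res.statistic == 6.0


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.3], 6) == [pytest.approx(0.06), 1.0]

    def test_single_test_identity(self):
        assert bonferroni([0.2], 1) == [pytest.approx(0.2)]

    def test_never_below_raw(self, rng):
        ps = rng.random(10)
        adj = bonferroni(ps, 4)
        assert all(a >= p for a, p in zip(adj, ps))


class TestCohensD:
    def test_identical_samples_zero(self):
        assert cohens_d_raw([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        # means 10 vs 8, both sample SDs 4 -> pooled SD 4, d = 0.5
        assert cohens_d_raw([6.0, 10.0, 14.0], [4.0, 8.0, 12.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_raw([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_lsmeans_formula(self):
        # (10-8)/(1*sqrt(16)) = 0.5
        assert cohens_d_lsmeans(10.0, 8.0, 1.0, 16) == pytest.approx(0.5)

    def test_lsmeans_bad_se_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_lsmeans(1.0, 0.0, 0.0, 10)


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one_pearson_below(self, rng):
        x = rng.random(30) * 3
        y = np.exp(x)
        assert spearman_rs(x, y).statistic == pytest.approx(1.0)
        assert pearson_r(x, y).statistic < 1.0

    def test_spearman_matches_hand_ranking(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 0.5, 0.2])
        rx = sstats.rankdata(x)
        ry = sstats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rs(x, y).statistic == pytest.approx(expected)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        assert pearson_r(x, y).n_used == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(0, 0.8, 500))
        res = box_cox(x)
        assert abs(res.lam) <= 0.15
        assert not res.normality_ok_before

    def test_normal_sample_lambda_near_one(self, rng):
        # spread large enough relative to the mean that lambda is identified
        x = rng.normal(10, 2, 300)
        x = x[x > 0]
        res = box_cox(x)
        assert abs(res.lam - 1.0) <= 0.5
        assert res.normality_ok_after

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            box_cox([1.0, -2.0, 3.0])

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            box_cox([2.0, 2.0, 2.0, 2.0])


def _env_log(values_by_param, start="2020-06-01 23:00", freq="min", n=481):
    ts = pd.date_range(start, periods=n, freq=freq)
    frame = {"timestamp": ts}
    for p in EnvLog.PARAMETERS:
        v = values_by_param.get(p, 0.0)
        frame[p] = v if np.ndim(v) else np.full(n, v)
    return EnvLog(frame=pd.DataFrame(frame))


class TestEnvSummarize:
    LIGHTS_OFF = pd.Timestamp("2020-06-01 23:00")
    LIGHTS_ON = pd.Timestamp("2020-06-02 07:00")

    def test_constant_humidity(self):
        log = _env_log({"humidity_pct": 50.0})
        s = env_summarize(log, self.LIGHTS_OFF, self.LIGHTS_ON)
        assert s.night_means["humidity_pct"] == pytest.approx(50.0)
        assert s.cv_pct["humidity_pct"] == pytest.approx(0.0)
        assert s.hourly_means["humidity_pct"] == pytest.approx([50.0] * 8)

    def test_step_change_in_sound(self):
        sound = np.concatenate([np.full(240, 30.0), np.full(241, 40.0)])
        log = _env_log({"sound_db": sound})
        s = env_summarize(log, self.LIGHTS_OFF, self.LIGHTS_ON)
        assert s.hourly_means["sound_db"][:4] == pytest.approx([30.0] * 4)
        assert s.hourly_means["sound_db"][4:] == pytest.approx([40.0] * 4)
        assert s.night_means["sound_db"] == pytest.approx(35.0, abs=0.05)

    def test_gap_in_hour_three_logged_not_imputed(self, caplog):
        temp = np.full(481, 24.0)
        temp[185:195] = np.nan  # 10-minute gap during hour 3
        log = _env_log({"temperature_c": temp})
        with caplog.at_level("INFO"):
            s = env_summarize(log, self.LIGHTS_OFF, self.LIGHTS_ON)
        assert s.n_missing["temperature_c"] == 10
        assert s.hourly_means["temperature_c"][3] == pytest.approx(24.0)

    def test_cv_invariant_to_unit_rescaling(self, rng):
        vals = 20 + rng.random(481) * 5
        a = env_summarize(_env_log({"temperature_c": vals}),
                          self.LIGHTS_OFF, self.LIGHTS_ON)
        b = env_summarize(_env_log({"temperature_c": vals * 1.8}),
                          self.LIGHTS_OFF, self.LIGHTS_ON)
        assert a.cv_pct["temperature_c"] == pytest.approx(
            b.cv_pct["temperature_c"])

    def test_no_overlap_rejected(self):
        log = _env_log({"humidity_pct": 50.0})
        with pytest.raises(ValueError):
            env_summarize(log, pd.Timestamp("2021-01-01"),
                          pd.Timestamp("2021-01-02"))
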