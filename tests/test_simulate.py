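"""Synthetic crossover study generator: determinism, structure recovery."""

import math

import numpy as np
import pytest

from psgequiv.errors import ValidationError
from psgequiv.hypnogram import compute_sleep_variables
from psgequiv.simulate import (SimConfig, night_layout, score_study,
                               simulate_environment, simulate_eeg,
                               simulate_hypnogram, simulate_osa_ma,
                               simulate_study, subject_order, write_study,
                               read_study)
from psgequiv.spectral import detect_artifacts_amplitude, epoch_band_power
from psgequiv.io import derive
from psgequiv.stats import pearson_r


class TestDeterminism:
    def test_same_seed_same_stages(self):
        cfg = SimConfig(master_seed=12)
        a = simulate_hypnogram(cfg, 3, 2)
        b = simulate_hypnogram(cfg, 3, 2)
        assert a == b

    def test_different_seed_differs(self):
        a = simulate_hypnogram(SimConfig(master_seed=1), 0, 1)
        b = simulate_hypnogram(SimConfig(master_seed=2), 0, 1)
        assert not np.array_equal(a.stages, b.stages)

    def test_adding_subjects_preserves_existing(self):
        small = SimConfig(n_subjects=5, master_seed=3)
        large = SimConfig(n_subjects=9, master_seed=3)
        for s in range(5):
            for n in (1, 2, 3, 4):
                assert simulate_hypnogram(small, s, n) == simulate_hypnogram(
                    large, s, n)

    def test_study_files_byte_stable(self, tmp_path):
        cfg = SimConfig(n_subjects=3, master_seed=4)
        d1 = write_study(simulate_study(cfg), tmp_path / "a")
        d2 = write_study(simulate_study(cfg), tmp_path / "b")
        for f1 in sorted(d1.iterdir()):
            f2 = d2 / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name


class TestConfigValidation:
    def test_bad_transition_matrix_rejected(self):
        t = np.full((5, 5), 0.2)
        t[0, 0] = 0.5  # row no longer sums to 1
        with pytest.raises(ValidationError):
            SimConfig(transitions=t)

    def test_negative_arousal_rate_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(arousal_rate_per_h={"W": -1, "N1": 0, "N2": 0,
                                          "N3": 0, "R": 0})


class TestCrossoverLayout:
    def test_arms_near_equal(self):
        cfg = SimConfig(n_subjects=15)
        arms = [subject_order(cfg, s) for s in range(15)]
        assert abs(arms.count("HSL_first") - arms.count("MSL_first")) == 1

    def test_night_layout(self):
        assert night_layout("HSL_first", 1) == ("HSL", 1)
        assert night_layout("HSL_first", 4) == ("MSL", 2)
        assert night_layout("MSL_first", 2) == ("MSL", 2)
        assert night_layout("MSL_first", 3) == ("HSL", 1)

    def test_scored_table_shape(self):
        table = score_study(simulate_study(SimConfig(n_subjects=4,
                                                     master_seed=5),
                                           include_env=False))
        assert len(table) == 16
        assert set(table["place"]) == {"HSL", "MSL"}
        assert table.groupby("subject")["night"].apply(list).map(
            lambda x: x == [1, 2, 3, 4]).all()


class TestN3Structure:
    N_SUBJECTS = 500

    def _mean_diff(self, cfg):
        h, m = [], []
        for s in range(self.N_SUBJECTS):
            for n in (1, 2, 3, 4):
                place, _ = night_layout(subject_order(cfg, s), n)
                v = compute_sleep_variables(simulate_hypnogram(cfg, s, n)).pct_n3
                (h if place == "HSL" else m).append(v)
        return np.mean(h) - np.mean(m)

    def test_null_site_effect_symmetric(self):
        cfg = SimConfig(master_seed=21, place_effect_n3=0.0)
        assert abs(self._mean_diff(cfg)) <= 0.5

    def test_default_site_effect_near_three_points(self):
        cfg = SimConfig(master_seed=22)
        assert self._mean_diff(cfg) == pytest.approx(3.0, abs=1.0)


class TestArousals:
    def test_arousal_index_tracks_configured_rates(self):
        cfg = SimConfig(master_seed=30)
        aris = [compute_sleep_variables(simulate_hypnogram(cfg, s, 1)).ari_per_h
                for s in range(60)]
        # rates are 4-25/h by stage; TST-weighted mean should land mid-range
        assert 5 < np.nanmean(aris) < 20


class TestEeg:
    def _short_cfg(self, **kw):
        return SimConfig(trt_minutes=5.0, master_seed=31, **kw)

    def test_n3_vs_wake_swa_contrast(self):
        """The generator-analyzer loop recovers the configured SWA contrast."""
        cfg = self._short_cfg()
        hyp_n3 = simulate_hypnogram(cfg, 0, 1)
        hyp_n3.stages[:] = "N3"
        hyp_w = simulate_hypnogram(cfg, 0, 1)
        hyp_w.stages[:] = "W"

        def mean_swa(hyp):
            rec = simulate_eeg(cfg, hyp, 0, 1)
            sig = derive(rec, "F3", "M2")
            vals = [epoch_band_power(sig, i).values["swa"]
                    for i in range(hyp.n_epochs - 1)]
            return np.mean(vals)

        w = cfg.eeg_band_weights
        swa_rms2 = lambda s: sum(w[s].get(b, 0.0) ** 2 for b in ("so", "delta"))
        expected = math.log(swa_rms2("N3") / swa_rms2("W"))
        observed = mean_swa(hyp_n3) - mean_swa(hyp_w)
        assert observed == pytest.approx(expected, rel=0.10)

    def test_zero_band_weights_give_flat_signal(self):
        cfg = self._short_cfg()
        for s in cfg.eeg_band_weights:
            cfg.eeg_band_weights[s] = {b: 0.0 for b in cfg.eeg_band_weights[s]}
        hyp = simulate_hypnogram(cfg, 0, 1)
        rec = simulate_eeg(cfg, hyp, 0, 1)
        sig = derive(rec, "F3", "M2")
        assert np.max(np.abs(sig.samples)) < 1e-9
        ep = epoch_band_power(sig, 0)
        assert all(math.isnan(v) for v in ep.values.values())

    def test_injected_artifacts_match_amplitude_heuristic(self):
        cfg = self._short_cfg(artifact_epoch_prob=0.3)
        hyp = simulate_hypnogram(cfg, 0, 1)
        assert hyp.artifact_flags.any()  # probabilistic but seeded
        rec = simulate_eeg(cfg, hyp, 0, 1)
        sig = derive(rec, "F3", "M2")
        flags = detect_artifacts_amplitude(sig, hyp.n_epochs, 500.0)
        assert list(flags) == list(hyp.artifact_flags)


class TestEnvironment:
    def test_humidity_offset_recovered(self):
        cfg = SimConfig(master_seed=33)
        hsl, msl = [], []
        for s in range(20):
            for n in (1, 2, 3, 4):
                log = simulate_environment(cfg, s, n)
                (hsl if log.place == "HSL" else msl).append(
                    log.frame["humidity_pct"].mean())
        diff = np.mean(hsl) - np.mean(msl)
        assert diff == pytest.approx(cfg.env.humidity_hsl_offset_pct, abs=1.0)

    def test_msl_first_hour_sound_bump(self):
        cfg = SimConfig(master_seed=34)
        log = simulate_environment(cfg, 1, 1)  # subject 1 is MSL-first
        assert log.place == "MSL"
        f = log.frame
        hours = (f["timestamp"] - f["timestamp"].iloc[0]).dt.total_seconds() / 3600
        first = f.loc[hours < 1, "sound_db"].mean()
        rest = f.loc[hours >= 1, "sound_db"].mean()
        assert first - rest == pytest.approx(
            cfg.env.msl_first_hour_sound_bump_db, abs=1.0)


class TestOsaMa:
    def test_factor2_correlates_with_n3(self):
        cfg = SimConfig(master_seed=35)
        rng = np.random.default_rng(99)
        n3, f2 = [], []
        for s in range(500):
            pct = {1: float(rng.normal(20, 5))}
            scores = simulate_osa_ma(cfg, pct, s)
            n3.append(pct[1])
            f2.append(scores[1]["factor2"])
        res = pearson_r(n3, f2)
        assert res.statistic > 0.15
        assert res.p < 0.001

    def test_other_factors_uncorrelated(self):
        cfg = SimConfig(master_seed=36)
        rng = np.random.default_rng(100)
        n3, f1 = [], []
        for s in range(500):
            pct = {1: float(rng.normal(20, 5))}
            scores = simulate_osa_ma(cfg, pct, s)
            n3.append(pct[1])
            f1.append(scores[1]["factor1"])
        assert abs(pearson_r(n3, f1).statistic) < 0.12


class TestRoundTrip:
    def test_write_read_study(self, tmp_path):
        cfg = SimConfig(n_subjects=3, master_seed=40)
        study = simulate_study(cfg)
        write_study(study, tmp_path)
        back = read_study(tmp_path)
        assert len(back.nights) == len(study.nights)
        for a, b in zip(study.nights, back.nights):
            assert a.hypnogram == b.hypnogram
            assert a.place == b.place and a.timepoint == b.timepoint
            assert a.osa_ma == pytest.approx(b.osa_ma)
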