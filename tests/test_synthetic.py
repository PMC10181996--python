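"""Generator determinism, label structure, and waveform construction."""

import numpy as np
import pytest

from cuffbp.synthetic import (
    RecordParams,
    SynthConfig,
    draw_record_params,
    generate_feature_table,
    generate_records,
    ppg_beat_template,
    sample_population,
    synthesize_record,
)


class TestSamplePopulation:
    def test_empty_cohort(self):
        config = SynthConfig(n_subjects=0, total_records=None)
        assert sample_population(config, np.random.default_rng(0)) == []

    def test_fixed_seed_reproduces_population(self):
        config = SynthConfig.compromised_cohort(seed=4)
        a = sample_population(config, np.random.default_rng(42))
        b = sample_population(config, np.random.default_rng(42))
        assert a == b

    def test_sex_fraction_matches_binomial_expectation(self):
        # n=10000, p=0.6: the observed male fraction should fall within
        # 3 standard errors, SE = sqrt(p(1-p)/n) ~ 0.0049
        config = SynthConfig(
            n_subjects=10_000, total_records=None, records_per_subject=1, p_male=0.6
        )
        pop = sample_population(config, np.random.default_rng(99))
        frac = np.mean([s.sex for s in pop])
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 10_000)

    def test_record_counts_capped_at_five_and_sum_to_total(self):
        config = SynthConfig.compromised_cohort(seed=0)
        pop = sample_population(config, np.random.default_rng(0))
        counts = [s.n_records for s in pop]
        assert sum(counts) == 126
        assert max(counts) <= 5

    def test_impossible_total_rejected(self):
        with pytest.raises(ValueError):
            sample_population(
                SynthConfig(n_subjects=2, total_records=11),
                np.random.default_rng(0),
            )


class TestFeatureTable:
    def test_row_count_and_schema(self, cohort_126):
        dataset, truth = cohort_126
        assert len(dataset) == 126
        assert len(truth) == 126
        assert dataset.frame["subject_id"].nunique() == 31

    def test_zero_noise_map_identity_holds_row_wise(self):
        config = SynthConfig.compromised_cohort(seed=5, noise_sd_bp=0.0)
        dataset, _ = generate_feature_table(config)
        f = dataset.frame
        np.testing.assert_allclose(
            f["map_mmhg"], (2 * f["dbp_mmhg"] + f["sbp_mmhg"]) / 3, rtol=0, atol=1e-12
        )
        assert (f["dbp_mmhg"] < f["map_mmhg"]).all()
        assert (f["map_mmhg"] < f["sbp_mmhg"]).all()

    def test_degenerate_ranges_give_identical_rows(self):
        config = SynthConfig(
            n_subjects=3,
            records_per_subject=2,
            total_records=None,
            noise_sd_bp=0.0,
            heart_rate_range=(75, 75),
            ptt_range=(0.22, 0.22),
            pep_range=(0.09, 0.09),
            pir_range=(2.2, 2.2),
            alpha_range=(3.0, 3.0),
            ts_fraction_range=(0.3, 0.3),
            vp_range=(1.0, 1.0),
        )
        dataset, _ = generate_feature_table(config)
        physio = dataset.frame.drop(
            columns=["subject_id", "age_y", "sex", "waist_cm", "weight_kg", "temp_c"]
        )
        assert (physio.nunique() == 1).all()

    def test_pat_sbp_correlation_is_negative(self):
        # the pressure model is decreasing in PTT, and PAT = PTT + PEP
        config = SynthConfig(n_subjects=500, records_per_subject=1, total_records=None, seed=21)
        dataset, _ = generate_feature_table(config)
        r = np.corrcoef(dataset.frame["pat_s"], dataset.frame["sbp_mmhg"])[0, 1]
        assert r < 0

    def test_fixed_seed_reproduces_table(self):
        config = SynthConfig.compromised_cohort(seed=17)
        a, _ = generate_feature_table(config)
        b, _ = generate_feature_table(config)
        assert a.frame.equals(b.frame)

    def test_log_features_make_dbp_exactly_linear(self):
        config = SynthConfig(
            n_subjects=50, records_per_subject=1, total_records=None, noise_sd_bp=0.0, seed=3
        )
        dataset, _ = generate_feature_table(config, include_log_features=True)
        f = dataset.frame
        # DBP = a*(log_pep - log_pir - 2*log_ptt + log_womersley) + b
        pred = (
            config.a_dbp
            * (f["log_pep"] - f["log_pir"] - 2 * f["log_ptt"] + f["log_womersley"])
            + config.b_dbp
        )
        np.testing.assert_allclose(f["dbp_mmhg"], pred, rtol=1e-12)


class TestBeatTemplate:
    def test_shape_length_and_peak_position(self):
        beat = ppg_beat_template(ts=0.3, td=0.7, vp=2.0, fs=100)
        assert len(beat) == 100
        assert beat.max() == pytest.approx(2.0)
        assert int(np.argmax(beat)) == 30

    def test_zero_amplitude_gives_zero_vector(self):
        beat = ppg_beat_template(ts=0.3, td=0.7, vp=0.0, fs=100)
        assert np.all(beat == 0)

    def test_monotone_rise_then_decay(self):
        beat = ppg_beat_template(ts=0.3, td=0.7, vp=1.0, fs=200)
        peak = int(np.argmax(beat))
        assert np.all(np.diff(beat[: peak + 1]) >= 0)
        assert np.all(np.diff(beat[peak:]) < 0)

    def test_roundtrip_ts_from_fiducials(self):
        fs = 100
        beat = ppg_beat_template(ts=0.3, td=0.7, vp=1.0, fs=fs)
        ts_est = (np.argmax(beat) - np.argmin(beat[: np.argmax(beat) + 1])) / fs
        assert ts_est == pytest.approx(0.30, abs=1 / fs)

    @pytest.mark.parametrize("ts,td", [(0, 0.5), (0.5, 0), (-0.1, 0.5)])
    def test_rejects_non_positive_durations(self, ts, td):
        with pytest.raises(ValueError):
            ppg_beat_template(ts=ts, td=td, vp=1.0, fs=100)

    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError):
            ppg_beat_template(ts=0.01, td=0.01, vp=1.0, fs=100)


class TestSynthesizeRecord:
    def _one(self, seed=0, noise=0.0, **cfg):
        config = SynthConfig.compromised_cohort(
            seed=seed, n_subjects=1, total_records=None, records_per_subject=1,
            noise_sd_signal=noise, **cfg
        )
        rng = np.random.default_rng(seed)
        subject = sample_population(config, rng)[0]
        rp = draw_record_params(config, rng)
        return config, subject, rp, rng

    def test_ppg_peak_lags_r_by_exact_pat(self):
        config, subject, _, rng = self._one(fs=400.0)
        rp = RecordParams(
            heart_rate=75, ptt=0.2, pep=0.05, pir=2.2, alpha=3.0, ts_fraction=0.3, vp=1.0
        )
        record, gt = synthesize_record(config, subject, rp, rng)
        assert gt.pat == pytest.approx(0.25)
        from cuffbp.features import build_cycle_set, detect_r_peaks

        r = detect_r_peaks(record.ecg, record.fs)
        cycles = build_cycle_set(record.ppg[0], record.fs, r)
        gaps = cycles.peaks - cycles.r_peaks
        assert np.all(gaps == 100)

    def test_fixed_seed_reproduces_record_bytes(self):
        config = SynthConfig.compromised_cohort(seed=8, n_subjects=2, total_records=None)
        a = generate_records(config)
        b = generate_records(config)
        for (ra, _), (rb, _) in zip(a, b):
            assert np.array_equal(ra.ecg, rb.ecg)
            assert np.array_equal(ra.ppg[0], rb.ppg[0])
            assert np.array_equal(ra.abp, rb.abp)

    def test_abp_swings_exactly_between_dbp_and_sbp(self):
        config, subject, rp, rng = self._one(seed=2)
        record, gt = synthesize_record(config, subject, rp, rng)
        assert record.abp.min() == pytest.approx(gt.dbp)
        assert record.abp.max() == pytest.approx(gt.sbp)

    def test_too_short_duration_rejected(self):
        config, subject, rp, rng = self._one(seed=3, duration=3.0)
        with pytest.raises(ValueError, match="beats"):
            synthesize_record(config, subject, rp, rng)

    def test_dual_ppg_distal_channel_lags_by_configured_delay(self):
        config = SynthConfig.healthy_cohort(seed=5, n_subjects=1, noise_sd_signal=0.0)
        rng = np.random.default_rng(5)
        subject = sample_population(config, rng)[0]
        rp = draw_record_params(config, rng)
        record, _ = synthesize_record(config, subject, rp, rng)
        delay = round(config.fs * config.ptt_channel_delay)
        assert delay == 2
        np.testing.assert_array_equal(record.ppg[1][delay:], record.ppg[0][:-delay])
        assert record.abp is None
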