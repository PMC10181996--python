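"""Fiducial detection and feature extraction against generator ground truth."""

import numpy as np
import pytest

from cuffbp.features import (
    FeatureExtractionError,
    average_reference_bp,
    build_cycle_set,
    compute_morphology,
    compute_pat,
    compute_ptt,
    compute_pulse_rate,
    detect_ppg_fiducials,
    detect_r_peaks,
    extract_record_features,
    select_clean_window,
)
from cuffbp.records import SubjectMeta, WaveformRecord
from cuffbp.synthetic import (
    RecordParams,
    SynthConfig,
    draw_record_params,
    generate_records,
    ppg_beat_template,
    sample_population,
    synthesize_record,
)


def _spike_train(positions, n=2000, height=1.0):
    ecg = np.zeros(n)
    ecg[list(positions)] = height
    return ecg


class TestDetectRPeaks:
    def test_clean_spikes_found_exactly(self):
        ecg = _spike_train([100, 500, 900])
        np.testing.assert_array_equal(detect_r_peaks(ecg, fs=250), [100, 500, 900])

    def test_robust_to_small_noise(self, rng):
        ecg = _spike_train([100, 500, 900]) + rng.normal(0, 0.01, 2000)
        np.testing.assert_array_equal(detect_r_peaks(ecg, fs=250), [100, 500, 900])

    def test_flat_signal_raises(self):
        with pytest.raises(FeatureExtractionError, match="flat"):
            detect_r_peaks(np.zeros(2000), fs=250)

    def test_short_signal_raises(self):
        with pytest.raises(FeatureExtractionError, match="2 s"):
            detect_r_peaks(np.ones(100), fs=250)

    def test_refractory_suppresses_double_detections(self):
        ecg = _spike_train([500, 510, 900])  # 10 samples < 250 ms at 250 Hz
        peaks = detect_r_peaks(ecg, fs=250)
        assert 900 in peaks
        assert len([p for p in peaks if 490 <= p <= 520]) == 1


class TestPpgFiducials:
    def test_template_train_fiducials_match_construction(self):
        fs, ts, td = 100.0, 0.3, 0.7
        beat = ppg_beat_template(ts, td, vp=1.0, fs=fs)
        ppg = np.tile(beat, 10)
        r_peaks = np.arange(10) * 100 + 10  # feet at k*100, peaks at k*100+30
        feet, peaks, kept = detect_ppg_fiducials(ppg, fs, r_peaks)
        assert len(feet) >= 8
        np.testing.assert_array_equal(peaks - feet, round(fs * ts))

    def test_constant_signal_yields_no_pairs(self):
        feet, peaks, kept = detect_ppg_fiducials(np.ones(1000), 100, np.array([100, 300]))
        assert len(feet) == len(peaks) == 0

    def test_small_noise_keeps_fiducials_within_one_sample(self, rng):
        config = SynthConfig.compromised_cohort(
            seed=1, n_subjects=1, total_records=None, records_per_subject=1,
            noise_sd_signal=0.0,
        )
        subject = sample_population(config, rng)[0]
        rp = draw_record_params(config, rng)
        record, gt = synthesize_record(config, subject, rp, rng)
        r = detect_r_peaks(record.ecg, record.fs)
        feet0, peaks0, _ = detect_ppg_fiducials(record.ppg[0], record.fs, r)
        noisy = record.ppg[0] + rng.normal(0, 0.002, len(record.ppg[0]))
        feet1, peaks1, _ = detect_ppg_fiducials(noisy, record.fs, r)
        n = min(len(peaks0), len(peaks1))
        # skip the boundary beat: its foot search has no preceding cycle
        assert np.max(np.abs(peaks1[1:n] - peaks0[1:n])) <= 1
        assert np.max(np.abs(feet1[1:n] - feet0[1:n])) <= 1


class TestWindowSelection:
    def _periodic_cycles(self, n=10, fs=100.0, corrupt=None):
        beat = ppg_beat_template(0.3, 0.7, 1.0, fs)
        ppg = np.tile(beat, n)
        if corrupt is not None:
            # stretch one cycle's amplitude to break the CV criterion
            ppg[corrupt * 100 : corrupt * 100 + 100] *= 3.0
        r_peaks = np.arange(n) * 100 + 10
        return build_cycle_set(ppg, fs, r_peaks)

    def test_periodic_record_selects_first_window(self):
        cycles = self._periodic_cycles()
        assert select_clean_window(cycles) == range(0, 5)

    def test_corrupted_cycle_pushes_window_past_it(self):
        cycles = self._periodic_cycles(corrupt=2)
        window = select_clean_window(cycles)
        # brute-force oracle: first j whose 5-cycle run avoids the bad cycle
        amplitudes = cycles.amplitudes
        oracle = next(
            j
            for j in range(cycles.n_cycles - 4)
            if np.std(amplitudes[j : j + 5]) / np.mean(amplitudes[j : j + 5]) < 0.2
        )
        assert window.start == oracle
        assert 2 not in window

    def test_too_few_cycles_raises(self):
        cycles = self._periodic_cycles(n=5)  # 5 pairs -> only 4 complete cycles
        with pytest.raises(FeatureExtractionError, match="complete cycles"):
            select_clean_window(cycles)


class TestIntervalFeatures:
    def test_pat_exact(self):
        r = np.array([400, 800, 1200, 1600, 2000])
        p = r + 100
        assert compute_pat(r, p, range(0, 5), fs=400) == pytest.approx(0.25)

    def test_pat_mean_oracle(self):
        r = np.array([400, 800, 1200, 1600, 2000])
        p = r + np.array([99, 100, 101, 100, 100])
        assert compute_pat(r, p, range(0, 5), fs=400) == pytest.approx(0.25)

    def test_pat_rejects_reversed_pair(self):
        r = np.array([400, 800, 1200, 1600, 2000])
        p = r + np.array([100, 100, -5, 100, 100])
        with pytest.raises(FeatureExtractionError, match="pat"):
            compute_pat(r, p, range(0, 5), fs=400)

    def test_ptt_small_lags(self):
        prox = np.array([400, 800, 1200, 1600, 2000])
        assert compute_ptt(prox, prox + 2, range(0, 5), fs=400) == pytest.approx(0.005)
        jitter = prox + np.array([1, 2, 3, 2, 2])
        assert compute_ptt(prox, jitter, range(0, 5), fs=400) == pytest.approx(0.005)

    def test_ptt_zero_lag_rejected(self):
        prox = np.array([400, 800, 1200, 1600, 2000])
        with pytest.raises(FeatureExtractionError, match="ptt"):
            compute_ptt(prox, prox, range(0, 5), fs=400)

    @pytest.mark.parametrize(
        "tc,expected", [(1.0, 60.0), (0.5, 120.0)]
    )
    def test_pulse_rate(self, tc, expected):
        assert compute_pulse_rate(np.full(5, tc)) == pytest.approx(expected)

    def test_pulse_rate_mean_oracle(self):
        assert compute_pulse_rate(np.array([1.0, 1.0, 1.0, 0.9, 1.1])) == pytest.approx(60.0)


class TestMorphology:
    def test_triangular_pulse_formula_oracle(self):
        fs = 1000.0
        # triangle: rise 0..0.3 s to 2.0, fall back to 0 at 1.0 s, repeated
        t = np.arange(0, 1, 1 / fs)
        cycle = np.where(t < 0.3, t / 0.3, (1 - t) / 0.7) * 2.0
        ppg = np.tile(cycle, 7)
        feet = np.arange(7) * 1000
        peaks = feet + 300
        m = compute_morphology(ppg, feet, peaks, range(0, 5), fs)
        assert m["ts"] == pytest.approx(0.3)
        assert m["td"] == pytest.approx(0.7)
        assert m["tc"] == pytest.approx(1.0)
        assert m["vp"] == pytest.approx(2.0)
        assert m["vs"] == pytest.approx(0.6)
        assert m["dvs"] == pytest.approx(6.667, abs=1e-3)
        assert m["vd"] == pytest.approx(1.4)
        assert m["dvd"] == pytest.approx(2.857, abs=1e-3)

    def test_symmetric_pulse_splits_volume_evenly(self):
        fs = 1000.0
        t = np.arange(0, 1, 1 / fs)
        cycle = np.where(t < 0.5, t / 0.5, (1 - t) / 0.5) * 3.0
        ppg = np.tile(cycle, 7)
        feet = np.arange(7) * 1000
        peaks = feet + 500
        m = compute_morphology(ppg, feet, peaks, range(0, 5), fs)
        assert m["vs"] == pytest.approx(m["vd"])
        assert m["vs"] == pytest.approx(1.5)

    def test_window_needs_following_foot(self):
        feet = np.arange(5) * 100
        peaks = feet + 30
        with pytest.raises(FeatureExtractionError, match="following"):
            compute_morphology(np.zeros(600), feet, peaks, range(0, 5), 100.0)


class TestReferenceBp:
    def test_constant_cycles(self):
        fs = 100
        cycle = 80 + 40 * np.sin(np.linspace(0, np.pi, 101)[:100])  # hits max exactly
        abp = np.tile(cycle, 7)
        feet = np.arange(7) * 100
        sbp, dbp, map_ = average_reference_bp(abp, feet, range(0, 5))
        assert (sbp, dbp) == (120, 80)
        assert map_ == pytest.approx(93.333, abs=1e-3)

    def test_mean_of_cycle_maxima(self):
        feet = np.arange(6) * 10
        abp = np.zeros(60)
        for i, peak in enumerate([118, 119, 120, 121, 122]):
            abp[i * 10 + 5] = peak
        sbp, _, _ = average_reference_bp(abp, feet, range(0, 5))
        assert sbp == pytest.approx(120.0)

    def test_missing_abp_raises(self):
        with pytest.raises(FeatureExtractionError, match="arterial"):
            average_reference_bp(None, np.arange(6) * 10, range(0, 5))


class TestEndToEnd:
    def test_noiseless_roundtrip_recovers_ground_truth(self):
        config = SynthConfig.compromised_cohort(
            seed=13, n_subjects=4, total_records=None, records_per_subject=2,
            noise_sd_signal=0.0,
        )
        for record, gt in generate_records(config):
            row = extract_record_features(record)
            assert row["pat_s"] == pytest.approx(gt.pat, abs=1 / config.fs)
            assert row["ts_s"] == pytest.approx(gt.ts, abs=2 / config.fs)
            assert row["td_s"] == pytest.approx(gt.td, abs=2 / config.fs)
            assert row["tc_s"] == pytest.approx(gt.tc, abs=2 / config.fs)
            assert row["vp_au"] == pytest.approx(gt.vp, rel=0.01)
            assert row["sbp_mmhg"] == pytest.approx(gt.sbp, abs=1e-6)
            assert row["dbp_mmhg"] == pytest.approx(gt.dbp, abs=1e-6)

    def test_extracted_rows_satisfy_algebraic_identities(self):
        config = SynthConfig.compromised_cohort(
            seed=19, n_subjects=3, total_records=None, records_per_subject=2,
            noise_sd_signal=0.02,
        )
        for record, _ in generate_records(config):
            row = extract_record_features(record)
            assert row["tc_s"] == pytest.approx(row["ts_s"] + row["td_s"], rel=1e-9)
            assert row["vs_au"] + row["vd_au"] == pytest.approx(row["vp_au"], rel=1e-9)

    def test_window_and_features_are_deterministic(self):
        config = SynthConfig.compromised_cohort(
            seed=23, n_subjects=1, total_records=None, records_per_subject=1
        )
        record, _ = generate_records(config)[0]
        assert extract_record_features(record) == extract_record_features(record)

    def test_record_without_abp_yields_features_but_no_labels(self):
        config = SynthConfig.healthy_cohort(seed=3, n_subjects=1, noise_sd_signal=0.0)
        record, gt = generate_records(config)[0]
        row = extract_record_features(record)
        assert row["sbp_mmhg"] is None and row["dbp_mmhg"] is None
        assert row["pat_s"] is not None
        assert row["ptt_s"] == pytest.approx(
            round(config.fs * config.ptt_channel_delay) / config.fs
        )

    def test_single_ppg_record_has_no_ptt(self):
        config = SynthConfig.compromised_cohort(
            seed=29, n_subjects=1, total_records=None, records_per_subject=1
        )
        record, _ = generate_records(config)[0]
        row = extract_record_features(record)
        assert row["ptt_s"] is None
        assert row["pat_s"] > 0


def test_waveform_record_validation():
    meta = SubjectMeta(subject_id="s1", age_y=50, sex=1)
    with pytest.raises(ValueError, match="equal length"):
        WaveformRecord(ecg=np.zeros(10), ppg=[np.zeros(9)], fs=100, meta=meta)
    with pytest.raises(ValueError, match="finite"):
        WaveformRecord(
            ecg=np.full(10, np.nan), ppg=[np.zeros(10)], fs=100, meta=meta
        )
    with pytest.raises(ValueError, match="fs"):
        WaveformRecord(ecg=np.zeros(10), ppg=[np.zeros(10)], fs=0, meta=meta)
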