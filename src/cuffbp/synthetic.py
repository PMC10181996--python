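"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates two acquisition set-ups:

* an ICU-style cohort (chest ECG, one finger PPG, invasive arterial pressure,
  default 125 Hz) yielding up to five measurement windows per subject, and
* a wrist-sensor cohort (two PPG channels 5 mm apart at 400 Hz, no arterial
  line) with the extra demographics waist, weight and temperature.

Per record the generator draws latent transit-time physiology (PTT, PEP, PIR,
Womersley number) and pulse morphology (cycle time from heart rate, systolic
rise fraction, peak amplitude), then produces

* ground-truth labels through the transit-time pressure model in
  :mod:`cuffbp.hemodynamics` plus additive Gaussian label noise, and/or
* raw waveforms: a stylized R-spike train, PPG beat templates delayed by PAT,
  and an arterial channel oscillating exactly between DBP and SBP.

Everything is driven by one ``numpy`` Generator so a fixed seed reproduces
records byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FeatureDataset
from .hemodynamics import HemoParams, bp_triple_from_params, womersley_factor
from .records import SubjectMeta, WaveformRecord

__all__ = [
    "SynthConfig",
    "SubjectParams",
    "RecordParams",
    "GroundTruth",
    "sample_population",
    "draw_record_params",
    "generate_feature_table",
    "ppg_beat_template",
    "synthesize_record",
    "generate_records",
]

Range = tuple[float, float]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the ICU-style cohort: 31 subjects contributing 126
    measurement windows in total, pressures spanning roughly SBP 90–180 and
    DBP 60–100 mmHg, and 2 mmHg of measurement noise on the reference labels.
    """

    n_subjects: int = 31
    records_per_subject: int = 4
    total_records: int | None = 126  # overrides records_per_subject when set
    fs: float = 125.0
    duration: float = 10.0
    heart_rate_range: Range = (60.0, 100.0)
    ptt_range: Range = (0.18, 0.28)
    pep_range: Range = (0.07, 0.11)  # PAT = PTT + PEP
    pir_range: Range = (1.8, 2.6)
    alpha_range: Range = (2.5, 3.5)
    k_pp: float = 32.0
    a_dbp: float = 20.0
    b_dbp: float = 78.0
    ts_fraction_range: Range = (0.25, 0.35)  # systolic rise as fraction of Tc
    vp_range: Range = (0.8, 1.5)  # PPG peak amplitude, a.u.
    noise_sd_signal: float = 0.02  # a.u., all waveform channels
    noise_sd_bp: float = 2.0  # mmHg, on each label
    p_male: float = 0.6
    age_range: Range = (35.0, 85.0)
    waist_range: Range = (70.0, 110.0)
    weight_range: Range = (55.0, 100.0)
    temp_range: Range = (36.0, 37.5)
    dual_ppg: bool = False
    ptt_channel_delay: float = 0.005  # s between proximal and distal PPG
    cohort: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "heart_rate_range",
            "ptt_range",
            "pep_range",
            "pir_range",
            "alpha_range",
            "ts_fraction_range",
            "vp_range",
            "age_range",
            "waist_range",
            "weight_range",
            "temp_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive non-empty range, got {(lo, hi)}")
        lo, hi = self.ts_fraction_range
        if not (0 < lo and hi < 1):
            raise ValueError("ts_fraction_range must lie strictly inside (0, 1)")
        if not 0 <= self.p_male <= 1:
            raise ValueError(f"p_male must be a probability, got {self.p_male}")
        if self.records_per_subject < 1 or self.records_per_subject > 5:
            raise ValueError("records_per_subject must be in 1..5")

    @classmethod
    def compromised_cohort(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """ICU-style conditions: 31 subjects, 126 windows, ECG+PPG+ABP at 125 Hz."""
        return cls(cohort="compromised", seed=seed, **overrides)

    @classmethod
    def healthy_cohort(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """Wrist-sensor conditions: 23 subjects, one window each, dual PPG at 400 Hz."""
        defaults = dict(
            n_subjects=23,
            records_per_subject=1,
            total_records=None,
            fs=400.0,
            dual_ppg=True,
            p_male=0.52,
            age_range=(25.0, 60.0),
            cohort="healthy",
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str
    age_y: float
    sex: int
    waist_cm: float
    weight_kg: float
    temp_c: float
    n_records: int


@dataclass(frozen=True)
class RecordParams:
    """Latent per-record physiology and morphology."""

    heart_rate: float
    ptt: float
    pep: float
    pir: float
    alpha: float
    ts_fraction: float
    vp: float

    @property
    def pat(self) -> float:
        return self.ptt + self.pep


@dataclass(frozen=True)
class GroundTruth:
    """The generator's latent state for one record, for recovery tests."""

    subject_id: str
    pat: float
    ptt: float
    pep: float
    pir: float
    alpha: float
    tc: float
    ts: float
    td: float
    vp: float
    heart_rate: float
    sbp: float
    dbp: float
    map: float

    def __post_init__(self) -> None:
        expected_map = (2.0 * self.dbp + self.sbp) / 3.0
        if not math.isclose(self.map, expected_map, rel_tol=0, abs_tol=1e-9):
            raise ValueError("ground-truth MAP must equal (2*DBP + SBP)/3 exactly")
        if not self.sbp > self.dbp:
            raise ValueError("ground truth requires SBP > DBP")


def _uniform(rng: np.random.Generator, rng_pair: Range) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def _records_per_subject(config: SynthConfig) -> list[int]:
    """Distribute the total record count over subjects (5-record cap)."""
    n = config.n_subjects
    if config.total_records is None:
        return [config.records_per_subject] * n
    total = config.total_records
    base, extra = divmod(total, n)
    if base > 5 or (base == 5 and extra):
        raise ValueError(
            f"cannot place {total} records on {n} subjects with <= 5 records each"
        )
    return [base + 1 if i < extra else base for i in range(n)]


def sample_population(config: SynthConfig, rng: np.random.Generator) -> list[SubjectParams]:
    """Draw demographics for every subject in the cohort."""
    counts = _records_per_subject(config) if config.n_subjects else []
    subjects = []
    for i in range(config.n_subjects):
        subjects.append(
            SubjectParams(
                subject_id=f"{config.cohort}-{i + 1:03d}",
                age_y=round(_uniform(rng, config.age_range), 1),
                sex=int(rng.random() < config.p_male),
                waist_cm=round(_uniform(rng, config.waist_range), 1),
                weight_kg=round(_uniform(rng, config.weight_range), 1),
                temp_c=round(_uniform(rng, config.temp_range), 2),
                n_records=counts[i],
            )
        )
    return subjects


def draw_record_params(config: SynthConfig, rng: np.random.Generator) -> RecordParams:
    return RecordParams(
        heart_rate=_uniform(rng, config.heart_rate_range),
        ptt=_uniform(rng, config.ptt_range),
        pep=_uniform(rng, config.pep_range),
        pir=_uniform(rng, config.pir_range),
        alpha=_uniform(rng, config.alpha_range),
        ts_fraction=_uniform(rng, config.ts_fraction_range),
        vp=_uniform(rng, config.vp_range),
    )


def _hemo_params(config: SynthConfig, rp: RecordParams) -> HemoParams:
    return HemoParams(
        pep=rp.pep,
        pir=rp.pir,
        ptt=rp.ptt,
        alpha=rp.alpha,
        k_pp=config.k_pp,
        a_dbp=config.a_dbp,
        b_dbp=config.b_dbp,
    )


def _ground_truth(
    config: SynthConfig, subject: SubjectParams, rp: RecordParams
) -> GroundTruth:
    bp = bp_triple_from_params(_hemo_params(config, rp))
    tc = 60.0 / rp.heart_rate
    ts = rp.ts_fraction * tc
    return GroundTruth(
        subject_id=subject.subject_id,
        pat=rp.pat,
        ptt=rp.ptt,
        pep=rp.pep,
        pir=rp.pir,
        alpha=rp.alpha,
        tc=tc,
        ts=ts,
        td=tc - ts,
        vp=rp.vp,
        heart_rate=rp.heart_rate,
        sbp=bp.sbp,
        dbp=bp.dbp,
        map=bp.map,
    )


def generate_feature_table(
    config: SynthConfig, include_log_features: bool = False
) -> tuple[FeatureDataset, pd.DataFrame]:
    """One feature row per record, labels generated through the pressure model.

    Labels are the model-implied SBP/DBP/MAP each perturbed by independent
    Gaussian noise of SD ``noise_sd_bp`` (zero noise keeps the exact
    ``MAP = (2*DBP + SBP)/3`` identity row-wise).  The returned ground-truth
    frame carries every latent draw; with ``include_log_features`` the feature
    table additionally gets the log-transformed driving-term components
    (``log_pep``, ``log_pir``, ``log_ptt``, ``log_womersley``) in which the
    DBP relation is exactly linear, enabling parameter-recovery tests.
    """
    # separate parameter and noise streams: the k-th record's physiology is
    # then identical between the feature-table and waveform-record paths
    rng = np.random.default_rng([config.seed, 0])
    noise_rng = np.random.default_rng([config.seed, 1])
    subjects = sample_population(config, rng)
    rows, truths = [], []
    for subject in subjects:
        for _ in range(subject.n_records):
            rp = draw_record_params(config, rng)
            gt = _ground_truth(config, subject, rp)
            noise = noise_rng.normal(0.0, config.noise_sd_bp, size=3) if config.noise_sd_bp > 0 else np.zeros(3)
            row = {
                "pat_s": gt.pat,
                "ptt_s": gt.ptt,
                "pulse_rate_bpm": gt.heart_rate,
                "tc_s": gt.tc,
                "ts_s": gt.ts,
                "td_s": gt.td,
                "vp_au": gt.vp,
                "vs_au": gt.vp * gt.ts / gt.tc,
                "dvs_au_per_s": gt.vp / gt.ts,
                "vd_au": gt.vp * gt.td / gt.tc,
                "dvd_au_per_s": gt.vp / gt.td,
                "age_y": subject.age_y,
                "sex": subject.sex,
                "waist_cm": subject.waist_cm,
                "weight_kg": subject.weight_kg,
                "temp_c": subject.temp_c,
                "sbp_mmhg": gt.sbp + noise[0],
                "dbp_mmhg": gt.dbp + noise[1],
                "map_mmhg": gt.map + noise[2],
                "subject_id": subject.subject_id,
                "cohort": config.cohort,
            }
            if include_log_features:
                row["log_pep"] = math.log(gt.pep)
                row["log_pir"] = math.log(gt.pir)
                row["log_ptt"] = math.log(gt.ptt)
                row["log_womersley"] = math.log(womersley_factor(gt.alpha))
            rows.append(row)
            truths.append(gt.__dict__ | {"cohort": config.cohort})
    frame = pd.DataFrame(rows)
    truth = pd.DataFrame(truths)
    return FeatureDataset(frame=frame, cohort=config.cohort), truth


def ppg_beat_template(ts: float, td: float, vp: float, fs: float) -> np.ndarray:
    """One PPG pulse: cosine rise 0 -> ``vp`` over ``ts``, exponential decay over ``td``.

    Length is ``round(fs*(ts+td))`` samples with the maximum at ``round(fs*ts)``.
    The decay time constant is ``td/5`` so the pulse returns to < 1 % of ``vp``
    by the next beat's foot.
    """
    if ts <= 0 or td <= 0:
        raise ValueError(f"ts and td must be positive, got ts={ts}, td={td}")
    n = round(fs * (ts + td))
    if n < 4:
        raise ValueError(f"fs*(ts+td) must cover >= 4 samples, got {n}")
    i_peak = round(fs * ts)
    i_peak = min(max(i_peak, 1), n - 1)
    out = np.empty(n)
    idx = np.arange(i_peak + 1)
    out[: i_peak + 1] = vp * 0.5 * (1.0 - np.cos(np.pi * idx / i_peak))
    tau = td / 5.0
    t_decay = (np.arange(i_peak + 1, n) - i_peak) / fs
    out[i_peak + 1 :] = vp * np.exp(-t_decay / tau)
    return out


def synthesize_record(
    config: SynthConfig,
    subject: SubjectParams,
    rp: RecordParams,
    rng: np.random.Generator,
) -> tuple[WaveformRecord, GroundTruth]:
    """Render one record's waveforms from its latent parameters.

    The R-spike train is periodic at the record's RR interval; each PPG beat
    peak lands exactly PAT after its R spike; the arterial channel repeats the
    beat shape scaled to swing exactly between DBP and SBP.  Beat timing is
    quantized to the sample grid, and the realized (grid-quantized) values are
    what the returned ground truth reports.
    """
    fs = config.fs
    n_total = round(config.duration * fs)
    rr_samp = round(fs * 60.0 / rp.heart_rate)
    tc = rr_samp / fs
    ts_samp = max(round(fs * rp.ts_fraction * tc), 1)
    td_samp = rr_samp - ts_samp
    pat_samp = round(fs * rp.pat)
    # first foot placed so every fiducial (incl. feet preceding R) is in range
    first_r = max(ts_samp - pat_samp, 0) + round(0.2 * fs)
    n_beats = (n_total - first_r - pat_samp) // rr_samp
    if n_beats < 7:
        raise ValueError(
            f"duration {config.duration} s covers only {n_beats} beats; need >= 7 "
            "for a clean five-cycle window"
        )
    r_peaks = first_r + rr_samp * np.arange(n_beats)

    ecg = np.zeros(n_total)
    ecg[r_peaks] = 1.0
    for shoulder in (r_peaks - 1, r_peaks + 1):
        valid = (shoulder >= 0) & (shoulder < n_total)
        ecg[shoulder[valid]] = 0.5

    template = ppg_beat_template(ts_samp / fs, td_samp / fs, rp.vp, fs)
    ppg = np.zeros(n_total)
    abp_shape = template / rp.vp  # 0 at foot, 1 at peak
    bp = _ground_truth(config, subject, rp)  # labels depend only on hemo params
    # realized (sample-grid) timing for the ground truth
    gt = GroundTruth(
        subject_id=subject.subject_id,
        pat=pat_samp / fs,
        ptt=rp.ptt,
        pep=pat_samp / fs - rp.ptt,
        pir=rp.pir,
        alpha=rp.alpha,
        tc=tc,
        ts=ts_samp / fs,
        td=td_samp / fs,
        vp=rp.vp,
        heart_rate=60.0 / tc,
        sbp=bp.sbp,
        dbp=bp.dbp,
        map=bp.map,
    )
    pp = gt.sbp - gt.dbp
    abp = np.full(n_total, gt.dbp)
    for r in r_peaks:
        foot = r + pat_samp - ts_samp
        stop = min(foot + len(template), n_total)
        if foot < 0 or stop <= foot:
            continue
        seg = slice(foot, stop)
        ppg[seg] += template[: stop - foot]
        abp[seg] = gt.dbp + pp * abp_shape[: stop - foot]

    channels = {"ecg": ecg, "ppg": [ppg], "abp": abp}
    if config.dual_ppg:
        delay = round(fs * config.ptt_channel_delay)
        distal = np.zeros(n_total)
        distal[delay:] = ppg[: n_total - delay] if delay else ppg
        channels["ppg"] = [ppg, distal]
        channels["abp"] = None  # wrist set-up has no arterial line
    if config.noise_sd_signal > 0:
        channels["ecg"] = ecg + rng.normal(0, config.noise_sd_signal, n_total)
        channels["ppg"] = [
            p + rng.normal(0, config.noise_sd_signal, n_total) for p in channels["ppg"]
        ]
        if channels["abp"] is not None:
            channels["abp"] = channels["abp"] + rng.normal(
                0, config.noise_sd_signal, n_total
            )

    meta = SubjectMeta(
        subject_id=subject.subject_id,
        age_y=subject.age_y,
        sex=subject.sex,
        cohort=config.cohort,
        waist_cm=subject.waist_cm,
        weight_kg=subject.weight_kg,
        temp_c=subject.temp_c,
    )
    record = WaveformRecord(
        ecg=channels["ecg"], ppg=channels["ppg"], abp=channels["abp"], fs=fs, meta=meta
    )
    return record, gt


def generate_records(config: SynthConfig) -> list[tuple[WaveformRecord, GroundTruth]]:
    """All cohort records, deterministically from ``config.seed``.

    Draws the same population and per-record physiology as
    :func:`generate_feature_table` under the same config and seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    noise_rng = np.random.default_rng([config.seed, 1])
    out = []
    for subject in sample_population(config, rng):
        for _ in range(subject.n_records):
            rp = draw_record_params(config, rng)
            out.append(synthesize_record(config, subject, rp, noise_rng))
    return out
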