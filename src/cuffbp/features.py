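"""Fiducial detection and pulse-wave feature extraction.

The pipeline mirrors how pulse-wave analysis is done on monitor data: find
ECG R peaks, locate each beat's PPG foot (the pre-upstroke minimum) and
systolic peak, pick the first artefact-free run of five consecutive cycles,
then average the temporal features (PAT, pulse rate, and PTT when two PPG
channels exist), the eight morphology features, and — when an arterial
channel is present — the per-cycle pressure extrema that form the reference
SBP/DBP/MAP labels.

Index convention: 0-based sample positions everywhere; seconds only appear
after division by the sampling rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .hemodynamics import map_from_sbp_dbp
from .records import WaveformRecord

__all__ = [
    "FeatureExtractionError",
    "CycleSet",
    "PulseFeatures",
    "detect_r_peaks",
    "detect_ppg_fiducials",
    "build_cycle_set",
    "select_clean_window",
    "compute_pat",
    "compute_ptt",
    "compute_morphology",
    "compute_pulse_rate",
    "average_reference_bp",
    "extract_record_features",
]

logger = logging.getLogger(__name__)

#: R-wave refractory period in seconds (no two detections closer than this).
R_REFRACTORY_S = 0.25
#: Adaptive R threshold as a fraction of the robust spike height.
R_THRESHOLD_FRACTION = 0.5
#: Window-selection artefact thresholds: cycle-length CV and amplitude CV.
MAX_CYCLE_LENGTH_CV = 0.10
MAX_AMPLITUDE_CV = 0.20


class FeatureExtractionError(RuntimeError):
    """Raised when a pipeline stage cannot produce its output."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class CycleSet:
    """Aligned fiducials: one (R, foot, peak) triple per resolved cardiac cycle."""

    r_peaks: np.ndarray
    feet: np.ndarray
    peaks: np.ndarray
    amplitudes: np.ndarray  # foot-to-peak PPG amplitude per cycle
    window: range | None = None

    def __post_init__(self) -> None:
        for name in ("r_peaks", "feet", "peaks"):
            arr = getattr(self, name)
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not (len(self.r_peaks) == len(self.feet) == len(self.peaks)):
            raise ValueError("r_peaks, feet and peaks must align one-to-one")
        if np.any(self.feet >= self.peaks):
            raise ValueError("each foot must precede its peak")

    @property
    def n_cycles(self) -> int:
        """Complete cycles (a cycle ends at the next cycle's foot)."""
        return max(len(self.feet) - 1, 0)


@dataclass(frozen=True)
class PulseFeatures:
    """The per-window averaged pulse features (times s, volumes a.u.)."""

    pat: float | None
    ptt: float | None
    pulse_rate: float
    tc: float
    ts: float
    td: float
    vp: float
    vs: float
    dvs: float
    vd: float
    dvd: float

    def __post_init__(self) -> None:
        for name in ("pulse_rate", "tc", "ts", "td", "vp", "vs", "dvs", "vd", "dvd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isclose(self.tc, self.ts + self.td, rtol=1e-9, atol=1e-12):
            raise ValueError("tc must equal ts + td")
        if not np.isclose(self.vs + self.vd, self.vp, rtol=1e-9, atol=1e-12):
            raise ValueError("vs + vd must equal vp")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-spike indices: local maxima above an adaptive threshold.

    The threshold is half the robust spike height (median of the largest
    plausible-beat-count samples, so a single artefact cannot inflate it);
    detections are separated by at least the 250 ms refractory period.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise FeatureExtractionError("r_peaks", "need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        raise FeatureExtractionError("r_peaks", "flat ECG signal")
    # robust spike height: median of the top-k samples, k = beats at 40 bpm
    k = max(3, int(len(ecg) / fs * 40.0 / 60.0))
    top = np.sort(ecg)[-k:]
    robust_max = float(np.median(top))
    if robust_max <= 0:
        raise FeatureExtractionError("r_peaks", "no positive spike amplitude")
    peaks, _ = find_peaks(
        ecg,
        height=R_THRESHOLD_FRACTION * robust_max,
        distance=max(int(R_REFRACTORY_S * fs), 1),
    )
    if len(peaks) == 0:
        raise FeatureExtractionError("r_peaks", "no R peaks above threshold")
    return peaks


def detect_ppg_fiducials(
    ppg: np.ndarray, fs: float, r_peaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per cardiac cycle, the PPG foot and systolic peak.

    For each R peak the systolic peak is the PPG maximum within the following
    beat interval, and the foot the latest minimum in the preceding
    0.6-beat span (the foot may precede the R peak itself when pulse arrival
    is faster than the systolic rise).  Unresolvable cycles are dropped with
    a logged count.

    Returns ``(feet, peaks, r_kept)`` aligned one-to-one.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(r_peaks) == 0:
        raise FeatureExtractionError("ppg_fiducials", "no R peaks supplied")
    if np.ptp(ppg) == 0:
        logger.warning("constant PPG signal: no fiducials resolvable")
        return np.array([], int), np.array([], int), np.array([], int)
    rr = float(np.median(np.diff(r_peaks))) if len(r_peaks) > 1 else 0.8 * fs
    search = max(int(0.9 * rr), 2)
    back = max(int(0.6 * rr), 2)
    feet, peaks, kept = [], [], []
    dropped = 0
    for r in np.asarray(r_peaks, int):
        lo, hi = r + 1, min(r + search, len(ppg))
        if hi - lo < 3:
            dropped += 1
            continue
        peak = lo + int(np.argmax(ppg[lo:hi]))
        if peak in (lo, hi - 1):  # maximum on the window edge: unresolved
            dropped += 1
            continue
        # never search the foot before the previous systolic peak
        flo = max(peak - back, peaks[-1] + 1 if peaks else 0, 0)
        seg = ppg[flo:peak]
        if len(seg) == 0:
            dropped += 1
            continue
        # latest occurrence of the minimum = the point closest to the upstroke
        foot = flo + (len(seg) - 1 - int(np.argmin(seg[::-1])))
        if foot >= peak or ppg[peak] <= ppg[foot]:
            dropped += 1
            continue
        if feet and foot <= feet[-1]:
            dropped += 1
            continue
        feet.append(foot)
        peaks.append(peak)
        kept.append(r)
    if dropped:
        logger.warning("dropped %d unresolvable cycles", dropped)
    return np.asarray(feet, int), np.asarray(peaks, int), np.asarray(kept, int)


def build_cycle_set(ppg: np.ndarray, fs: float, r_peaks: np.ndarray) -> CycleSet:
    feet, peaks, kept = detect_ppg_fiducials(ppg, fs, r_peaks)
    if len(feet) == 0:
        raise FeatureExtractionError("ppg_fiducials", "no resolvable cycles")
    amplitudes = np.asarray(ppg, float)[peaks] - np.asarray(ppg, float)[feet]
    return CycleSet(r_peaks=kept, feet=feet, peaks=peaks, amplitudes=amplitudes)


def select_clean_window(
    cycles: CycleSet,
    k: int = 5,
    max_length_cv: float = MAX_CYCLE_LENGTH_CV,
    max_amplitude_cv: float = MAX_AMPLITUDE_CV,
) -> range:
    """First run of ``k`` consecutive cycles that looks artefact-free.

    A run qualifies when the coefficient of variation of its cycle lengths is
    below ``max_length_cv`` and of its pulse amplitudes below
    ``max_amplitude_cv``.  Cycle length is measured R-to-R: the R spike is a
    sharp landmark, whereas the PPG foot sits on the flat diastolic tail and
    jitters under noise.  Deterministic: the scan is left to right.
    """
    n = cycles.n_cycles
    if n < k:
        raise FeatureExtractionError(
            "window", f"need >= {k} complete cycles, have {n}"
        )
    lengths = np.diff(cycles.r_peaks).astype(float)
    diagnostics = []
    for j in range(n - k + 1):
        run_len = lengths[j : j + k]
        run_amp = cycles.amplitudes[j : j + k]
        cv_len = run_len.std() / run_len.mean()
        cv_amp = run_amp.std() / run_amp.mean() if run_amp.mean() > 0 else np.inf
        if cv_len < max_length_cv and cv_amp < max_amplitude_cv:
            return range(j, j + k)
        diagnostics.append(f"run {j}: length CV {cv_len:.3f}, amplitude CV {cv_amp:.3f}")
    raise FeatureExtractionError(
        "window", "no artefact-free run of %d cycles; " % k + "; ".join(diagnostics)
    )


def _mean_interval(
    ref: np.ndarray, arrival: np.ndarray, window: range, fs: float, stage: str
) -> float:
    gaps = (np.asarray(arrival)[list(window)] - np.asarray(ref)[list(window)]) / fs
    if np.any(gaps <= 0):
        raise FeatureExtractionError(
            stage, f"non-positive interval in window (mis-paired fiducials): {gaps}"
        )
    return float(np.mean(gaps))


def compute_pat(
    r_peaks: np.ndarray, ppg_peaks: np.ndarray, window: range, fs: float
) -> float:
    """Pulse arrival time: mean R-peak -> PPG-peak delay over the window."""
    return _mean_interval(r_peaks, ppg_peaks, window, fs, "pat")


def compute_ptt(
    prox_peaks: np.ndarray, dist_peaks: np.ndarray, window: range, fs: float
) -> float:
    """Pulse transit time between two PPG sites, mean peak-to-peak delay."""
    return _mean_interval(prox_peaks, dist_peaks, window, fs, "ptt")


def compute_morphology(
    ppg: np.ndarray, feet: np.ndarray, peaks: np.ndarray, window: range, fs: float
) -> dict[str, float]:
    """The eight morphology features averaged over the window's cycles.

    Per cycle: Ts = foot->peak time, Td = peak->next-foot time, Tc = Ts + Td,
    Vp = foot-to-peak amplitude, then the four volume features
    Vs = Vp*Ts/Tc, dVs = Vp/Ts, Vd = Vp*Td/Tc, dVd = Vp/Td.
    """
    ppg = np.asarray(ppg, float)
    if window.stop > len(feet) - 1:
        raise FeatureExtractionError(
            "morphology", "window requires the foot of the following cycle"
        )
    per_cycle = {key: [] for key in ("tc", "ts", "td", "vp", "vs", "dvs", "vd", "dvd")}
    for i in window:
        ts = (peaks[i] - feet[i]) / fs
        td = (feet[i + 1] - peaks[i]) / fs
        vp = ppg[peaks[i]] - ppg[feet[i]]
        if ts <= 0 or td <= 0 or vp <= 0:
            raise FeatureExtractionError(
                "morphology", f"cycle {i}: non-positive ts={ts}, td={td} or vp={vp}"
            )
        tc = ts + td
        per_cycle["tc"].append(tc)
        per_cycle["ts"].append(ts)
        per_cycle["td"].append(td)
        per_cycle["vp"].append(vp)
        per_cycle["vs"].append(vp * ts / tc)
        per_cycle["dvs"].append(vp / ts)
        per_cycle["vd"].append(vp * td / tc)
        per_cycle["dvd"].append(vp / td)
    return {key: float(np.mean(vals)) for key, vals in per_cycle.items()}


def compute_pulse_rate(cycle_times: np.ndarray) -> float:
    """Pulse rate in bpm from the window's cycle times: 60 / mean(Tc)."""
    cycle_times = np.asarray(cycle_times, float)
    if np.any(cycle_times <= 0):
        raise FeatureExtractionError("pulse_rate", "non-positive cycle time")
    return 60.0 / float(np.mean(cycle_times))


def average_reference_bp(
    abp: np.ndarray | None, feet: np.ndarray, window: range
) -> tuple[float, float, float]:
    """Reference SBP/DBP/MAP from the arterial channel over the window.

    SBP is the mean of the cycle maxima, DBP the mean of the cycle minima,
    MAP the weighted (2*DBP + SBP)/3 of the two.
    """
    if abp is None:
        raise FeatureExtractionError("reference_bp", "record has no arterial channel")
    abp = np.asarray(abp, float)
    maxima, minima = [], []
    for i in window:
        seg = abp[feet[i] : feet[i + 1]]
        if len(seg) == 0:
            raise FeatureExtractionError("reference_bp", f"empty cycle segment {i}")
        maxima.append(seg.max())
        minima.append(seg.min())
    sbp, dbp = float(np.mean(maxima)), float(np.mean(minima))
    return sbp, dbp, map_from_sbp_dbp(sbp, dbp)


def extract_record_features(record: WaveformRecord) -> dict[str, float | str | None]:
    """Run the full extraction pipeline on one record.

    Returns a feature-table row (schema of :mod:`cuffbp.datasets`): temporal
    and morphology features plus demographics always; PTT only when a second
    PPG channel exists; labels only when the arterial channel exists (missing
    entries are ``None``).
    """
    r_peaks = detect_r_peaks(record.ecg, record.fs)
    cycles = build_cycle_set(record.ppg[0], record.fs, r_peaks)
    window = select_clean_window(cycles)
    cycles.window = window

    pat = compute_pat(cycles.r_peaks, cycles.peaks, window, record.fs)
    morph = compute_morphology(
        record.ppg[0], cycles.feet, cycles.peaks, window, record.fs
    )
    pulse_rate = compute_pulse_rate(
        np.diff(cycles.feet)[list(window)] / record.fs
    )

    ptt = None
    if len(record.ppg) == 2:
        _, dist_peaks, dist_kept = detect_ppg_fiducials(
            record.ppg[1], record.fs, cycles.r_peaks
        )
        if len(dist_peaks) < window.stop:
            raise FeatureExtractionError(
                "ptt", "distal PPG cycles unresolved inside the selected window"
            )
        ptt = compute_ptt(cycles.peaks, dist_peaks, window, record.fs)

    sbp = dbp = map_ = None
    if record.abp is not None:
        sbp, dbp, map_ = average_reference_bp(record.abp, cycles.feet, window)

    meta = record.meta
    return {
        "pat_s": pat,
        "ptt_s": ptt,
        "pulse_rate_bpm": pulse_rate,
        "tc_s": morph["tc"],
        "ts_s": morph["ts"],
        "td_s": morph["td"],
        "vp_au": morph["vp"],
        "vs_au": morph["vs"],
        "dvs_au_per_s": morph["dvs"],
        "vd_au": morph["vd"],
        "dvd_au_per_s": morph["dvd"],
        "age_y": meta.age_y,
        "sex": meta.sex,
        "waist_cm": meta.waist_cm,
        "weight_kg": meta.weight_kg,
        "temp_c": meta.temp_c,
        "sbp_mmhg": sbp,
        "dbp_mmhg": dbp,
        "map_mmhg": map_,
        "subject_id": meta.subject_id,
        "cohort": meta.cohort,
    }
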