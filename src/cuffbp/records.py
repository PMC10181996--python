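"""In-memory and on-disk container for synchronized ECG/PPG/ABP recordings."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubjectMeta", "WaveformRecord", "save_record", "load_record"]


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics attached to a recording; wrist-cohort extras optional."""

    subject_id: str
    age_y: float
    sex: int  # 0 = female, 1 = male
    cohort: str = "synthetic"
    waist_cm: float | None = None
    weight_kg: float | None = None
    temp_c: float | None = None


@dataclass
class WaveformRecord:
    """Equal-length sample channels at a common sampling rate.

    ``ppg`` holds one channel (finger-sensor style) or two (proximal and
    distal wrist sensors, for transit-time extraction).  ``abp`` is the
    invasive arterial pressure reference in mmHg, absent for cuff-referenced
    recordings.
    """

    ecg: np.ndarray
    ppg: list[np.ndarray]
    fs: float
    meta: SubjectMeta
    abp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 1 <= len(self.ppg) <= 2:
            raise ValueError(f"expected 1 or 2 PPG channels, got {len(self.ppg)}")
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = [np.asarray(p, dtype=float) for p in self.ppg]
        if self.abp is not None:
            self.abp = np.asarray(self.abp, dtype=float)
        n = len(self.ecg)
        channels = [self.ecg, *self.ppg] + ([self.abp] if self.abp is not None else [])
        if any(len(ch) != n for ch in channels):
            raise ValueError("all channels must have equal length")
        if any(not np.all(np.isfinite(ch)) for ch in channels):
            raise ValueError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def save_record(record: WaveformRecord, directory: str | Path, name: str) -> Path:
    """Persist a record as ``<name>.csv`` (channels) + ``<name>.meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = {"ecg": record.ecg}
    for i, p in enumerate(record.ppg, start=1):
        columns[f"ppg{i}"] = p
    if record.abp is not None:
        columns["abp"] = record.abp
    pd.DataFrame(columns).to_csv(directory / f"{name}.csv", index=False)
    meta = {"fs": record.fs, "meta": asdict(record.meta)}
    (directory / f"{name}.meta.json").write_text(json.dumps(meta, indent=1))
    return directory / f"{name}.csv"


def load_record(csv_path: str | Path) -> WaveformRecord:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix("").with_suffix(".meta.json")
    if not meta_path.exists():  # <name>.meta.json next to <name>.csv
        meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
    info = json.loads(meta_path.read_text())
    ppg = [frame[c].to_numpy() for c in frame.columns if c.startswith("ppg")]
    return WaveformRecord(
        ecg=frame["ecg"].to_numpy(),
        ppg=ppg,
        abp=frame["abp"].to_numpy() if "abp" in frame else None,
        fs=float(info["fs"]),
        meta=SubjectMeta(**info["meta"]),
    )
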