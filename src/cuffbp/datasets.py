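"""Feature-table schema, persistence and feature-set views.

A feature table has one row per averaged five-cycle measurement window.  The
compromised-cohort protocol yields up to five rows per subject (126 rows for
31 subjects); the healthy-cohort protocol yields one row per subject.

Column names are the on-disk contract: times in seconds, pulse rate in bpm,
PPG volumes in arbitrary units (a.u.), pressures in mmHg, sex coded 0/1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "FEATURE_COLUMNS",
    "LABEL_COLUMNS",
    "META_COLUMNS",
    "SCHEMA_COLUMNS",
    "FEATURE_SETS",
    "TARGETS",
    "FeatureDataset",
    "select_feature_set",
    "save_table",
    "load_table",
    "load_reference_summaries",
]

MORPHOLOGY_COLUMNS = [
    "tc_s",
    "ts_s",
    "td_s",
    "vp_au",
    "vs_au",
    "dvs_au_per_s",
    "vd_au",
    "dvd_au_per_s",
]

FEATURE_COLUMNS = [
    "pat_s",
    "ptt_s",
    "pulse_rate_bpm",
    *MORPHOLOGY_COLUMNS,
    "age_y",
    "sex",
    "waist_cm",
    "weight_kg",
    "temp_c",
]

LABEL_COLUMNS = {"sbp": "sbp_mmhg", "dbp": "dbp_mmhg", "map": "map_mmhg"}
META_COLUMNS = ["subject_id", "cohort"]
SCHEMA_COLUMNS = FEATURE_COLUMNS + list(LABEL_COLUMNS.values()) + META_COLUMNS

TARGETS = ("sbp", "dbp", "map")

#: The model-input views.  ``combined`` is the 12-feature compromised-cohort
#: set (2 temporal + 2 demographic + 8 morphology); ``pat`` and ``morphology``
#: are its temporal-only and morphology-only restrictions, each keeping the
#: demographics so it is a self-contained predictor set; ``healthy7`` is the
#: 7-feature wrist-sensor set (PTT + pulse rate + 5 demographics).
FEATURE_SETS: dict[str, list[str]] = {
    "combined": ["pat_s", "pulse_rate_bpm", "age_y", "sex", *MORPHOLOGY_COLUMNS],
    "pat": ["pat_s", "pulse_rate_bpm", "age_y", "sex"],
    "morphology": [*MORPHOLOGY_COLUMNS, "age_y", "sex"],
    "healthy7": [
        "ptt_s",
        "pulse_rate_bpm",
        "waist_cm",
        "weight_kg",
        "sex",
        "temp_c",
        "age_y",
    ],
}


@dataclass
class FeatureDataset:
    """A validated feature table plus its cohort tag.

    ``frame`` must carry every schema column; extra columns are preserved.
    """

    frame: pd.DataFrame
    cohort: str = "synthetic"
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing schema columns: {missing}")
        self.extra_columns = [
            c for c in self.frame.columns if c not in SCHEMA_COLUMNS
        ]

    def __len__(self) -> int:
        return len(self.frame)

    def labels(self, target: str) -> pd.Series:
        if target not in LABEL_COLUMNS:
            raise KeyError(f"unknown target {target!r}; expected one of {TARGETS}")
        return self.frame[LABEL_COLUMNS[target]]


def select_feature_set(dataset: FeatureDataset, set_id: str, target: str = "sbp"):
    """Return ``(X, y)`` for one feature-set view.

    ``X`` is a column-ordered DataFrame restricted to the view's features and
    ``y`` the label series for ``target``.  A view with any missing value in
    its columns is rejected: each declared set must be complete.
    """
    if set_id not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {set_id!r}; known: {sorted(FEATURE_SETS)}")
    columns = FEATURE_SETS[set_id]
    missing = [c for c in columns if c not in dataset.frame.columns]
    if missing:
        raise ValueError(f"feature set {set_id!r} missing columns: {missing}")
    X = dataset.frame[columns].copy()
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"feature set {set_id!r} has missing values in {bad}")
    y = dataset.labels(target)
    if y.isna().any():
        raise ValueError(f"labels for {target!r} contain missing values")
    return X, y


def save_table(dataset: FeatureDataset, path: str | Path) -> None:
    """Write the table as CSV (lossless for the schema's float columns)."""
    dataset.frame.to_csv(path, index=False)


def load_table(path: str | Path, cohort: str | None = None) -> FeatureDataset:
    """Read a feature table, validating the schema.

    Unknown extra columns are preserved with a warning; missing schema columns
    raise with the offending names.
    """
    frame = pd.read_csv(path)
    extra = [c for c in frame.columns if c not in SCHEMA_COLUMNS]
    if extra:
        warnings.warn(f"preserving unknown columns: {extra}", stacklevel=2)
    if cohort is None:
        cohort = (
            str(frame["cohort"].iloc[0]) if "cohort" in frame and len(frame) else "synthetic"
        )
    return FeatureDataset(frame=frame, cohort=cohort)


def load_reference_summaries() -> pd.DataFrame:
    """Published leave-one-out error summaries for the two study cohorts.

    One row per (cohort, feature_set, method, target) with the reported bias
    ``mu``, standard deviation ``sd``, printed 95 % CI bounds and sample size
    ``n``.  These are inputs to the CI-consistency and standards-grading
    checks, not outputs of this package.
    """
    with resources.files("cuffbp").joinpath("data/reference_summaries.csv").open() as fh:
        return pd.read_csv(fh)
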