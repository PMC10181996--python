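"""Cross-validation protocols, error summaries, accuracy grading, Bland–Altman.

Signed error is always estimate minus truth, in mmHg.  Summaries report the
bias (mean signed error), the sample SD (n−1 denominator), and a normal-
approximation 95 % CI ``bias ± 1.96·sd/sqrt(n)``.  Grading follows the
automated-sphygmomanometer accuracy requirement (IEC 80601-2-30 criterion 1):
|bias| ≤ 5 mmHg and SD ≤ 8 mmHg, both inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datasets import FEATURE_SETS, FeatureDataset, TARGETS, select_feature_set
from .models import FAMILIES, ModelSpec, fit, predict, reported_selection

__all__ = [
    "ErrorSummary",
    "IECGrade",
    "BlandAltman",
    "loo_errors",
    "holdout_errors",
    "summarize_errors",
    "ci_from_summary",
    "iec_grade",
    "bland_altman",
    "full_protocol",
    "round_half_away",
]

IEC_BIAS_LIMIT_MMHG = 5.0
IEC_SD_LIMIT_MMHG = 8.0
_Z95 = 1.96


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report convention; numpy rounds half-even)."""
    q = Decimal(10) ** -decimals
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP) if x >= 0 else -(
        Decimal(repr(-float(x))).quantize(q, rounding=ROUND_HALF_UP)
    )
    return float(d)


@dataclass(frozen=True)
class ErrorSummary:
    """Bias/SD/CI of one signed-error vector."""

    target: str
    n: int
    bias: float
    sd: float
    mean_abs_error: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.ci_low <= self.bias <= self.ci_high:
            raise ValueError("CI must bracket the bias")


@dataclass(frozen=True)
class IECGrade:
    bias_pass: bool
    sd_pass: bool

    @property
    def overall(self) -> bool:
        return self.bias_pass and self.sd_pass


@dataclass(frozen=True)
class BlandAltman:
    means: np.ndarray
    differences: np.ndarray
    mean_difference: float
    sd_difference: float

    @property
    def limits(self) -> tuple[float, float]:
        """Agreement limits at mean difference ± 2 SD."""
        return (
            self.mean_difference - 2.0 * self.sd_difference,
            self.mean_difference + 2.0 * self.sd_difference,
        )


def _resolve_feature_set(dataset: FeatureDataset, feature_set, target: str):
    """Accept a named view or an explicit column list."""
    if isinstance(feature_set, str):
        return select_feature_set(dataset, feature_set, target)
    X = dataset.frame[list(feature_set)]
    if X.isna().any().any():
        raise ValueError("explicit feature columns contain missing values")
    return X, dataset.labels(target)


def loo_errors(
    spec: ModelSpec, dataset: FeatureDataset, feature_set, target: str
) -> np.ndarray:
    """Leave-one-out signed errors: row i predicted by a fit on the other n−1."""
    X, y = _resolve_feature_set(dataset, feature_set, target)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError(f"leave-one-out needs n >= 3, got {n}")
    errors = np.empty(n)
    mask = np.ones(n, bool)
    for i in range(n):
        mask[i] = False
        try:
            model = fit(spec, X[mask], y[mask])
            errors[i] = predict(model, X[i : i + 1])[0] - y[i]
        except Exception as exc:
            raise RuntimeError(f"leave-one-out fold {i} failed: {exc}") from exc
        finally:
            mask[i] = True
    return errors


def holdout_errors(
    spec: ModelSpec,
    dataset: FeatureDataset,
    feature_set,
    target: str,
    ratio: float = 0.8,
    seed: int = 0,
    allow_any_ratio: bool = False,
) -> np.ndarray:
    """Signed errors on a held-out split (training fraction ``ratio``).

    The split is a seeded permutation with ``floor(ratio*n)`` training rows;
    only the study's 80:20 and 70:30 splits are accepted unless overridden.
    """
    if ratio not in (0.8, 0.7) and not allow_any_ratio:
        raise ValueError(f"ratio must be 0.8 or 0.7 (got {ratio}); override explicitly")
    X, y = _resolve_feature_set(dataset, feature_set, target)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    n_train = int(np.floor(ratio * n))
    if n_train < 2 or n_train >= n:
        raise ValueError(f"split leaves no usable train/test rows (n={n}, ratio={ratio})")
    order = np.random.default_rng(seed).permutation(n)
    train, test = order[:n_train], order[n_train:]
    model = fit(spec, X[train], y[train])
    return predict(model, X[test]) - y[test]


def summarize_errors(errors: np.ndarray, target: str = "sbp") -> ErrorSummary:
    errors = np.asarray(errors, float)
    n = len(errors)
    if n < 2:
        raise ValueError("need at least 2 errors to summarize")
    bias = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1))
    half = _Z95 * sd / np.sqrt(n)
    return ErrorSummary(
        target=target,
        n=n,
        bias=bias,
        sd=sd,
        mean_abs_error=float(np.mean(np.abs(errors))),
        ci_low=bias - half,
        ci_high=bias + half,
    )


def ci_from_summary(
    mu: float, sd: float, n: int, decimals: int | None = 2
) -> tuple[float, float]:
    """95 % CI from summary statistics: ``mu ± 1.96·sd/sqrt(n)``.

    ``decimals`` applies report rounding (half away from zero); pass ``None``
    for the unrounded bounds.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2")
    half = _Z95 * sd / np.sqrt(n)
    low, high = mu - half, mu + half
    if decimals is None:
        return low, high
    return round_half_away(low, decimals), round_half_away(high, decimals)


def iec_grade(summary: ErrorSummary | None = None, *, bias=None, sd=None) -> IECGrade:
    """Grade against the ±5 mmHg bias / 8 mmHg SD requirement (inclusive)."""
    if summary is not None:
        bias, sd = summary.bias, summary.sd
    if bias is None or sd is None:
        raise ValueError("provide a summary or explicit bias and sd")
    return IECGrade(
        bias_pass=abs(bias) <= IEC_BIAS_LIMIT_MMHG, sd_pass=sd <= IEC_SD_LIMIT_MMHG
    )


def bland_altman(estimates: np.ndarray, truths: np.ndarray) -> BlandAltman:
    """Per-pair (mean, difference) with agreement limits at ± 2 SD."""
    estimates = np.asarray(estimates, float)
    truths = np.asarray(truths, float)
    if len(estimates) != len(truths):
        raise ValueError("estimates and truths must have equal length")
    if len(estimates) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = estimates - truths
    return BlandAltman(
        means=(estimates + truths) / 2.0,
        differences=diffs,
        mean_difference=float(np.mean(diffs)),
        sd_difference=float(np.std(diffs, ddof=1)),
    )


def full_protocol(
    dataset: FeatureDataset,
    feature_sets: tuple[str, ...] = ("combined", "pat", "morphology"),
    families: tuple[str, ...] = FAMILIES,
    targets: tuple[str, ...] = TARGETS,
    protocol: str = "loo",
    seed: int = 0,
    specs: dict | None = None,
    **protocol_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """The full method × feature-set × target benchmark grid.

    Each cell trains the family at its reported grid selection (override via
    ``specs`` keyed ``(family, feature_set, target)``), collects signed errors
    under the chosen protocol, and summarizes + grades them.  Returns the
    summary table (one row per cell) and the raw error vectors keyed by cell.
    """
    for fs in feature_sets:
        if fs not in FEATURE_SETS:
            raise KeyError(f"unknown feature set {fs!r}")
    rows, errors_store, failures = [], {}, []
    for family in families:
        for fs in feature_sets:
            for target in targets:
                key = (family, fs, target)
                spec = (specs or {}).get(key) or reported_selection(
                    family, target, seed=seed
                )
                try:
                    if protocol == "loo":
                        errors = loo_errors(spec, dataset, fs, target)
                    else:
                        errors = holdout_errors(
                            spec, dataset, fs, target, seed=seed, **protocol_kwargs
                        )
                except Exception as exc:  # noqa: BLE001 - report per-cell failures
                    failures.append((key, str(exc)))
                    continue
                s = summarize_errors(errors, target=target)
                g = iec_grade(s)
                rows.append(
                    {
                        "method": family,
                        "feature_set": fs,
                        "target": target,
                        "n": s.n,
                        "bias": s.bias,
                        "sd": s.sd,
                        "mean_abs_error": s.mean_abs_error,
                        "ci_low": s.ci_low,
                        "ci_high": s.ci_high,
                        "bias_pass": g.bias_pass,
                        "sd_pass": g.sd_pass,
                        "iec_pass": g.overall,
                    }
                )
                errors_store[key] = errors
    if failures:
        detail = "; ".join(f"{k}: {msg}" for k, msg in failures)
        raise RuntimeError(f"{len(failures)} benchmark cells failed: {detail}")
    return pd.DataFrame(rows), errors_store
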