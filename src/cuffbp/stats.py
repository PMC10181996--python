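"""Method-comparison statistics: two-way ANOVA, Levene spread tests, post hocs.

The benchmark design is a balanced two-factor layout — five regression
methods crossed with three feature sets, each cell holding the n signed
cross-validation errors of one pressure target.  Mean differences are tested
with a classical two-way ANOVA; spread differences with Levene's test in its
two-factor form (the same ANOVA applied to absolute deviations of each error
from its cell mean).  Pairwise follow-ups use two-group F-tests on means and
two-sample t-tests on the Levene deviations, with step-down Bonferroni–Holm
control within each family of comparisons.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "two_way_anova",
    "levene_two_way",
    "posthoc_pairwise",
    "holm_adjust",
    "compare_all",
]


def _as_long_frame(errors: dict) -> pd.DataFrame:
    """Accept ``{(method, feature_set): vector}`` and return a long frame."""
    if isinstance(errors, pd.DataFrame):
        required = {"error", "method", "feature_set"}
        if not required <= set(errors.columns):
            raise ValueError(f"long frame needs columns {sorted(required)}")
        return errors
    frames = []
    for (method, feature_set), vec in errors.items():
        vec = np.asarray(vec, float)
        if len(vec) == 0:
            raise ValueError(f"empty cell ({method}, {feature_set})")
        frames.append(
            pd.DataFrame(
                {"error": vec, "method": method, "feature_set": feature_set}
            )
        )
    return pd.concat(frames, ignore_index=True)


def two_way_anova(errors) -> pd.DataFrame:
    """Classical two-way ANOVA of signed errors over feature set × method.

    ``errors`` is either ``{(method, feature_set): error vector}`` or a long
    DataFrame with columns ``error``, ``method``, ``feature_set``.  Returns
    one row per effect (feature, method, interaction) with F, numerator and
    denominator df, and p.  The design is balanced by construction, so the
    classical sums of squares are unambiguous.
    """
    data = _as_long_frame(errors)
    counts = data.groupby(["method", "feature_set"], sort=False).size()
    if counts.min() < 2:
        raise ValueError("every method × feature-set cell needs >= 2 observations")
    labels = {}
    terms = []
    if data["feature_set"].nunique() > 1:
        terms.append("C(feature_set)")
        labels["C(feature_set)"] = "feature"
    if data["method"].nunique() > 1:
        terms.append("C(method)")
        labels["C(method)"] = "method"
    if len(terms) == 2:
        labels["C(feature_set):C(method)"] = "interaction"
    if not terms:
        raise ValueError("need at least one factor with two levels")
    nf = data["feature_set"].nunique()
    nm = data["method"].nunique()
    if data["error"].nunique() == 1:  # constant response: no variance anywhere
        dfs = {"feature": nf - 1, "method": nm - 1, "interaction": (nf - 1) * (nm - 1)}
        return pd.DataFrame(
            [
                {
                    "factor": name,
                    "F": 0.0,
                    "df_num": dfs[name],
                    "df_den": len(data) - nf * nm,
                    "p": 1.0,
                }
                for name in labels.values()
            ]
        )
    formula = "error ~ " + " * ".join(terms)  # single-level factors drop out
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])
    rows = []
    for src, name in labels.items():
        rows.append(
            {
                "factor": name,
                "F": float(table.loc[src, "F"]),
                "df_num": int(table.loc[src, "df"]),
                "df_den": int(df_resid),
                "p": float(table.loc[src, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)


def levene_two_way(errors, center: str = "mean") -> pd.DataFrame:
    """Two-factor Levene test on the spread of signed errors.

    Each observation is replaced by its absolute deviation from the cell's
    center (mean by default — the classical Levene statistic; ``median``
    gives the robust variant), then the two-way ANOVA is applied to the
    deviations.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    data = _as_long_frame(errors).copy()
    centerer = np.mean if center == "mean" else np.median
    data["error"] = data.groupby(["method", "feature_set"], sort=False)[
        "error"
    ].transform(lambda x: np.abs(x - centerer(x)))
    return two_way_anova(data)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Bonferroni–Holm adjusted p-values, order-preserving.

    ``adj[(i)] = max_{j<=i} (m - j + 1) * p_(j)``, capped at 1, where (i)
    indexes the ascending order; never smaller than the raw p.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def posthoc_pairwise(
    errors: dict,
    measure: str = "mean",
    correction: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered pairwise comparisons between groups of errors.

    ``measure='mean'`` compares group means with a two-group F-test (the
    square of the two-sample t statistic); ``measure='absolute'`` compares
    spread with a two-sample t-test on each group's absolute deviations from
    its own mean.  p-values are Holm-adjusted over the emitted family.  The
    winner (the group with the smaller error measure: |mean| for means, mean
    deviation for spread) is reported only for significant pairs.
    """
    if measure not in ("mean", "absolute"):
        raise ValueError("measure must be 'mean' or 'absolute'")
    if correction not in ("holm", "none"):
        raise ValueError("correction must be 'holm' or 'none'")
    groups = {k: np.asarray(v, float) for k, v in errors.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vec in groups.items():
        if len(vec) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
    if measure == "absolute":
        groups = {k: np.abs(v - v.mean()) for k, v in groups.items()}

    rows = []
    for a, b in itertools.combinations(groups, 2):
        va, vb = groups[a], groups[b]
        if measure == "mean":
            stat, p = sps.f_oneway(va, vb)
            stat_name, df = "F", (1, len(va) + len(vb) - 2)
            if not np.isfinite(p):  # identical groups: F underflows negative
                stat = max(float(stat), 0.0)
                p = float(sps.f.sf(stat, *df))
            score_a, score_b = abs(va.mean()), abs(vb.mean())
        else:
            stat, p = sps.ttest_ind(va, vb)
            stat_name, df = "t", (len(va) + len(vb) - 2,)
            score_a, score_b = va.mean(), vb.mean()
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": float(stat),
                "stat_name": stat_name,
                "df": df,
                "p_raw": float(p),
                "_winner": a if score_a < score_b else b,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = (
        holm_adjust(out["p_raw"].to_numpy())
        if correction == "holm"
        else out["p_raw"].to_numpy()
    )
    out["significant"] = out["p_adj"] < alpha
    out["winner"] = out["_winner"].where(out["significant"], other=None)
    return out.drop(columns="_winner")


def compare_all(
    errors_store: dict,
    targets: tuple[str, ...] = ("sbp", "dbp", "map"),
    mean_posthoc_feature_set: str = "combined",
    alpha: float = 0.05,
) -> dict[str, dict[str, pd.DataFrame]]:
    """The full statistical report over a benchmark error store.

    ``errors_store`` is keyed ``(method, feature_set, target)`` (the output
    of :func:`cuffbp.evaluation.full_protocol`).  Per target: the two-way
    ANOVA on signed errors, the two-factor Levene test on their spread,
    pairwise mean comparisons between methods on one feature set (the
    combined set by default, where the feature factor shows no effect), and
    pairwise spread comparisons across all method × feature-set cells.
    """
    report: dict[str, dict[str, pd.DataFrame]] = {}
    for target in targets:
        cells = {
            (m, f): v for (m, f, t), v in errors_store.items() if t == target
        }
        if not cells:
            raise ValueError(f"no error vectors for target {target!r}")
        mean_groups = {
            m: v for (m, f), v in cells.items() if f == mean_posthoc_feature_set
        }
        abs_groups = {f"{m}[{f}]": v for (m, f), v in cells.items()}
        report[target] = {
            "anova": two_way_anova(cells),
            "levene": levene_two_way(cells),
            "posthoc_mean": posthoc_pairwise(mean_groups, measure="mean", alpha=alpha),
            "posthoc_absolute": posthoc_pairwise(
                abs_groups, measure="absolute", alpha=alpha
            ),
        }
    return report
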