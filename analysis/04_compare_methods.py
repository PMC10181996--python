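#!/usr/bin/env python
"""Statistical comparison of methods and feature sets from benchmark errors.

Per pressure target: two-way ANOVA on signed errors (method x feature set),
the two-factor Levene test on error spread, Holm-corrected pairwise mean
comparisons between methods on the combined feature set, and Holm-corrected
pairwise spread comparisons across all 15 method x feature-set cells.
Writes one CSV per table under results/compare/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cuffbp.stats import compare_all


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--errors", type=Path, default=Path("results/errors.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/compare"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    long = pd.read_csv(args.errors)
    store = {
        key: grp["error"].to_numpy()
        for key, grp in long.groupby(["method", "feature_set", "target"])
    }
    report = compare_all(store, targets=tuple(long["target"].unique()))
    for target, tables in report.items():
        anova = tables["anova"].set_index("factor")
        print(
            f"{target}: method F({int(anova.loc['method','df_num'])}) = "
            f"{anova.loc['method','F']:.2f} (p = {anova.loc['method','p']:.2g}); "
            f"feature F({int(anova.loc['feature','df_num'])}) = "
            f"{anova.loc['feature','F']:.2f} (p = {anova.loc['feature','p']:.2g})"
        )
        n_sig = int(tables["posthoc_absolute"]["significant"].sum())
        print(f"  spread post hocs: {n_sig} significant pairs after Holm")
        for name, frame in tables.items():
            frame.to_csv(args.out / f"{name}_{target}.csv", index=False)
    print(f"wrote comparison tables to {args.out}")


if __name__ == "__main__":
    main()
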