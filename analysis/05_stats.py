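"""Group and drinking statistics: per-measure mixed ANOVA (group x
treatment x channel), channelwise paired t-tests with FDR, drinking
BL/ADE/relapse summaries with their tests, and partial Spearman
correlations of post-stimulation activity with drinking controlling for
pre-stimulation activity.

Reads results/tables/features_imputed.csv and results/data/drinking.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from oddconn.stats import (
    drinking_measures,
    fdr_adjust,
    paired_t_by_channel,
    rm_anova,
)
from oddconn.pipeline import _drinking_correlations


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tables", default="results/tables")
    ap.add_argument("--data", default="results/data")
    args = ap.parse_args()

    tables = Path(args.tables)
    feats = pd.read_csv(tables / "features_imputed.csv")

    anova_rows = []
    for measure, df_m in feats.groupby("measure"):
        tab = rm_anova(df_m)
        tab.insert(0, "measure", measure)
        anova_rows.append(tab)
    anova = pd.concat(anova_rows, ignore_index=True)
    for effect, idx in anova.groupby("effect").groups.items():
        anova.loc[idx, "p_fdr"] = fdr_adjust(anova.loc[idx, "p"].to_numpy())
    anova.to_csv(tables / "anova.csv", index=False)
    sig = anova[(anova["effect"] == "group") & (anova["p_fdr"] < 0.05)]
    print(f"group effects significant after FDR: {len(sig)} measures")
    if len(sig):
        print(sig[["measure", "F", "p", "p_fdr"]].to_string(index=False))

    paired_rows = []
    for (measure, group), df_m in feats.groupby(["measure", "group"]):
        wide = df_m.pivot_table(index="subject",
                                columns=["treatment", "channel"], values="value")
        if wide.shape[0] < 3:
            continue
        chans = sorted(df_m["channel"].unique())
        tt = paired_t_by_channel(wide["pre"][chans].to_numpy(),
                                 wide["post"][chans].to_numpy())
        tt["channel"] = chans
        tt.insert(0, "group", group)
        tt.insert(0, "measure", measure)
        paired_rows.append(tt)
    if paired_rows:
        pd.concat(paired_rows, ignore_index=True).to_csv(
            tables / "paired_t.csv", index=False
        )

    drinking = pd.read_csv(Path(args.data) / "drinking.csv")
    res = drinking_measures(drinking)
    res.per_rat.to_csv(tables / "drinking_measures.csv", index=False)
    res.relapse_tests.to_csv(tables / "drinking_relapse_tests.csv", index=False)
    tot = res.per_rat[res.per_rat["concentration"] == "total"]
    print(
        f"drinking (total, g/kg/day): BL {tot['BL'].mean():.2f} +/- "
        f"{tot['BL'].std(ddof=1):.2f}, ADE {tot['ADE'].mean():.2f} +/- "
        f"{tot['ADE'].std(ddof=1):.2f}, relapse {tot['relapse'].mean():.2f}"
    )

    corr = _drinking_correlations(feats, res.per_rat)
    if corr is not None:
        corr.to_csv(tables / "drinking_correlations.csv", index=False)
        print(f"drinking correlations: {int((corr['p'] < 0.05).sum())} "
              f"significant of {len(corr)}")
    else:
        print("drinking correlations skipped (needs >= 5 alcohol subjects)")


if __name__ == "__main__":
    main()
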