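"""Group comparisons on the scorecards.

Runs the ANCOVA battery (group effect controlling for age and NART) on
fluency totals and each error/frequency metric, followed by
Bonferroni-corrected pairwise contrasts against the healthy-control group
(alpha 0.05/4), plus a chi-square test of the gender split. Writes a tidy
results table and prints the headline effects.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import fluencygraph as fg
from fluencygraph import io as fio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--scorecards", default="results/scorecards.tsv")
    ap.add_argument("--out", default="results/group_stats.tsv")
    args = ap.parse_args()

    participants = fio.read_metadata(Path(args.cohort) / "metadata.tsv")
    cards = fio.read_scorecards(args.scorecards)
    groups = np.array([p.group for p in participants])
    covs = np.column_stack([[p.age for p in participants],
                            [p.nart for p in participants]])

    rows = []
    for var in ("correct_words", "pct_rulebreak", "pct_inappropriate",
                "pct_proper_noun", "pct_permutation", "pct_perseveration",
                "pct_lowfreq", "mean_cluster_size", "relative_switches"):
        y = np.nan_to_num(cards[var].to_numpy(dtype=float))
        r = fg.ancova(y, groups, covs)
        rows.append(dict(variable=var, test="ancova", F=r.F, p=r.p,
                         partial_eta_sq=r.partial_eta_sq,
                         df_between=r.df_between, df_within=r.df_within))
        if r.p < 0.05:
            pairs = [(g, "HC") for g in ("LF", "RF", "LP", "RP")]
            post = fg.bonferroni_pairwise(y, groups, covs, family_alpha=0.05,
                                          n_comparisons=4, pairs=pairs)
            for p_row in post.itertuples():
                rows.append(dict(variable=var,
                                 test=f"pairwise:{p_row.group_a}-vs-HC",
                                 F=np.nan, p=p_row.p, partial_eta_sq=np.nan,
                                 df_between=np.nan, df_within=p_row.df))

    gender = pd.crosstab(groups, [p.gender for p in participants])
    cat = fg.categorical_tests(gender.to_numpy())
    rows.append(dict(variable="gender", test=cat.test, F=cat.statistic,
                     p=cat.p, partial_eta_sq=np.nan,
                     df_between=np.nan, df_within=np.nan))

    table = pd.DataFrame(rows)
    table.to_csv(args.out, sep="\t", index=False)
    print(table[table.test == "ancova"].round(4).to_string(index=False))
    sig = table[(table.test != "ancova") & (table.p < 0.0125)]
    print(f"\n{len(sig)} pairwise contrasts significant at 0.05/4 = 0.0125")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
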