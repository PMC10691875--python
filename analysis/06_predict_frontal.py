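"""Predict frontal-lesion status from nested feature sets.

Compares three Bayesian logistic models of the frontal-vs-rest target:
'baseline' (age, NART, fluency score; ridge prior), 'errors' (baseline plus
rule-break, low-frequency, switching and clustering metrics; ridge) and
'full' (errors plus the random-projected sequence embeddings; horseshoe).
Reports McFadden pseudo-R^2, WAIC and the minimum effective-sample-size
fraction per model.
"""

import argparse
import warnings
from pathlib import Path

import fluencygraph as fg
from fluencygraph import io as fio
from fluencygraph.bayes import compare_models


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--embeddings", default="results/embeddings.tsv")
    ap.add_argument("--scorecards", default="results/scorecards.tsv")
    ap.add_argument("--k-project", type=int, default=64)
    ap.add_argument("--mcmc", type=int, nargs=3, default=(2000, 2000, 2),
                    metavar=("BURN", "SAMPLES", "THIN"))
    ap.add_argument("--out", default="results/model_comparison.tsv")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    participants = fio.read_metadata(cohort / "metadata.tsv")
    cards_df = fio.read_scorecards(args.scorecards)
    E = fio.read_embeddings(args.embeddings)

    feats = cards_df.set_index("participant_id")[
        ["pct_rulebreak", "pct_lowfreq", "n_switches", "relative_switches",
         "mean_cluster_size"]].fillna(0.0)
    feats.insert(0, "fluency", cards_df.set_index("participant_id").correct_words)
    feats.insert(0, "nart", [p.nart for p in participants])
    feats.insert(0, "age", [p.age for p in participants])
    y = fg.frontal_target(participants)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = compare_models(feats, y, embeddings=E, seed=args.seed,
                               k_project=args.k_project,
                               mcmc=tuple(args.mcmc))
    table.to_csv(args.out, sep="\t", index=False)
    print(table.round(4).to_string(index=False))
    best = table.loc[table.waic.idxmin(), "model"]
    print(f"\nbest model by WAIC: {best}; wrote {args.out}")


if __name__ == "__main__":
    main()
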