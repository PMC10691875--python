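"""Score every transcript.

Classifies each uttered token (correct / inappropriate / proper noun /
permutation / wrong letter / perseveration), computes the error and
low-frequency percentages against the cohort-pooled 2-SD threshold, and the
Troyer first-two-letter cluster/switch statistics. Writes one scorecard row
per participant and prints the group-level summary (the analogue of the
study's demographic and error tables).
"""

import argparse
from pathlib import Path

import pandas as pd

import fluencygraph as fg
from fluencygraph import io as fio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/scorecards.tsv")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    transcripts = fio.read_transcripts(cohort / "transcripts.jsonl")
    participants = fio.read_metadata(cohort / "metadata.tsv")
    lexica = [fg.FrequencyLexicon.from_tsv(cohort / "lexicon.tsv")]
    style_path = cohort / "style_lexicon.tsv"
    if style_path.exists():
        lexica.append(fg.FrequencyLexicon.from_tsv(style_path))

    cards, threshold = fg.score_cohort(transcripts, lexica)
    fio.write_scorecards(cards, args.out)

    df = pd.DataFrame([c.as_dict() for c in cards])
    df["group"] = [p.group for p in participants]
    print(f"low-frequency threshold (transformed scale): {threshold:.3f}")
    cols = ["correct_words", "pct_rulebreak", "pct_perseveration",
            "pct_lowfreq", "mean_cluster_size", "relative_switches"]
    summary = df.groupby("group")[cols].agg(["mean", "std"]).round(2)
    print(summary.to_string())
    print(f"wrote {len(cards)} scorecards -> {args.out}")


if __name__ == "__main__":
    main()
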