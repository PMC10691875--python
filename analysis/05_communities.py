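"""Infer participant communities from the similarity graph.

Fits the degree-corrected stochastic block model (description-length
minimization with age/NART edge covariates) to the cosine-similarity graph,
profiles each community (group composition, median fluency/age/NART and the
most characteristic words by TF-IDF) and runs the one-vs-rest Mann-Whitney
battery at the alpha/40 Bonferroni threshold.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

import fluencygraph as fg
from fluencygraph import io as fio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--edges", default="results/embeddings.tsv")
    ap.add_argument("--scorecards", default="results/scorecards.tsv")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    out = Path(args.out_dir)
    transcripts = fio.read_transcripts(cohort / "transcripts.jsonl")
    participants = fio.read_metadata(cohort / "metadata.tsv")
    lexicon = fg.FrequencyLexicon.from_tsv(cohort / "lexicon.tsv")
    E = fio.read_embeddings(args.edges)
    cards_df = fio.read_scorecards(args.scorecards)

    G = fg.cosine_adjacency(E)
    fg.attach_covariates(G, participants, transcripts, lexicon)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        part = fg.fit_sbm(G, max_blocks=25, n_sweeps=10, seed=args.seed)

    flu = pd.DataFrame({"fluency": cards_df.correct_words.to_numpy()},
                       index=cards_df.participant_id.astype(str))
    labels = [fg.classify_tokens(t, fg.load_wordlist("profanity"),
                                 fg.load_wordlist("proper_nouns"))
              for t in transcripts]
    cards = [fg.score(t, ls) for t, ls in zip(transcripts, labels)]
    profiles = fg.profile_communities(part, participants, transcripts, cards)
    contrasts = fg.community_contrasts(part, participants, flu)

    pd.DataFrame({"participant_id": part.participant_ids,
                  "block": part.assignment}).to_csv(
        out / "partition.tsv", sep="\t", index=False)
    with open(out / "communities.json", "w") as fh:
        json.dump([p.__dict__ for p in profiles], fh, indent=1, default=float)
    contrasts.to_csv(out / "community_contrasts.tsv", sep="\t", index=False)

    print(f"{part.n_blocks} communities "
          f"(description length {part.description_length:.1f})")
    for p in profiles:
        frontal = p.pct_by_group.get("LF", 0) + p.pct_by_group.get("RF", 0)
        words = ", ".join(w for w, _ in p.top_words[:5])
        print(f"  block {p.block}: n={p.n}, {frontal:.0f}% frontal, "
              f"median fluency {p.median_fluency:.1f}, "
              f"median age {p.median_age:.0f}; characteristic words: {words}")
    n_sig = int(contrasts.significant.sum())
    print(f"{n_sig} one-vs-rest contrasts significant at alpha/40")


if __name__ == "__main__":
    main()
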