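"""Simulate the study cohort.

Generates a five-group synthetic cohort (left/right frontal, left/right
posterior, healthy controls) with the published group means for fluency
totals, error-type rates, low-frequency usage and age/NART, plus a distinct
"style" lexicon for the frontal groups so that sequence-level structure is
present for the downstream graph and predictive analyses. Writes the lexica,
metadata and transcripts under results/cohort/.
"""

import argparse
from pathlib import Path

import fluencygraph as fg
from fluencygraph import io as fio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-group", type=int, default=48)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    profiles = fg.make_default_profiles()
    for p in profiles:
        p.n = args.n_per_group
    lexicon = fg.make_lexicon(1000, 1.0, seed=args.seed)
    style = fg.make_lexicon(1000, 1.0, seed=args.seed + 1000)
    participants, transcripts = fg.simulate_cohort(
        profiles, lexicon, seed=args.seed,
        group_lexicons={"LF": style, "RF": style})

    lexicon.to_frequency_lexicon().to_tsv(out / "lexicon.tsv")
    style.to_frequency_lexicon().to_tsv(out / "style_lexicon.tsv")
    fio.write_metadata(participants, out / "metadata.tsv")
    fio.write_transcripts(transcripts, out / "transcripts.jsonl")

    n_words = sum(len(t.tokens) for t in transcripts)
    print(f"simulated {len(participants)} participants "
          f"({args.n_per_group}/group), {n_words} words -> {out}/")


if __name__ == "__main__":
    main()
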