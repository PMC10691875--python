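"""Embed word sequences and build the participant similarity graph.

Each participant's full word sequence is mapped to a 2048-dimensional
unit vector by the deterministic hashing embedder; pairwise cosine
similarities form a complete weighted graph whose edges carry absolute
age and NART differences as covariates and whose nodes carry the mean
transformed word frequency. Writes the embedding matrix and the edge list.
"""

import argparse
from pathlib import Path

import fluencygraph as fg
from fluencygraph import io as fio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--d", type=int, default=2048)
    ap.add_argument("--out-embeddings", default="results/embeddings.tsv")
    ap.add_argument("--out-edges", default="results/edges.tsv")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    transcripts = fio.read_transcripts(cohort / "transcripts.jsonl")
    participants = fio.read_metadata(cohort / "metadata.tsv")
    lexicon = fg.FrequencyLexicon.from_tsv(cohort / "lexicon.tsv")

    E = fg.embed_sequences(transcripts, d=args.d, seed=args.seed)
    G = fg.cosine_adjacency(E)
    fg.attach_covariates(G, participants, transcripts, lexicon)
    fio.write_embeddings(E, args.out_embeddings)
    fio.write_edges(G, args.out_edges)

    w = G.weights[G.weights != 0]
    print(f"embedded {len(transcripts)} sequences at d={args.d}; "
          f"cosine weights span [{w.min():.3f}, {w.max():.3f}] "
          f"(mean {w.mean():.3f})")
    print(f"wrote {args.out_embeddings} and {args.out_edges}")


if __name__ == "__main__":
    main()
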