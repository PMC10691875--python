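"""Plain-text artifact formats.

Cohort metadata is TSV (participant_id, group, age, nart, gender);
transcripts are JSON-lines with one ``{"participant_id", "words",
"annotations"?}`` object per participant; lexica are two-column TSV;
embeddings are TSV with a participant_id column; graph edges are a TSV
edge list (id_i, id_j, weight, plus any edge covariates).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Participant
from .embedding import EmbeddingMatrix, SimilarityGraph
from .scoring import ScoreCard, Transcript

__all__ = [
    "write_metadata", "read_metadata",
    "write_transcripts", "read_transcripts",
    "write_scorecards", "read_scorecards",
    "write_embeddings", "read_embeddings",
    "write_edges",
]


def write_metadata(participants: Sequence[Participant], path: str | Path) -> None:
    df = pd.DataFrame([p.__dict__ for p in participants])
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, sep="\t")
    return [Participant(str(r.participant_id), str(r.group), float(r.age),
                        float(r.nart), str(r.gender))
            for r in df.itertuples()]


def write_transcripts(transcripts: Sequence[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            obj: dict = {"participant_id": t.participant_id, "words": t.tokens}
            if t.annotations:
                obj["annotations"] = {str(k): v for k, v in t.annotations.items()}
            fh.write(json.dumps(obj) + "\n")


def read_transcripts(path: str | Path) -> list[Transcript]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        ann = obj.get("annotations")
        out.append(Transcript(
            participant_id=str(obj["participant_id"]),
            tokens=[str(w) for w in obj["words"]],
            annotations={int(k): v for k, v in ann.items()} if ann else None,
        ))
    return out


def write_scorecards(cards: Sequence[ScoreCard], path: str | Path) -> None:
    pd.DataFrame([c.as_dict() for c in cards]).to_csv(path, sep="\t", index=False)


def read_scorecards(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_embeddings(E: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(E.vectors, index=pd.Index(E.participant_ids,
                                                name="participant_id"))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_embeddings(path: str | Path, backend_tag: str = "file") -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vec = df.to_numpy(dtype=float)
    vec = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    return EmbeddingMatrix(list(df.index.astype(str)), vec, backend_tag)


def write_edges(G: SimilarityGraph, path: str | Path) -> None:
    n = G.n
    iu = np.triu_indices(n, k=1)
    data = {
        "id_i": [G.participant_ids[i] for i in iu[0]],
        "id_j": [G.participant_ids[j] for j in iu[1]],
        "weight": G.weights[iu],
    }
    for name, C in G.edge_covariates.items():
        data[name] = np.asarray(C)[iu]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.8g")
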