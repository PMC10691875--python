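"""Cohort-level scoring and feature assembly.

Glue between the single-transcript scoring primitives and the cohort-level
analyses: classify and score every transcript against the pooled
low-frequency threshold, and assemble the predictive-model feature table
(age, NART, fluency score, error and clustering metrics) with the binary
frontal target (frontal = 1 versus posterior and control = 0).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Participant, load_wordlist
from .lexicon import FrequencyLexicon, lowfreq_threshold
from .scoring import ScoreCard, Transcript, classify_tokens, score

__all__ = ["UnionLexicon", "score_cohort", "feature_table", "frontal_target"]

FRONTAL_GROUPS = ("LF", "RF")


class UnionLexicon:
    """First-hit union of several frequency lexica (duck-typed lookup)."""

    def __init__(self, lexica: Sequence[FrequencyLexicon]):
        if not lexica:
            raise ValueError("need at least one lexicon")
        self.lexica = list(lexica)

    def transformed(self, word: str) -> float:
        for lx in self.lexica:
            v = lx.transformed(word)
            if not math.isnan(v):
                return v
        return float("nan")


def score_cohort(
    transcripts: Sequence[Transcript],
    lexica: Sequence[FrequencyLexicon],
    profanity: Optional[Sequence[str]] = None,
    proper_nouns: Optional[Sequence[str]] = None,
) -> tuple[list[ScoreCard], float]:
    """Classify and score every transcript; returns (scorecards, threshold).

    The low-frequency threshold is the cohort-pooled mean minus two SDs of
    the transformed frequencies of all correct tokens (the cohort-relative
    rule), computed before any per-participant percentage.
    """
    profanity = list(profanity) if profanity is not None else load_wordlist("profanity")
    proper_nouns = (list(proper_nouns) if proper_nouns is not None
                    else load_wordlist("proper_nouns"))
    union = UnionLexicon(lexica)
    labels = [classify_tokens(t, profanity, proper_nouns) for t in transcripts]
    pooled = [union.transformed(tok)
              for t, labs in zip(transcripts, labels)
              for tok, lab in zip(t.tokens, labs) if lab.label == "correct"]
    threshold = lowfreq_threshold(pooled)
    cards = [score(t, labs, lexicon=union, threshold=threshold)
             for t, labs in zip(transcripts, labels)]
    return cards, threshold


def feature_table(participants: Sequence[Participant],
                  cards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Predictive-model features, one row per participant (order preserved).

    NaN clustering/low-frequency values (single-token transcripts, no
    correct words) are coded as 0.
    """
    if len(participants) != len(cards):
        raise ValueError("participants and scorecards are misaligned")
    return pd.DataFrame({
        "age": [p.age for p in participants],
        "nart": [p.nart for p in participants],
        "fluency": [c.correct_words for c in cards],
        "pct_rulebreak": [c.pct_rulebreak for c in cards],
        "pct_lowfreq": [np.nan_to_num(c.pct_lowfreq) for c in cards],
        "n_switches": [c.n_switches for c in cards],
        "relative_switches": [np.nan_to_num(c.relative_switches) for c in cards],
        "mean_cluster_size": [c.mean_cluster_size for c in cards],
    }, index=[p.participant_id for p in participants])


def frontal_target(participants: Sequence[Participant]) -> np.ndarray:
    """Binary target: 1 for frontal groups, 0 for posterior and control."""
    return np.array([1.0 if p.group in FRONTAL_GROUPS else 0.0
                     for p in participants])
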