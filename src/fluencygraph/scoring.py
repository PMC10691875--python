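"""Single-word scoring of letter-fluency transcripts.

Each uttered token receives exactly one label:

``correct``
    a valid response starting with the target letter.
``inappropriate``
    a profanity or otherwise socially inappropriate word (rule break).
``proper_noun``
    a name (rule break).
``permutation``
    an inflectional variant of an earlier response, e.g. "say, saying"
    (rule break).
``wrong_letter``
    a response not starting with the target letter (rule break subtype that
    is excluded from the rule-break percentage, these being too rare for
    meaningful analysis).
``perseveration``
    an exact repeat of any earlier response; *recurrent* when at least one
    response intervenes ("sun, sea, sun"), as opposed to an immediate repeat.

Percentages are errors relative to the total number of words produced
(``count / total * 100``); the low-frequency percentage is relative to the
number of correct words only. Clustering and switching follow the Troyer
phonemic convention restricted to shared first-two-letter onsets: a cluster
is a maximal run of consecutive words sharing their first two letters, its
size is the run length minus one (singletons score 0), a switch is a
transition between runs, and the relative number of switches is
``switches / (total words - 1) * 100``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .lexicon import MISSING, FrequencyLexicon, pct_lowfreq

__all__ = [
    "LABELS",
    "DEFAULT_SUFFIX_RULES",
    "Transcript",
    "TokenLabel",
    "ScoreCard",
    "stem",
    "classify_tokens",
    "cluster_switch",
    "score",
]

LABELS = (
    "correct",
    "inappropriate",
    "proper_noun",
    "permutation",
    "wrong_letter",
    "perseveration",
)

# Ordered suffix-stripping rules for permutation detection; the first rule
# whose removal leaves a stem of >= 3 characters applies.
DEFAULT_SUFFIX_RULES = ("ing", "ings", "ed", "er", "ers", "est", "en", "s", "es", "'s")


@dataclass
class Transcript:
    """An ordered list of uttered tokens for one participant.

    ``annotations`` optionally maps token index to a manual label that
    overrides automatic classification. ``planted`` holds generator ground
    truth for synthetic transcripts; it is never consulted by scoring.
    """

    participant_id: str
    tokens: list[str]
    annotations: Optional[dict[int, str]] = None
    planted: Optional[list[str]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(not t for t in self.tokens):
            raise ValueError("transcript tokens must be non-empty strings")


@dataclass(frozen=True)
class TokenLabel:
    label: str
    recurrent: Optional[bool] = None  # set only for perseverations

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def stem(token: str, suffix_rules: Sequence[str] = DEFAULT_SUFFIX_RULES,
         min_stem: int = 3) -> str:
    """Strip the first applicable suffix rule, keeping stems of >= min_stem."""
    for suf in suffix_rules:
        if token.endswith(suf) and len(token) - len(suf) >= min_stem:
            return token[: -len(suf)]
    return token


def classify_tokens(
    t: Transcript,
    profanity_list: Iterable[str],
    proper_noun_list: Iterable[str],
    target_letter: str = "s",
    suffix_rules: Sequence[str] = DEFAULT_SUFFIX_RULES,
) -> list[TokenLabel]:
    """Assign one label per token, in priority order.

    Priority: exact repeat (perseveration) > inappropriate > proper noun >
    permutation (shared stem with an earlier token) > wrong letter > correct.
    Manual annotations in the transcript override the automatic label.
    """
    if not t.tokens:
        raise ValueError("cannot classify an empty transcript")
    profanity = set(profanity_list)
    proper = set(proper_noun_list)
    annotations = t.annotations or {}
    labels: list[TokenLabel] = []
    for i, tok in enumerate(t.tokens):
        earlier = t.tokens[:i]
        if i in annotations:
            lab = annotations[i]
            rec = None
            if lab == "perseveration" and tok in earlier:
                rec = t.tokens[i - 1] != tok
            labels.append(TokenLabel(lab, rec))
            continue
        if tok in earlier:
            # recurrent iff >= 1 response intervenes since the last occurrence
            labels.append(TokenLabel("perseveration", recurrent=t.tokens[i - 1] != tok))
        elif tok in profanity:
            labels.append(TokenLabel("inappropriate"))
        elif tok in proper:
            labels.append(TokenLabel("proper_noun"))
        elif _is_permutation(tok, earlier, suffix_rules):
            labels.append(TokenLabel("permutation"))
        elif not tok.startswith(target_letter):
            labels.append(TokenLabel("wrong_letter"))
        else:
            labels.append(TokenLabel("correct"))
    return labels


def _is_permutation(tok: str, earlier: Sequence[str],
                    suffix_rules: Sequence[str]) -> bool:
    s = stem(tok, suffix_rules)
    if len(s) < 3:
        return False
    return any(prev != tok and stem(prev, suffix_rules) == s for prev in earlier)


def cluster_switch(t: Transcript) -> tuple[float, int, float]:
    """Troyer first-two-letter clustering over all uttered tokens.

    Returns ``(mean_cluster_size, n_switches, relative_switches)``;
    ``relative_switches`` is NaN for single-token transcripts.
    """
    if not t.tokens:
        raise ValueError("cannot analyse an empty transcript")
    prefixes = [tok[:2] for tok in t.tokens]
    run_lengths: list[int] = []
    for i, p in enumerate(prefixes):
        if i == 0 or p != prefixes[i - 1]:
            run_lengths.append(1)
        else:
            run_lengths[-1] += 1
    sizes = [r - 1 for r in run_lengths]
    mean_cluster_size = sum(sizes) / len(sizes)
    n_switches = len(run_lengths) - 1
    total = len(t.tokens)
    relative = MISSING if total < 2 else 100.0 * n_switches / (total - 1)
    return mean_cluster_size, n_switches, relative


@dataclass
class ScoreCard:
    """Per-participant fluency metrics."""

    participant_id: str
    total_words: int
    correct_words: int
    n_inappropriate: int
    n_proper_noun: int
    n_permutation: int
    n_wrong_letter: int
    n_perseveration: int
    n_recurrent_perseveration: int
    pct_rulebreak: float
    pct_inappropriate: float
    pct_proper_noun: float
    pct_permutation: float
    pct_perseveration: float
    pct_lowfreq: float
    mean_cluster_size: float
    n_switches: int
    relative_switches: float
    mean_word_frequency: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def score(
    t: Transcript,
    labels: Sequence[TokenLabel],
    lexicon: Optional[FrequencyLexicon] = None,
    threshold: Optional[float] = None,
) -> ScoreCard:
    """Summarize a labelled transcript into a :class:`ScoreCard`.

    The rule-break percentage counts inappropriate words, proper nouns and
    permutations (wrong-letter words are excluded from the numerator but stay
    in the total-word denominator). The low-frequency percentage is computed
    over correct tokens only and requires a lexicon plus cohort threshold;
    without them it is NaN.
    """
    if len(labels) != len(t.tokens):
        raise ValueError("labels are not aligned with transcript tokens")
    counts = Counter(lab.label for lab in labels)
    total = len(t.tokens)
    n_corr = counts["correct"]
    n_inapp = counts["inappropriate"]
    n_pn = counts["proper_noun"]
    n_perm = counts["permutation"]
    n_wl = counts["wrong_letter"]
    n_pers = counts["perseveration"]
    n_rec = sum(1 for lab in labels if lab.label == "perseveration" and lab.recurrent)

    def pct(k: int) -> float:
        return MISSING if total == 0 else 100.0 * k / total

    correct_tokens = [tok for tok, lab in zip(t.tokens, labels) if lab.label == "correct"]
    if lexicon is not None and threshold is not None and correct_tokens:
        p_low = pct_lowfreq(correct_tokens, lexicon, threshold)
    else:
        p_low = MISSING

    if lexicon is not None:
        vals = [lexicon.transformed(tok) for tok in t.tokens]
        vals = [v for v in vals if not math.isnan(v)]
        mean_freq = sum(vals) / len(vals) if vals else MISSING
    else:
        mean_freq = MISSING

    mean_cs, n_sw, rel_sw = cluster_switch(t)
    return ScoreCard(
        participant_id=t.participant_id,
        total_words=total,
        correct_words=n_corr,
        n_inappropriate=n_inapp,
        n_proper_noun=n_pn,
        n_permutation=n_perm,
        n_wrong_letter=n_wl,
        n_perseveration=n_pers,
        n_recurrent_perseveration=n_rec,
        pct_rulebreak=pct(n_inapp + n_pn + n_perm),
        pct_inappropriate=pct(n_inapp),
        pct_proper_noun=pct(n_pn),
        pct_permutation=pct(n_perm),
        pct_perseveration=pct(n_pers),
        pct_lowfreq=p_low,
        mean_cluster_size=mean_cs,
        n_switches=n_sw,
        relative_switches=rel_sw,
        mean_word_frequency=mean_freq,
    )
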