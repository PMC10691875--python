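"""Synthetic letter-fluency cohorts.

Generates participants and transcripts whose statistical structure matches a
clinical fluency study with five groups — left frontal (LF), right frontal
(RF), left posterior (LP), right posterior (RP) and healthy controls (HC):
group-dependent correct-word totals, error-type rates (inappropriate words,
proper nouns, permutations, perseverations), low-frequency-word usage,
first-two-letter cluster structure in word order, and group age/NART
distributions. The default :func:`make_default_profiles` carry the published
group means and standard deviations; everything downstream of the generator
is therefore testable without patient data.

The synthetic lexicon is a Zipf-ranked vocabulary of pronounceable nonsense
's'-words. Its lowest-frequency decile is additionally depressed by a
``rare_gap`` factor, producing a bimodal log-frequency distribution: the
cohort-relative "two SD below the mean" threshold then falls inside the gap,
so words planted from the rare tier are exactly the ones scored as
low-frequency (see docs/methods.md for the rationale and its limits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .lexicon import FrequencyLexicon
from .scoring import DEFAULT_SUFFIX_RULES, Transcript, stem

__all__ = [
    "GROUPS",
    "GroupProfile",
    "Participant",
    "SyntheticLexicon",
    "make_default_profiles",
    "make_lexicon",
    "simulate_cohort",
    "load_wordlist",
]

GROUPS = ("LF", "RF", "LP", "RP", "HC")

#: Table-style subtype means need not sum exactly to the published rule-break
#: mean (participant-level means of ratios do not add); allow this much slack.
RULEBREAK_SUM_TOL = 0.75


def load_wordlist(name: str) -> list[str]:
    """Load a packaged fixture word list (``profanity`` or ``proper_nouns``)."""
    text = resources.files("fluencygraph.data").joinpath(f"{name}.txt").read_text()
    return [w.strip() for w in text.splitlines() if w.strip()]


@dataclass
class GroupProfile:
    """Generating parameters for one participant group.

    Percentages are per generated word (error types) or per correct word
    (``lowfreq_pct``); ``mean_correct``/``sd_correct`` parametrize the
    truncated-normal correct-word count.
    """

    group_label: str
    mean_correct: float
    sd_correct: float
    rulebreak_pct: float
    inappropriate_pct: float
    proper_noun_pct: float
    permutation_pct: float
    perseveration_pct: float
    lowfreq_pct: float
    age_mean: float
    age_sd: float
    nart_mean: float
    nart_sd: float
    n: int
    male_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        pcts = (
            self.rulebreak_pct, self.inappropriate_pct, self.proper_noun_pct,
            self.permutation_pct, self.perseveration_pct, self.lowfreq_pct,
        )
        if any(p < 0 or p > 100 for p in pcts):
            raise ValueError("all percentages must lie in [0, 100]")
        subtype_sum = self.inappropriate_pct + self.proper_noun_pct + self.permutation_pct
        if subtype_sum > self.rulebreak_pct + RULEBREAK_SUM_TOL:
            raise ValueError(
                "rule-break subtype percentages exceed rulebreak_pct beyond tolerance"
            )
        if min(self.sd_correct, self.age_sd, self.nart_sd) < 0:
            raise ValueError("sd fields must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.male_frac <= 1:
            raise ValueError("male_frac must lie in [0, 1]")


@dataclass
class Participant:
    participant_id: str
    group: str
    age: float
    nart: float
    gender: str


@dataclass
class SyntheticLexicon:
    """Ranked synthetic vocabulary with Zipf raw frequencies."""

    entries: list[tuple[str, float]]
    seed: int
    zipf_s: float = 1.0
    rare_gap: float = 1e-4

    def __post_init__(self) -> None:
        words = [w for w, _ in self.entries]
        if len(set(words)) != len(words):
            raise ValueError("lexicon words must be unique")
        if any(r <= 0 for _, r in self.entries):
            raise ValueError("raw frequencies must be strictly positive")

    @property
    def words(self) -> list[str]:
        return [w for w, _ in self.entries]

    @property
    def raw_frequencies(self) -> np.ndarray:
        return np.array([r for _, r in self.entries], dtype=float)

    @property
    def rare_start(self) -> int:
        """Index of the first rank in the depressed lowest-frequency decile."""
        return len(self.entries) - len(self.entries) // 10

    def to_frequency_lexicon(self) -> FrequencyLexicon:
        return FrequencyLexicon(dict(self.entries), source_tag=f"synthetic:seed={self.seed}")


def make_default_profiles() -> list[GroupProfile]:
    """The five published group profiles (group means/SDs of the study)."""
    return [
        GroupProfile("LF", 11.40, 5.75, 5.40, 1.47, 2.66, 1.80, 1.59, 4.37,
                     44.38, 15.26, 105.88, 12.62, 63, male_frac=39 / 63),
        GroupProfile("RF", 13.90, 5.59, 3.56, 1.56, 1.26, 0.73, 0.90, 3.67,
                     48.65, 14.93, 108.42, 10.28, 80, male_frac=40 / 80),
        GroupProfile("LP", 15.27, 4.54, 1.79, 0.69, 1.14, 0.32, 3.88, 2.30,
                     50.21, 14.72, 109.45, 14.31, 33, male_frac=23 / 33),
        GroupProfile("RP", 15.49, 4.77, 2.64, 1.16, 1.25, 0.82, 1.84, 3.06,
                     51.48, 12.87, 107.96, 11.00, 63, male_frac=37 / 63),
        GroupProfile("HC", 16.67, 4.05, 2.00, 0.46, 0.80, 0.81, 1.73, 2.48,
                     47.93, 15.38, 108.09, 9.80, 136, male_frac=60 / 136),
    ]


# second letters give ~14 two-letter onsets so cluster runs are plannable
_SECOND = "aceihklmnoptuw"
_TAIL = "abdefgilmnoprstuvz"


def _make_words(size: int, rng: np.random.Generator) -> list[str]:
    """Unique pronounceable-ish 's' nonsense words with unique stems.

    Words and stems of the packaged profanity/proper-noun fixtures are
    excluded so a sampled "correct" word can never be scored as an error.
    """
    reserved = set(load_wordlist("profanity")) | set(load_wordlist("proper_nouns"))
    words: list[str] = []
    stems: set[str] = {stem(w) for w in reserved}
    seen: set[str] = set(reserved)
    while len(words) < size:
        length = int(rng.integers(3, 8))
        w = "s" + _SECOND[rng.integers(len(_SECOND))] + "".join(
            _TAIL[rng.integers(len(_TAIL))] for _ in range(length - 2)
        )
        if w in seen:
            continue
        st = stem(w)
        if st in stems:
            continue
        seen.add(w)
        stems.add(st)
        words.append(w)
    return words


def make_lexicon(size: int, zipf_s: float = 1.0, seed: int = 0,
                 rare_gap: float = 1e-4) -> SyntheticLexicon:
    """Build a synthetic Zipf lexicon of 's'-words.

    Rank-``r`` raw frequency is proportional to ``r ** -zipf_s`` (maximum
    normalized to 1); the lowest-frequency decile is further multiplied by
    ``rare_gap`` to open a gap that makes the cohort 2-SD low-frequency
    threshold well defined. The seed controls only the word strings, not the
    frequency profile.
    """
    if size < 10:
        raise ValueError("lexicon size must be >= 10")
    if rare_gap <= 0 or rare_gap > 1:
        raise ValueError("rare_gap must lie in (0, 1]")
    ranks = np.arange(1, size + 1, dtype=float)
    freqs = ranks ** (-zipf_s)
    freqs /= freqs[0]
    n_rare = size // 10
    freqs[size - n_rare:] *= rare_gap
    rng = np.random.default_rng(seed)
    words = _make_words(size, rng)
    return SyntheticLexicon(list(zip(words, freqs.tolist())), seed=seed,
                            zipf_s=zipf_s, rare_gap=rare_gap)


def _truncnorm_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Rounded normal draw truncated at zero (>= 1 so transcripts are non-empty)."""
    if sd == 0:
        return max(1, round(mean))
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return max(1, round(x))


def _order_words(words: list[str], rng: np.random.Generator, p_stay: float) -> list[str]:
    """Two-state Markov ordering: stay in the current first-two-letter
    neighbourhood with probability ``p_stay``, otherwise switch."""
    by_prefix: dict[str, list[str]] = {}
    for w in words:
        by_prefix.setdefault(w[:2], []).append(w)
    for group in by_prefix.values():
        rng.shuffle(group)
    prefixes = sorted(by_prefix)
    current = prefixes[rng.integers(len(prefixes))]
    out: list[str] = []
    n = len(words)
    while len(out) < n:
        stay = rng.random() < p_stay and by_prefix.get(current)
        if not stay:
            others = [p for p in prefixes if p != current and by_prefix.get(p)]
            if others:
                current = others[rng.integers(len(others))]
            elif not by_prefix.get(current):
                current = next(p for p in prefixes if by_prefix.get(p))
        out.append(by_prefix[current].pop())
    return out


def _permutation_token(source: str, existing: set[str]) -> Optional[str]:
    """An inflectional variant of *source* that the suffix rules map back to
    the same stem and that is not an exact repeat of an existing token."""
    base = stem(source)
    for suf in ("ing", "ed", "s", "er", "est", "en"):
        cand = base + suf
        if cand != source and cand not in existing and stem(cand) == base:
            return cand
    return None


def simulate_cohort(
    profiles: Sequence[GroupProfile],
    lexicon: SyntheticLexicon,
    seed: int,
    p_stay: float = 0.4,
    immediate_perseveration: bool = False,
    group_lexicons: Optional[dict[str, SyntheticLexicon]] = None,
) -> tuple[list[Participant], list[Transcript]]:
    """Generate a full cohort of participants and transcripts.

    Per participant: the correct-word count is a truncated-normal draw with
    the group's moments; correct words are frequency-weighted samples without
    replacement, each independently replaced by a rare-tier word with
    probability ``lowfreq_pct / 100``; word order follows the stay/switch
    Markov process; error tokens are inserted at the profile's per-word
    rates, with permutations placed immediately after their source word and
    perseverations repeating an earlier response with at least one
    intervening token (unless ``immediate_perseveration``). ``group_lexicons``
    optionally substitutes a different lexicon for named groups, planting a
    group-specific "style" in word choice that sequence embeddings can see
    while leaving the frequency profile unchanged.

    Deterministic under ``seed``. The planted label of every token is stored
    in ``Transcript.planted`` (ground truth; never consulted by scoring).
    """
    if not lexicon.entries:
        raise ValueError("lexicon must be non-empty")
    profanity = load_wordlist("profanity")
    proper_nouns = load_wordlist("proper_nouns")
    rng = np.random.default_rng(seed)
    participants: list[Participant] = []
    transcripts: list[Transcript] = []
    for prof in profiles:
        lex = (group_lexicons or {}).get(prof.group_label, lexicon)
        raw = lex.raw_frequencies
        n_rare = len(lex.entries) - lex.rare_start
        w_common = raw[: lex.rare_start] / raw[: lex.rare_start].sum()
        w_rare = raw[lex.rare_start:] / raw[lex.rare_start:].sum() if n_rare else None
        for i in range(prof.n):
            pid = f"{prof.group_label}{i + 1:03d}"
            age = float(rng.normal(prof.age_mean, prof.age_sd))
            nart = float(rng.normal(prof.nart_mean, prof.nart_sd))
            gender = "male" if rng.random() < prof.male_frac else "female"
            tokens, planted = _simulate_transcript(
                prof, lex, w_common, w_rare, rng, p_stay, profanity,
                proper_nouns, immediate_perseveration,
            )
            participants.append(Participant(pid, prof.group_label, age, nart, gender))
            transcripts.append(Transcript(pid, tokens, planted=planted))
    return participants, transcripts


def _simulate_transcript(
    prof: GroupProfile,
    lex: SyntheticLexicon,
    w_common: np.ndarray,
    w_rare: Optional[np.ndarray],
    rng: np.random.Generator,
    p_stay: float,
    profanity: list[str],
    proper_nouns: list[str],
    immediate_perseveration: bool,
) -> tuple[list[str], list[str]]:
    m = _truncnorm_count(rng, prof.mean_correct, prof.sd_correct)
    # correct words: frequency-weighted without replacement, rare-tier swaps
    n_low = int(rng.binomial(m, prof.lowfreq_pct / 100.0)) if w_rare is not None else 0
    n_low = min(n_low, len(w_rare) if w_rare is not None else 0)
    n_common = min(m - n_low, len(w_common))
    common_idx = rng.choice(len(w_common), size=n_common, replace=False, p=w_common)
    words = [lex.entries[j][0] for j in common_idx]
    if n_low:
        rare_idx = rng.choice(len(w_rare), size=n_low, replace=False, p=w_rare)
        words += [lex.entries[lex.rare_start + j][0] for j in rare_idx]
    ordered = _order_words(words, rng, p_stay)
    seq: list[str] = list(ordered)
    labels: list[str] = ["correct"] * len(seq)

    # error counts: per-word binomials over the expected total word count
    p_err = (prof.inappropriate_pct + prof.proper_noun_pct
             + prof.permutation_pct + prof.perseveration_pct) / 100.0
    t0 = max(len(seq), round(len(seq) / max(1e-9, 1.0 - p_err)))
    e_inapp = int(rng.binomial(t0, prof.inappropriate_pct / 100.0))
    e_pn = int(rng.binomial(t0, prof.proper_noun_pct / 100.0))
    e_perm = min(int(rng.binomial(t0, prof.permutation_pct / 100.0)), len(ordered))
    e_pers = int(rng.binomial(t0, prof.perseveration_pct / 100.0))

    def stems_in_use() -> set[str]:
        return {stem(tok) for tok in seq}

    def insert(pos: int, tok: str, lab: str) -> None:
        seq.insert(pos, tok)
        labels.insert(pos, lab)

    # inappropriate words and proper nouns at uniform positions
    for pool, lab, count in ((profanity, "inappropriate", e_inapp),
                             (proper_nouns, "proper_noun", e_pn)):
        used = stems_in_use()
        candidates = [w for w in pool if w not in seq and stem(w) not in used]
        rng.shuffle(candidates)
        for tok in candidates[:count]:
            insert(int(rng.integers(0, len(seq) + 1)), tok, lab)

    # permutations immediately after their source (distinct correct sources)
    sources = list(rng.choice(len(ordered), size=e_perm, replace=False)) if e_perm else []
    for src_idx in sources:
        src = ordered[src_idx]
        tok = _permutation_token(src, set(seq))
        if tok is None:
            continue
        insert(seq.index(src) + 1, tok, "permutation")

    # perseverations: repeat an earlier response, >= 1 intervening by default
    for _ in range(e_pers):
        min_pos = 1 if immediate_perseveration else 2
        if len(seq) < min_pos:
            continue
        pos = int(rng.integers(min_pos, len(seq) + 1))
        src_pos = pos - 1 if immediate_perseveration else int(rng.integers(0, pos - 1))
        insert(pos, seq[src_pos], "perseveration")

    return seq, labels
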