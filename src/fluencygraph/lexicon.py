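"""Word-frequency lookup, the decimal-log frequency transform and the
cohort-relative low-frequency rule.

Raw corpus frequencies (probabilities in ``(0, 1]``) are mapped to a decimal
log scale anchored at one-per-billion: ``transform_frequency(raw) =
log10(raw * 1e9)``, so a word occurring once per billion tokens scores 0 and
one per hundred thousand scores 4. Words absent from the lexicon carry a
missing marker (NaN) and are excluded from all summary statistics.

A *low-frequency* word is a correct response whose transformed frequency lies
at least two sample standard deviations below the mean of the pooled
transformed frequencies of every correct word produced by the whole cohort
(token-level pooling, patients and controls together). The boundary is
inclusive: a value exactly at ``mean - 2*SD`` counts as low-frequency.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MISSING",
    "FrequencyLexicon",
    "normalize_token",
    "transform_frequency",
    "lowfreq_threshold",
    "pct_lowfreq",
]

#: Marker for words absent from the lexicon ("not a number").
MISSING = float("nan")

_PUNCT = re.compile(r"[^a-z']")


def normalize_token(token: str) -> str:
    """Lowercase a token and strip punctuation (apostrophes are kept)."""
    return _PUNCT.sub("", token.lower())


def transform_frequency(raw: float | None) -> float:
    """Decimal-log transform of a raw corpus frequency.

    Parameters
    ----------
    raw
        Raw word frequency in ``(0, 1]``, or ``None``/NaN for an absent word.

    Returns
    -------
    float
        ``log10(raw * 1e9)``, or NaN for absent words.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return MISSING
    if raw <= 0:
        raise ValueError(f"raw frequency must be positive, got {raw!r}")
    return math.log10(raw * 1e9)


@dataclass
class FrequencyLexicon:
    """Case-insensitive mapping from word to raw corpus frequency."""

    frequencies: Mapping[str, float]
    source_tag: str = "synthetic"
    _table: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        table = {}
        for word, raw in self.frequencies.items():
            if raw <= 0:
                raise ValueError(f"non-positive frequency for {word!r}")
            table[normalize_token(word)] = float(raw)
        self._table = table

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, word: str) -> bool:
        return normalize_token(word) in self._table

    def raw(self, word: str) -> float:
        """Raw frequency of *word*, NaN if absent."""
        return self._table.get(normalize_token(word), MISSING)

    def transformed(self, word: str) -> float:
        """Decimal-log transformed frequency of *word*, NaN if absent."""
        return transform_frequency(self._table.get(normalize_token(word)))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path, source_tag: str | None = None) -> "FrequencyLexicon":
        """Load a two-column ``word<TAB>raw_frequency`` table."""
        path = Path(path)
        freqs = {}
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            word, raw = line.split("\t")
            freqs[word] = float(raw)
        return cls(freqs, source_tag=source_tag or path.name)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{w}\t{r:.12g}" for w, r in sorted(self._table.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_wordfreq(cls, words: Iterable[str], lang: str = "en") -> "FrequencyLexicon":
        """Fill a lexicon from the ``wordfreq`` corpus package, if installed.

        This adapter is a convenience for real transcripts; the packaged
        synthetic lexicon is the default and the test suite never calls this.
        """
        try:
            from wordfreq import word_frequency  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the optional 'wordfreq' package is required for "
                "FrequencyLexicon.from_wordfreq"
            ) from exc
        freqs = {}
        for w in words:  # pragma: no cover - optional dependency
            f = word_frequency(w, lang)
            if f > 0:
                freqs[w] = f
        return cls(freqs, source_tag=f"wordfreq:{lang}")  # pragma: no cover


def lowfreq_threshold(transformed: Iterable[float]) -> float:
    """Low-frequency cut-off: ``mean - 2*SD`` of pooled transformed values.

    Missing markers (NaN) are excluded; the SD uses the sample (``n - 1``)
    formula. At least two non-missing values are required.
    """
    vals = np.asarray([v for v in transformed if not math.isnan(v)], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two non-missing frequencies")
    return float(vals.mean() - 2.0 * vals.std(ddof=1))


def pct_lowfreq(correct_words: Iterable[str], lexicon: FrequencyLexicon,
                threshold: float) -> float:
    """Percentage of correct words at or below the low-frequency threshold.

    Words missing from the lexicon are never counted as low-frequency but
    remain in the denominator. Returns NaN for an empty word list.
    """
    words = list(correct_words)
    if not words:
        return MISSING
    n_low = 0
    for w in words:
        v = lexicon.transformed(w)
        if not math.isnan(v) and v <= threshold:
            n_low += 1
    return 100.0 * n_low / len(words)
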