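"""Independent brute-force oracles for the test suite.

Deliberately naive re-implementations (nested loops, no shared helpers with
the package) used to cross-check the scoring pipeline, the Mann-Whitney U
statistic and the chi-square statistic.
"""

from __future__ import annotations

import math

SUFFIXES = ("ing", "ings", "ed", "er", "ers", "est", "en", "s", "es", "'s")


def oracle_stem(word: str) -> str:
    for suf in SUFFIXES:
        if word.endswith(suf):
            remainder = word[: len(word) - len(suf)]
            if len(remainder) >= 3:
                return remainder
    return word


def oracle_labels(tokens, profanity, proper, target="s"):
    out = []
    for i in range(len(tokens)):
        tok = tokens[i]
        repeated = False
        for j in range(i):
            if tokens[j] == tok:
                repeated = True
        if repeated:
            recurrent = tokens[i - 1] != tok
            out.append(("perseveration", recurrent))
            continue
        if tok in profanity:
            out.append(("inappropriate", None))
            continue
        if tok in proper:
            out.append(("proper_noun", None))
            continue
        perm = False
        for j in range(i):
            if tokens[j] != tok and oracle_stem(tokens[j]) == oracle_stem(tok) \
                    and len(oracle_stem(tok)) >= 3:
                perm = True
        if perm:
            out.append(("permutation", None))
            continue
        if not tok.startswith(target):
            out.append(("wrong_letter", None))
            continue
        out.append(("correct", None))
    return out


def oracle_scorecard(tokens, profanity, proper, lexicon=None, threshold=None):
    """Full recount: counts, percentages and cluster/switch statistics."""
    labs = oracle_labels(tokens, profanity, proper)
    counts = {}
    for lab, _ in labs:
        counts[lab] = counts.get(lab, 0) + 1
    total = len(tokens)
    n_corr = counts.get("correct", 0)
    n_in = counts.get("inappropriate", 0)
    n_pn = counts.get("proper_noun", 0)
    n_pm = counts.get("permutation", 0)
    n_wl = counts.get("wrong_letter", 0)
    n_ps = counts.get("perseveration", 0)
    n_rec = sum(1 for lab, rec in labs if lab == "perseveration" and rec)
    card = {
        "total_words": total,
        "correct_words": n_corr,
        "n_inappropriate": n_in,
        "n_proper_noun": n_pn,
        "n_permutation": n_pm,
        "n_wrong_letter": n_wl,
        "n_perseveration": n_ps,
        "n_recurrent_perseveration": n_rec,
        "pct_rulebreak": 100.0 * (n_in + n_pn + n_pm) / total,
        "pct_inappropriate": 100.0 * n_in / total,
        "pct_proper_noun": 100.0 * n_pn / total,
        "pct_permutation": 100.0 * n_pm / total,
        "pct_perseveration": 100.0 * n_ps / total,
    }
    # low-frequency percentage over correct tokens (inclusive boundary)
    if lexicon is not None and threshold is not None and n_corr > 0:
        n_low = 0
        for tok, (lab, _) in zip(tokens, labs):
            if lab == "correct":
                v = lexicon.transformed(tok)
                if not math.isnan(v) and v <= threshold:
                    n_low += 1
        card["pct_lowfreq"] = 100.0 * n_low / n_corr
    else:
        card["pct_lowfreq"] = float("nan")
    # clusters: maximal runs sharing the first two letters
    runs = []
    for i, tok in enumerate(tokens):
        if i > 0 and tok[:2] == tokens[i - 1][:2]:
            runs[-1] += 1
        else:
            runs.append(1)
    sizes = [r - 1 for r in runs]
    card["mean_cluster_size"] = sum(sizes) / len(sizes)
    card["n_switches"] = len(runs) - 1
    card["relative_switches"] = (
        float("nan") if total < 2 else 100.0 * (len(runs) - 1) / (total - 1)
    )
    return card


def oracle_mannwhitney_u(x, y):
    """U statistic of x by exhaustive pair counting (ties count half)."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def oracle_chi2(table):
    """Chi-square by the direct sum((O - E)^2 / E) formula."""
    rows = len(table)
    cols = len(table[0])
    n = sum(sum(r) for r in table)
    chi2 = 0.0
    for i in range(rows):
        for j in range(cols):
            e = sum(table[i]) * sum(table[k][j] for k in range(rows)) / n
            chi2 += (table[i][j] - e) ** 2 / e
    return chi2


def random_transcript(rng, profanity, proper, lexicon_words):
    """A random token sequence mixing every label type, repeats included."""
    n = int(rng.integers(1, 30))
    tokens = []
    for _ in range(n):
        kind = rng.random()
        if kind < 0.62 or not tokens:
            tokens.append(lexicon_words[rng.integers(len(lexicon_words))])
        elif kind < 0.72:
            tokens.append(profanity[rng.integers(len(profanity))])
        elif kind < 0.80:
            tokens.append(proper[rng.integers(len(proper))])
        elif kind < 0.88:  # inflectional variant of an earlier token
            base = tokens[rng.integers(len(tokens))]
            tokens.append(base + ("es" if base.endswith("s") else "s"))
        elif kind < 0.94:  # exact repeat
            tokens.append(tokens[rng.integers(len(tokens))])
        else:  # wrong letter
            tokens.append("tree" + str(rng.integers(100)))
    return tokens
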