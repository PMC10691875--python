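"""Token classification, percentage metrics and Troyer cluster/switch."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fluencygraph as fg
from fluencygraph import Transcript, classify_tokens, cluster_switch, score, stem

from _oracles import oracle_scorecard, random_transcript


def labels_of(tokens, profanity, proper, **kw):
    return [l.label for l in
            classify_tokens(Transcript("t", tokens), profanity, proper, **kw)]


class TestClassification:
    def test_inflectional_variant_is_permutation(self, profanity, proper_nouns):
        assert labels_of(["say", "saying"], profanity, proper_nouns) == \
            ["correct", "permutation"]

    def test_recurrent_perseveration(self, profanity, proper_nouns):
        labs = classify_tokens(Transcript("t", ["sun", "sea", "sun"]),
                               profanity, proper_nouns)
        assert [l.label for l in labs] == ["correct", "correct", "perseveration"]
        assert labs[2].recurrent is True

    def test_immediate_repeat_not_recurrent(self, profanity, proper_nouns):
        labs = classify_tokens(Transcript("t", ["sun", "sun"]),
                               profanity, proper_nouns)
        assert labs[1].label == "perseveration" and labs[1].recurrent is False

    def test_wrong_letter(self, profanity, proper_nouns):
        assert labels_of(["sea", "tree"], profanity, proper_nouns) == \
            ["correct", "wrong_letter"]

    def test_list_membership(self, profanity, proper_nouns):
        assert labels_of(["sod", "samantha"], profanity, proper_nouns) == \
            ["inappropriate", "proper_noun"]

    def test_repeat_takes_precedence_over_profanity(self, profanity, proper_nouns):
        assert labels_of(["sod", "sea", "sod"], profanity, proper_nouns)[2] == \
            "perseveration"

    def test_manual_annotation_overrides(self, profanity, proper_nouns):
        t = Transcript("t", ["sushi"], annotations={0: "proper_noun"})
        assert classify_tokens(t, profanity, proper_nouns)[0].label == "proper_noun"

    def test_empty_transcript_rejected(self, profanity, proper_nouns):
        with pytest.raises(ValueError):
            classify_tokens(Transcript("t", []), profanity, proper_nouns)

    def test_list_order_irrelevant(self, profanity, proper_nouns, rng, lexicon):
        toks = random_transcript(rng, profanity, proper_nouns, lexicon.words)
        a = labels_of(toks, profanity, proper_nouns)
        b = labels_of(toks, list(reversed(profanity)), list(reversed(proper_nouns)))
        assert a == b

    def test_stem_rules(self):
        assert stem("saying") == "say"
        assert stem("singers") == "sing"
        assert stem("say") == "say"   # too short to strip further


class TestClusterSwitch:
    def test_published_example(self):
        # "snore, snail, show": one cluster of size 1 plus a singleton
        mean_cs, n_sw, rel = cluster_switch(Transcript("t", ["snore", "snail", "show"]))
        assert mean_cs == pytest.approx(0.5)
        assert n_sw == 1
        assert rel == pytest.approx(50.0)

    def test_single_token(self):
        mean_cs, n_sw, rel = cluster_switch(Transcript("t", ["sun"]))
        assert mean_cs == 0.0 and n_sw == 0 and math.isnan(rel)

    def test_shared_two_letter_onset(self):
        mean_cs, n_sw, rel = cluster_switch(
            Transcript("t", ["sing", "sling", "sled", "sea"]))
        assert mean_cs == pytest.approx(1.0 / 3.0)
        assert n_sw == 2
        assert rel == pytest.approx(200.0 / 3.0)


class TestScoreCard:
    def test_simple_percentage(self, profanity, proper_nouns):
        toks = ["sod", "samantha"] + [f"s{i}x" for i in range(8)]
        t = Transcript("t", toks)
        card = score(t, classify_tokens(t, profanity, proper_nouns))
        assert card.pct_rulebreak == pytest.approx(20.0)

    def test_error_free_transcript(self, profanity, proper_nouns):
        t = Transcript("t", ["sea", "sun", "silk"])
        card = score(t, classify_tokens(t, profanity, proper_nouns))
        assert card.correct_words == card.total_words == 3
        assert card.pct_rulebreak == card.pct_perseveration == 0.0

    def test_hand_built_twelve_token_transcript(self, profanity, proper_nouns):
        toks = ["sun", "sea", "sod", "samantha", "say", "saying",
                "salt", "sun", "sand", "silk", "sock", "sip"]
        t = Transcript("t", toks)
        labels = classify_tokens(t, profanity, proper_nouns)
        card = score(t, labels)
        assert card.pct_rulebreak == pytest.approx(25.0)
        assert card.pct_perseveration == pytest.approx(100.0 / 12.0)
        assert card.correct_words == 8
        assert card.n_recurrent_perseveration == 1

    def test_counts_partition_total(self, profanity, proper_nouns, rng, lexicon):
        for _ in range(50):
            toks = random_transcript(rng, profanity, proper_nouns, lexicon.words)
            t = Transcript("t", toks)
            card = score(t, classify_tokens(t, profanity, proper_nouns))
            parts = (card.correct_words + card.n_inappropriate + card.n_proper_noun
                     + card.n_permutation + card.n_wrong_letter
                     + card.n_perseveration)
            assert parts == card.total_words
            assert card.n_switches >= 0
            if not math.isnan(card.relative_switches):
                assert 0.0 <= card.relative_switches <= 100.0

    def test_matches_bruteforce_recount(self, profanity, proper_nouns, rng,
                                        lexicon, freq_lexicon):
        for _ in range(100):
            toks = random_transcript(rng, profanity, proper_nouns, lexicon.words)
            t = Transcript("t", toks)
            card = score(t, classify_tokens(t, profanity, proper_nouns),
                         freq_lexicon, threshold=5.0)
            expected = oracle_scorecard(toks, set(profanity), set(proper_nouns),
                                        freq_lexicon, threshold=5.0)
            for key, val in expected.items():
                got = getattr(card, key)
                if isinstance(val, float) and math.isnan(val):
                    assert math.isnan(got)
                else:
                    assert got == val, key

    def test_misaligned_labels_rejected(self, profanity, proper_nouns):
        t = Transcript("t", ["sea", "sun"])
        labels = classify_tokens(t, profanity, proper_nouns)
        with pytest.raises(ValueError):
            score(Transcript("t", ["sea"]), labels)


@given(st.lists(st.sampled_from(["sun", "sea", "say", "saying", "sod", "tree",
                                 "samantha", "snore", "snail"]),
                min_size=1, max_size=15))
def test_every_token_gets_exactly_one_label(tokens):
    t = Transcript("t", tokens)
    labels = classify_tokens(t, {"sod"}, {"samantha"})
    assert len(labels) == len(tokens)
    assert all(l.label in fg.LABELS for l in labels)
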