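import numpy as np
import pytest
from hypothesis import settings

import fluencygraph as fg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return fg.make_lexicon(1000, 1.0, seed=3)


@pytest.fixture(scope="session")
def freq_lexicon(lexicon):
    return lexicon.to_frequency_lexicon()


@pytest.fixture(scope="session")
def profanity():
    return fg.load_wordlist("profanity")


@pytest.fixture(scope="session")
def proper_nouns():
    return fg.load_wordlist("proper_nouns")


@pytest.fixture(scope="session")
def small_cohort(lexicon):
    """20 participants per group, fixed seed."""
    profiles = fg.make_default_profiles()
    for p in profiles:
        p.n = 20
    return fg.simulate_cohort(profiles, lexicon, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
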