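import numpy as np
import pytest
from hypothesis import settings

import flscan as fl

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def uniform_bg():
    return fl.Background.uniform()


@pytest.fixture(scope="session")
def gata3():
    """The packaged GATA-3 example PWM with its published background."""
    return fl.gata3_matrix(), fl.gata3_background()


def exact_match_matrix(word: str, scale_digits: int = 3) -> "fl.ScoringMatrix":
    """0/1 scoring matrix: 1 for the word's symbol at each position, 0 otherwise.

    With threshold k = len(word) this reduces PWM search to plain substring
    matching.
    """
    idx = {s: i for i, s in enumerate(fl.ALPHABET)}
    scores = np.zeros((len(word), 4))
    for i, s in enumerate(word):
        scores[i, idx[s]] = 1.0
    return fl.ScoringMatrix(scores, scale_digits=scale_digits)


def random_scoring_matrix(rng, width, scale_digits=3, low=-4.0, high=4.0):
    """Arbitrary real-valued PWM (not necessarily log-odds of anything)."""
    return fl.ScoringMatrix(rng.uniform(low, high, size=(width, 4)), scale_digits=scale_digits)


def enumerate_score_distribution(M, bg):
    """Brute-force distribution of the integer k-mer score over all 4^n words.

    Independent oracle for the threshold dynamic program: outer-sums the
    per-column integer scores and outer-multiplies the background
    probabilities.
    """
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for i in range(M.width):
        scores = (scores[:, None] + M.int_scores[i][None, :]).ravel()
        probs = (probs[:, None] * bg.probs[None, :]).ravel()
    return scores, probs
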