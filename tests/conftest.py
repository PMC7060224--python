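import numpy as np
import pandas as pd
import pytest

from oculoread.simulate import FIXATION_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_report(word_seq, xs=None, durations=None, word_lengths=None, trial=1):
    """Build a one-trial fixation report from a word-index sequence."""
    n = len(word_seq)
    if xs is None:
        xs = [float(6 * w) for w in word_seq]
    if durations is None:
        durations = [250.0] * n
    if word_lengths is None:
        word_lengths = [5] * n
    return pd.DataFrame(
        {
            "subject": 1,
            "session": 1,
            "trial": trial,
            "fix_index": range(1, n + 1),
            "x_col": xs,
            "duration_ms": durations,
            "word_index": word_seq,
            "letter_index": 3,
            "word_length": word_lengths,
        },
        columns=FIXATION_COLUMNS,
    )


@pytest.fixture
def toy_report():
    """Words 1,2,3,3,1: two forward saccades, one refixation, one regression."""
    return make_report([1, 2, 3, 3, 1])
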