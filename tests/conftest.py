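"""Shared fixtures: synthetic corpora scored once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from fallkit.evaluate import score_corpus
from fallkit.synthetic import default_corpus, hard_corpus

CORPUS_SEED = 1
HARD_SEED = 2


@pytest.fixture(scope="session")
def default_scored() -> pd.DataFrame:
    """The default separable corpus (40 ADL / 20 fall files), veto on."""
    recordings, _ = default_corpus(seed=CORPUS_SEED)
    return score_corpus(recordings, veto=True)


@pytest.fixture(scope="session")
def hard_scored() -> dict[str, pd.DataFrame]:
    """The hard corpus scored with and without the periodicity veto."""
    recordings, _ = hard_corpus(seed=HARD_SEED)
    return {
        "on": score_corpus(recordings, veto=True),
        "off": score_corpus(recordings, veto=False),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
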