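import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from metamd import Corpus, MetaAnalysisGroup, TrialSummary


def make_trial(review="r1", study="s1", n_t=10, mean_t=11.0, sd_t=1.0,
               n_c=10, mean_c=10.0, sd_c=1.0) -> TrialSummary:
    return TrialSummary(review_id=review, study_id=study, n_t=n_t, mean_t=mean_t,
                        sd_t=sd_t, n_c=n_c, mean_c=mean_c, sd_c=sd_c)


def make_group(review="r1", rows=((10, 11, 1, 10, 10, 1),) * 3) -> MetaAnalysisGroup:
    trials = tuple(
        make_trial(review, f"s{i + 1}", n_t, m_t, s_t, n_c, m_c, s_c)
        for i, (n_t, m_t, s_t, n_c, m_c, s_c) in enumerate(rows)
    )
    return MetaAnalysisGroup(review_id=review, trials=trials)


def random_group(rng: np.random.Generator, review="r1", k=None) -> MetaAnalysisGroup:
    """A random valid group with dispersed sizes, means and SDs."""
    k = k if k is not None else int(rng.integers(3, 11))
    trials = []
    for i in range(k):
        n_t, n_c = (int(rng.integers(2, 200)) for _ in range(2))
        sd_t, sd_c = (float(np.exp(rng.normal(0, 1))) for _ in range(2))
        m_t, m_c = (float(rng.normal(0, 2)) for _ in range(2))
        trials.append(make_trial(review, f"s{i + 1}", n_t, m_t, sd_t, n_c, m_c, sd_c))
    return MetaAnalysisGroup(review_id=review, trials=tuple(trials))


@pytest.fixture
def homogeneous_group():
    """Three trials with identical arm summaries: zero heterogeneity."""
    return make_group()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_corpus(rng):
    groups = [random_group(rng, review=f"r{i}") for i in range(5)]
    return Corpus.from_groups(groups)
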