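import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from swayscore.signal import RawTrace
from swayscore.synthetic import CohortConfig, PhenotypeParams, simulate_trace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_raw_trace(rng, n=60, span=4.0, condition="open"):
    """An irregular random trace: sorted uniform timestamps, Gaussian walk."""
    t = np.sort(rng.uniform(0.0, span, size=n))
    t[0], t[-1] = 0.0, span
    while np.any(np.diff(t) <= 0):  # enforce strict increase
        t = np.sort(rng.uniform(0.0, span, size=n))
        t[0], t[-1] = 0.0, span
    ml = np.cumsum(rng.normal(0, 0.1, size=n)) + 2.0
    ap = np.cumsum(rng.normal(0, 0.1, size=n))
    return RawTrace(timestamps=t, ml=ml, ap=ap, condition=condition)


def short_cohort_config(seed=0, seconds=10.0, **kw):
    """Small, fast cohort settings for unit tests."""
    return CohortConfig(n_subjects=kw.pop("n_subjects", 10),
                        record_seconds=seconds, seed=seed, **kw)


@pytest.fixture
def grid_trace():
    """A trace sampled exactly on the 25 Hz grid."""
    rng = np.random.default_rng(7)
    n = 100
    t = np.arange(n) / 25.0
    return RawTrace(timestamps=t, ml=rng.normal(size=n),
                    ap=rng.normal(size=n))
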