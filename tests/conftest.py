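"""Shared fixtures: one small simulated study reused across test modules."""

import numpy as np
import pytest

from tipscan import detect, simulate


@pytest.fixture(scope="session")
def small_study():
    """A reduced panel (400 kb, 4 accessions, 12 loci) for module tests."""
    return simulate.simulate_study(seed=7, length=400_000, n_accessions=4,
                                   n_loci=12, repeat_fraction=0.3)


@pytest.fixture(scope="session")
def small_detection(small_study):
    return detect.detect_tips(small_study.reads, small_study.library,
                              small_study.reference.genome)


@pytest.fixture(scope="session")
def trio():
    return simulate.simulate_trio(seed=3, per_category=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
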