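import pytest

from mirsat import (
    CompositionProfile,
    ReadAligner,
    SimConfig,
    build_decoys,
    build_reference,
    simulate_abundances,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_ref():
    return build_reference(20, length_range=(20, 23), seed=3)


@pytest.fixture(scope="session")
def small_profile(small_ref):
    return simulate_abundances(small_ref, seed=4)


@pytest.fixture(scope="session")
def small_decoys(small_ref):
    return build_decoys(small_ref, n_ncrna=30, n_repeat=15, n_unclassified=40, seed=5)


@pytest.fixture(scope="session")
def small_aligner(small_ref, small_decoys):
    return ReadAligner(small_ref, ncrna=small_decoys.ncrna, repeat=small_decoys.repeat)


@pytest.fixture(scope="session")
def muscle_library(small_ref, small_profile, small_decoys):
    """A 20k-read muscle-like library with its truth ledger."""
    cfg = SimConfig(n_reads=20_000, seed=7)
    return simulate_library(small_ref, small_profile,
                            CompositionProfile.muscle_like(), cfg, decoys=small_decoys)
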