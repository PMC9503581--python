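import pytest

from ssassign.model import ProteinSequence
from ssassign.profiles import get_profile
from ssassign.statistics import load_statistics
from ssassign.synth import SyntheticOptions, generate_peaklists, synthetic_shift_table

# the twelve experiments of the synthetic benchmark protocol
BENCHMARK_EXPERIMENTS = [
    "CC", "NCA", "NCACB-2D", "NCO", "NCACB-3D", "NCACX",
    "NCACO", "CANCO", "CANCOCX", "NCOCA", "NCOCACB", "NCOCX",
]


@pytest.fixture(scope="session")
def stats():
    return load_statistics()


@pytest.fixture(scope="session")
def seq10():
    return ProteinSequence("MQYKLILNGK")


@pytest.fixture(scope="session")
def seq24():
    return ProteinSequence("MQIFVKTLTGKTITLEVEPSDTIE")


@pytest.fixture(scope="session")
def table10(seq10, stats):
    return synthetic_shift_table(seq10, stats, seed=11)


@pytest.fixture(scope="session")
def table24(seq24, stats):
    return synthetic_shift_table(seq24, stats, seed=7)


@pytest.fixture(scope="session")
def clean_lists24(table24, seq24):
    profiles = [get_profile(e) for e in BENCHMARK_EXPERIMENTS]
    return list(generate_peaklists(table24, seq24, profiles,
                                   SyntheticOptions(seed=5)).values())


@pytest.fixture(scope="session")
def clean_lists10(table10, seq10):
    profiles = [get_profile(e) for e in BENCHMARK_EXPERIMENTS]
    return list(generate_peaklists(table10, seq10, profiles,
                                   SyntheticOptions(seed=5)).values())
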