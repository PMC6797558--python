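import pytest
from hypothesis import HealthCheck, settings

from totiscan.comparative import compare_genomes
from totiscan.orf_annotation import derive_architecture, find_orfs
from totiscan.prf_scanner import detect_prf
from totiscan.synthetic_data import generate_isolate_pair, tktv1_architecture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tktv1_arch():
    return tktv1_architecture(seed=1)


@pytest.fixture(scope="session")
def fixture_pair(tktv1_arch):
    """The synthetic totivirus fixture genome and its companion isolate."""
    return generate_isolate_pair(tktv1_arch)


@pytest.fixture(scope="session")
def fixture_genome(fixture_pair):
    return fixture_pair[0]


@pytest.fixture(scope="session")
def fixture_orfs(fixture_genome):
    return find_orfs(fixture_genome)


@pytest.fixture(scope="session")
def fixture_architecture(fixture_genome, fixture_orfs):
    return derive_architecture(fixture_genome, fixture_orfs)


@pytest.fixture(scope="session")
def fixture_signal(fixture_genome, fixture_orfs):
    return detect_prf(fixture_genome, fixture_orfs[0])


@pytest.fixture(scope="session")
def fixture_comparison(fixture_pair, fixture_architecture):
    genome, mutant = fixture_pair
    return compare_genomes(genome, mutant, fixture_architecture)
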