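import pytest
from hypothesis import HealthCheck, settings

from mitokit.synthetic_data import CRSpec, GenomeSpec, generate_genome

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome_and_truth():
    """One default synthetic mitogenome shared across tests."""
    return generate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def genome(genome_and_truth):
    return genome_and_truth[0]


@pytest.fixture(scope="session")
def truth(genome_and_truth):
    return genome_and_truth[1]


@pytest.fixture(scope="session")
def genome_with_repeat():
    """Genome whose CR carries a planted 10-bp x 4 tandem repeat."""
    spec = GenomeSpec(seed=7, cr=CRSpec(tandem_repeat=(10, 4.0, 250)))
    return generate_genome(spec)
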