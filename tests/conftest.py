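import pytest
from hypothesis import HealthCheck, settings

from circscreen import pipeline
from circscreen.simulate import SimConfig, simulate_study

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_chroms=2, chrom_len=35_000, n_genes=14, n_circles=6)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A light four-library study for unit tests."""
    return simulate_study(
        config=small_config, seed=11,
        n_linear_total=2_000, n_linear_rnc=6_000, n_linear_control=1_000,
    )


@pytest.fixture(scope="session")
def small_analysis(small_study):
    return pipeline.analyze_study(small_study)


@pytest.fixture(scope="session")
def demo_study():
    """The packaged demo simulation at full desk scale (~200k reads)."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def demo_analysis(demo_study):
    return pipeline.analyze_study(demo_study)


def planted_key(circ):
    """Candidate-style id for a planted circle."""
    return f"{circ.chrom}:{circ.acceptor}-{circ.donor}:{circ.strand}"
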