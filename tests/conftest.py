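"""Shared fixtures: small synthetic datasets built at test time."""

import pytest

from lysvote import SubstrateVotingModel, SynthConfig, generate_fixture


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A fast planted-signal fixture for unit tests (not the benchmark size)."""
    return SynthConfig(
        n_proteins=60,
        protein_length=(120, 200),
        n_substrate_proteins=10,
        n_candidates=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return generate_fixture(small_config)


@pytest.fixture(scope="session")
def small_model(small_fixture) -> SubstrateVotingModel:
    return SubstrateVotingModel.from_fixture(small_fixture, K=3, cutoff=2)


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit(seed=3)


@pytest.fixture(scope="session")
def benchmark_fixture():
    """The standard planted-signal benchmark conditions."""
    return generate_fixture(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def null_fixture():
    """Same shape as the benchmark, with nothing planted."""
    return generate_fixture(SynthConfig(seed=42).null())
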