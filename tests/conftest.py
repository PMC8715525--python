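import pytest

from silkscreen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def bench():
    """One default-condition benchmark instance shared across tests."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_bench():
    """A reduced instance for pipeline tests that need speed, not scale."""
    return generate_dataset(
        SynthConfig(seed=7, n_decoys=40, decoy_transcripts_per_species=8, n_species=3)
    )
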