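import pytest

from pseudopipe import GenomeLayout, ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic scenario (seed 0, dropout 0)."""
    return generate_scenario(ScenarioConfig(seed=0))


@pytest.fixture(scope="session")
def dropout_scenario():
    """Default scenario with per-(exon, species) presence dropout 0.1."""
    return generate_scenario(ScenarioConfig(seed=1, dropout=0.1))


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 100_000, "chrX": 50_000, "chrY": 20_000})
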