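import pytest

from exonweaver import PenaltyScheme, SearchParams, generate_gene


@pytest.fixture(scope="session")
def scheme():
    return PenaltyScheme()


@pytest.fixture(scope="session")
def small_scheme():
    """Reduced minimum intron length so tiny oracle instances can splice."""
    return PenaltyScheme(min_intron_len=5)


@pytest.fixture(scope="session")
def default_params():
    return SearchParams()


@pytest.fixture(scope="session")
def three_intron_fixture():
    """A 150-aa gene with GT---AG and GC---AG introns in all three phases."""
    return generate_gene(
        seed=3,
        protein_length=150,
        n_introns=3,
        border_patterns=(("GT", "AG"), ("GC", "AG"), ("GT", "AG")),
        phases=(0, 1, 2),
    )
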