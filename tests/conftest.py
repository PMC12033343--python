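import pytest

from slocus_kit import synthetic_data as synth


@pytest.fixture(scope="session")
def pru_locus():
    """Synthetic Prunus-type locus (genome, models, truth), seed 0."""
    return synth.generate_locus(synth.default_pru_design(0))


@pytest.fixture(scope="session")
def mal_locus():
    """Synthetic Maleae-type locus with one planted 20 kb duplication."""
    return synth.generate_locus(synth.default_mal_design(0))


@pytest.fixture(scope="session")
def screen_refs():
    return synth.screen_references()


@pytest.fixture(scope="session")
def lineage_refs():
    return synth.lineage_references()
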