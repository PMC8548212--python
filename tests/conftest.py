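import pytest

from fusionsplice.synthetic_data import LocusSpec, build_fixture_genome


@pytest.fixture(scope="session")
def locus():
    """The default engineered mini-locus (seed 1), shared across the suite."""
    return build_fixture_genome(LocusSpec(), seed=1)


@pytest.fixture(scope="session")
def model(locus):
    return locus.model


@pytest.fixture(scope="session")
def templates(locus):
    """The three named isoform templates keyed by isoform name."""
    return locus.isoform_templates()
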