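import pytest

from indelpop import fixture_study, fixture_table1


@pytest.fixture(scope="session")
def study():
    """(FreqTable, reconstructed GenotypeCounts, DA DistanceMatrix)."""
    return fixture_study()


@pytest.fixture(scope="session")
def table1():
    """The packaged 30-locus summary table as a DataFrame."""
    return fixture_table1()


@pytest.fixture(scope="session")
def study_counts(study):
    return study[1]


@pytest.fixture(scope="session")
def da_fixture(study):
    return study[2]
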