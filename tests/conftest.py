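import pytest

from ibmfs import build_reference_fixture, classify, load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def fixture_cohort():
    records, intended = build_reference_fixture()
    return records, intended


@pytest.fixture(scope="session")
def fixture_results(fixture_cohort, catalog):
    records, _ = fixture_cohort
    return [classify(r, catalog) for r in records]
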