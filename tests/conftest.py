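import pytest

from pvdose import category_counts, load_default_taxonomy, reference_fixture


@pytest.fixture(scope="session")
def taxonomy():
    return load_default_taxonomy()


@pytest.fixture(scope="session")
def fixture_ds():
    """Dataset of the published DOAC dosing-error counts."""
    return reference_fixture()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_ds, taxonomy):
    return category_counts(fixture_ds, taxonomy)
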