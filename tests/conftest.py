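import pytest

from nodulestrat import (
    packaged_counts_spec,
    reconstruct_fixture,
    reduce_to_index,
)
from nodulestrat.brock import brock_for_cohort


@pytest.fixture(scope="session")
def counts_spec():
    return packaged_counts_spec()


@pytest.fixture(scope="session")
def fixture_cohort(counts_spec):
    """The deterministic count-matched cohort (seed fixed for covariates)."""
    return reconstruct_fixture(counts_spec, seed=7)


@pytest.fixture(scope="session")
def indexed_fixture(fixture_cohort):
    return reduce_to_index(fixture_cohort, size_key="volume")


@pytest.fixture(scope="session")
def fixture_brock(indexed_fixture):
    return brock_for_cohort(indexed_fixture)
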