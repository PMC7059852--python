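import pytest

from metadepth.fixtures import declared_mock_abundances, table3_abundances
from metadepth.synthetic import default_mock_model, mock_spec, simulate_profile
from metadepth.taxprofile import AbundanceVector, TaxonProfile


@pytest.fixture(scope="session")
def mock():
    return mock_spec()


@pytest.fixture(scope="session")
def nt_vector():
    """Observed mock abundances under the broadest reference database."""
    return AbundanceVector(fractions=table3_abundances("nt"), basis="total")


@pytest.fixture(scope="session")
def declared_vector():
    return AbundanceVector(fractions=declared_mock_abundances(), basis="classified")


@pytest.fixture(scope="session")
def mock_profile_1m():
    """One simulated mock-community classifier run at 10^6 reads."""
    return simulate_profile(
        mock_spec(), default_mock_model(), depth=1_000_000, seed=12345, sample_id="mock1m"
    )


@pytest.fixture()
def toy_profile():
    return TaxonProfile(sample_id="toy", counts={"A": 10, "B": 30, "C": 60}, unclassified=0)
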