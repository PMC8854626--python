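import pytest
from hypothesis import settings

from col4gly import data_path
from col4gly.chain_model import build_architecture, read_architecture
from col4gly.io import read_fasta_sequence
from col4gly.population import default_rate_table, read_rate_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_arch():
    """NC[1-10], collagenous[11-40] (10 triplets), NC[41-50]; two exons."""
    return build_architecture(
        [
            ("amino_terminus", 1, 10),
            ("collagenous", 11, 40),
            ("carboxyl_terminus", 41, 50),
        ],
        [(1, 1, 90), (2, 91, 150)],
        chain_id="toy",
    )


@pytest.fixture
def two_region_arch():
    """Two collagenous regions of 5 and 7 triplets around one interruption."""
    return build_architecture(
        [
            ("amino_terminus", 1, 6),
            ("collagenous", 7, 21),
            ("interruption", 22, 27),
            ("collagenous", 28, 48),
            ("carboxyl_terminus", 49, 60),
        ],
        [(1, 1, 60), (2, 61, 120), (3, 121, 180)],
        chain_id="two_region",
    )


@pytest.fixture(scope="session")
def col4a5_like_arch():
    return read_architecture(
        data_path("synthetic_col4a5_like.segments.tsv"),
        data_path("synthetic_col4a5_like.exons.tsv"),
        chain_id="synthetic_col4a5_like",
    )


@pytest.fixture(scope="session")
def col4a5_like_cds():
    return read_fasta_sequence(data_path("synthetic_col4a5_like.cds.fasta"))


@pytest.fixture(scope="session")
def neighbour_rates():
    return read_rate_table(data_path("rates_neighbour_dependent.tsv"))


@pytest.fixture(scope="session")
def uniform_rates():
    table = default_rate_table(1.0, 1.0)
    assert set(table.rates.values()) == {1.0}
    return table
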