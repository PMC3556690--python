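import pytest

from proteodiff.io_formats import ProteinRecord, SequenceDatabase
from proteodiff.synthetic import SyntheticConfig, generate_pair

#: small, fast study conditions used across tests
SMALL_KWARGS = dict(
    n_shared=30,
    n_lost=8,
    n_target_only=5,
    n_duplicate_sequence_pairs=3,
    n_multi_xref=4,
    n_bad_xref=3,
    n_mutated_shared=4,
    protein_length_range=(40, 120),
    seed=7,
)


def make_db(name, *seq_pairs):
    return SequenceDatabase(
        name, "test", [ProteinRecord(acc, seq) for acc, seq in seq_pairs]
    )


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(**SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_pair(small_config):
    return generate_pair(small_config)
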