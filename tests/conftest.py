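import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from memclust.io_fasta import SequenceRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)
dna_n = st.text(alphabet="ACGTN", min_size=1, max_size=200)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_records(seqs):
    """Helper: SequenceRecords from raw strings with file-order ranks."""
    return [SequenceRecord(f"s{i}", s, i) for i, s in enumerate(seqs)]


@pytest.fixture
def records_factory():
    return make_records
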