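import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from issalign.seqcore import AA20, ScoringScheme, SequenceRecord


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


def make_random_record(rng: np.random.Generator, length: int, rec_id: str) -> SequenceRecord:
    return SequenceRecord(rec_id, "".join(AA20[i] for i in rng.integers(0, 20, length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family():
    """One fixed 2-intermediate family reused across module tests."""
    from issalign.synthfam import generate_family

    return generate_family(seed=3, ancestor_length=150, n_intermediates=2,
                           branch_identity=0.55, indel_rate=0.02)
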