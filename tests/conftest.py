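import numpy as np
import pytest

from pairtrim.fastq_io import NucleotideRead, ReadPair
from pairtrim.simulator import QualityModel


def make_pair(seq1: str, seq2: str, pair_id: str = "p") -> ReadPair:
    """Build a ReadPair with uniform high qualities from two sequences."""
    return ReadPair(
        NucleotideRead(f"{pair_id}/1", seq1, "I" * len(seq1)),
        NucleotideRead(f"{pair_id}/2", seq2, "I" * len(seq2)),
    )


def error_free_quality_model(read_length: int = 101) -> QualityModel:
    """All mass at Phred 93: per-base error probability ~5e-10."""
    values = np.array([93])
    probs = np.ones((read_length, 1))
    return QualityModel(values, probs, "degenerate")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
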