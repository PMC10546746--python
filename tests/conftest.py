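import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from seqlayers import DNA, FrequencyMatrix, SequenceSet


@pytest.fixture
def dna_pfm_3100() -> FrequencyMatrix:
    """One DNA column with counts A=3, C=1, G=0, T=0."""
    return FrequencyMatrix(DNA, np.array([[3.0], [1.0], [0.0], [0.0]]))


@pytest.fixture
def small_alignment() -> SequenceSet:
    return SequenceSet(["ACGTA", "ACGTC", "AC-TA"], alphabet=DNA)


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "aln.fa"
    p.write_text(">s1\nACGT\n>s2\nACGA\n>s3\nACGT\n")
    return p


def random_counts_matrix(rng: np.random.Generator, n_letters=4, n_pos=6):
    """Random nonnegative count matrix with at least one nonzero column."""
    m = rng.integers(0, 20, size=(n_letters, n_pos)).astype(float)
    if not np.any(m.sum(axis=0) > 0):
        m[0, 0] = 1.0
    return m
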