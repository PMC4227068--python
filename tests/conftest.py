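import numpy as np
import pytest

from codivabc.mutate import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20140703)


def make_alignment(rows, pops, pair="pairA", locus="loc1"):
    """Build an Alignment from string sequences ('ACGT', '-'/'N' missing)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    seqs = np.array([[code.get(ch, -1) for ch in row.upper()]
                     for row in rows], dtype=np.int8)
    return Alignment(seqs, np.asarray(pops, dtype=np.int8), pair, locus)


@pytest.fixture
def toy_alignment():
    # 4 sequences, 10 sites, 2 + 2 per population
    return make_alignment(
        ["ACGTACGTAC",
         "ACGTACGTAT",
         "ACGAACGTCC",
         "ACGAACTTCC"],
        [0, 0, 1, 1])
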