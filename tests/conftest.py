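import numpy as np
import pytest

from refguide import ReadRecord, SequenceRecord
from refguide.simulate import random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    """A 20 kb single-contig random genome."""
    return random_genome(20_000, seed=7)


def make_read(seq, qual=40, rid="r", mate=1, library_id="lib"):
    if isinstance(qual, int):
        qual = [qual] * len(seq)
    return ReadRecord(rid, mate, seq, np.array(qual, dtype=np.int16), library_id)


def tiling_reads(seq, read_len=100, step=25, library_id="lib"):
    """Error-free reads tiling a sequence so every k-mer is seen >= 2 times."""
    reads = []
    i = 0
    n = 0
    for start in range(0, len(seq) - read_len + 1, step):
        for dup in range(2):
            reads.append(make_read(seq[start : start + read_len],
                                   rid=f"t{n}", library_id=library_id))
            n += 1
    # make sure the final window is covered twice as well
    tail = seq[-read_len:]
    reads.append(make_read(tail, rid=f"t{n}"))
    reads.append(make_read(tail, rid=f"t{n+1}"))
    return reads
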