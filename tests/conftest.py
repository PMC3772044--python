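import numpy as np
import pytest

from chromborder.core import GenomicInterval, Tag


@pytest.fixture
def rng():
    return np.random.default_rng(20130912)


def random_intervals(rng, n, chroms=("chr1",), max_pos=10_000, max_width=300):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width, ".", f"iv{i}"))
    return out


def random_tags(rng, n, chroms=("chr1",), max_pos=10_000, length=36):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, max_pos))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(Tag(chrom, pos, strand, length))
    return out
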