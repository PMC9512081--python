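import numpy as np
import pytest

from peakenrich.genome import GenomeSpec
from peakenrich.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome() -> GenomeSpec:
    return GenomeSpec([("chr1", 10_000), ("chr2", 10_000)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)


def make_set(spans, chrom="chr1", label="") -> IntervalSet:
    """Terse constructor: make_set([(0, 100), (50, 150)])."""
    return IntervalSet([GenomicInterval(chrom, s, e) for s, e in spans], label=label)
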