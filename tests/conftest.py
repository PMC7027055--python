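import numpy as np
import pandas as pd
import pytest

from peakvar.core import CountMatrix, GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_width=2000, prefix="iv"):
    """Random named intervals, possibly overlapping."""
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width, f"{prefix}_{i}"))
    return PeakSet(out)


def random_reads(rng, n, chroms=("chr1", "chr2"), span=100_000, length=75, prefix="read"):
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(GenomicInterval(chrom, start, start + length, f"{prefix}_{i}", strand))
    return PeakSet(out)


def matrix(values, stage="normalized", samples=None, peaks=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    df = pd.DataFrame(
        values,
        index=peaks or [f"pk{i}" for i in range(n)],
        columns=samples or [f"s{j}" for j in range(m)],
    )
    return CountMatrix(df, stage=stage)
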