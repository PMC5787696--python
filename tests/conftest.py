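import numpy as np
import pytest

from epimosaic.methio import MethRead


def make_read(read_id, positions, states, chrom="chr1", start=None, orientation="+"):
    calls = [(int(p), bool(s)) for p, s in zip(positions, states)]
    if start is None:
        start = positions[0] if len(positions) else 1
    return MethRead(read_id, chrom, int(start), orientation, calls)


def random_read_set(rng, n_reads=30, n_cpgs=15, chrom="chr1", spacing=20):
    """Reads over a shared CpG grid with random subsets of covered sites."""
    grid = np.arange(1, n_cpgs + 1) * spacing
    reads = []
    for i in range(n_reads):
        lo = rng.integers(0, n_cpgs)
        hi = rng.integers(lo + 1, n_cpgs + 1)
        positions = grid[lo:hi]
        states = rng.random(len(positions)) < rng.random()
        reads.append(make_read(f"r{i}", positions, states, chrom=chrom))
    return [r for r in reads if r.calls]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
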