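import numpy as np
import pytest

from chip4c.io import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_intervals(rng):
    def make(n=100, chroms=("chr1", "chr2"), max_pos=1_000_000):
        out = []
        for _ in range(n):
            start = int(rng.integers(0, max_pos))
            length = int(rng.integers(1, 500))
            out.append(
                GenomicInterval(
                    str(rng.choice(chroms)),
                    start,
                    start + length,
                    str(rng.choice(["+", "-", "."])),
                )
            )
        return out

    return make
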