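import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sonic4c.core import FeatureTrack, GenomeDef, GenomicInterval, GenomicSite


@pytest.fixture
def small_genome() -> GenomeDef:
    return GenomeDef(("chr1", "chr2"), (1_000_000, 500_000))


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


def random_intervals(rng, genome, n, max_len=5_000, valued=False):
    out = []
    for _ in range(n):
        chrom = genome.names[int(rng.integers(0, len(genome.names)))]
        L = genome.length(chrom)
        start = int(rng.integers(0, L - 1))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                chrom,
                start,
                min(L, start + length),
                value=float(rng.normal()) if valued else None,
            )
        )
    return out


def random_sites(rng, genome, n):
    out = []
    for _ in range(n):
        chrom = genome.names[int(rng.integers(0, len(genome.names)))]
        out.append(GenomicSite(chrom, int(rng.integers(0, genome.length(chrom)))))
    return out
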