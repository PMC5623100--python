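import numpy as np
import pandas as pd
import pytest

from xover.genome import GenomeMap, default_genome
from xover.genotypes import CODE_MISSING, GenotypeMatrix


@pytest.fixture(scope="session")
def small_genome() -> GenomeMap:
    """Two short chromosomes, dense markers, uniform genetic map."""
    return default_genome(
        lengths={"c1": 60_000_000, "c2": 40_000_000},
        marker_spacing=200_000,
        gap_size=2_000_000,
        genetic_length=1.0,
        map_kind="uniform",
        seed=11,
    )


@pytest.fixture(scope="session")
def barley_genome() -> GenomeMap:
    """Default 7-chromosome genome with the distal genetic map."""
    return default_genome(seed=0)


def make_matrix(vectors: dict[str, list[list[int]]], bin_size: int = 1_000_000) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-chromosome sample x bin code lists.

    Use -1 for missing; chromosome length is taken as n_bins * bin_size.
    """
    samples = None
    bin_starts, codes, support, lengths = {}, {}, {}, {}
    for chrom, rows in vectors.items():
        arr = np.asarray(rows, np.int8)
        if samples is None:
            samples = [f"s{i}" for i in range(arr.shape[0])]
        bin_starts[chrom] = np.arange(arr.shape[1], dtype=np.int64) * bin_size
        codes[chrom] = arr
        support[chrom] = (arr != CODE_MISSING).astype(np.int32)
        lengths[chrom] = arr.shape[1] * bin_size
    return GenotypeMatrix(
        samples=samples,
        bin_starts=bin_starts,
        codes=codes,
        support=support,
        bin_size=bin_size,
        chrom_lengths=lengths,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
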