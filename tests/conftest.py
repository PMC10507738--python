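"""Shared test fixtures: tiny genomes and catalog builders.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from mutotopo.genome import GenomeSequence


@pytest.fixture(scope="session")
def random_genome():
    """One 60 kb random chromosome (every trinucleotide context present)."""
    rng = np.random.default_rng(20240917)
    return GenomeSequence.from_codes({"chr1": rng.integers(0, 4, 60_000).astype(np.uint8)})


@pytest.fixture(scope="session")
def two_chrom_genome():
    rng = np.random.default_rng(7)
    return GenomeSequence.from_codes(
        {
            "chr1": rng.integers(0, 4, 50_000).astype(np.uint8),
            "chr2": rng.integers(0, 4, 50_000).astype(np.uint8),
        }
    )


def make_catalog_frame(rows):
    """rows: (sample, chrom, pos, ref, alt, mut_type)"""
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "mut_type"]
    )


@pytest.fixture
def catalog_builder():
    return make_catalog_frame
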