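import numpy as np
import pandas as pd
import pytest

from autozygy.genome import GenomeBuild


@pytest.fixture
def tiny_build() -> GenomeBuild:
    return GenomeBuild((("chr1", 10_000_000), ("chr2", 5_000_000)))


@pytest.fixture
def one_chrom_build() -> GenomeBuild:
    return GenomeBuild((("chr1", 10_000_000),))


def windows_frame(chrom, window_size, dens, masked=None):
    """Build a window track directly from a density vector (test helper)."""
    n = len(dens)
    dens = np.asarray(dens, dtype=float)
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    masked = np.asarray(masked, dtype=bool)
    starts = np.arange(n) * window_size
    eff = np.where(masked, 0, window_size)
    het_count = np.where(masked, 0, np.round(dens * window_size / 1000)).astype(int)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "het_count": het_count,
            "effective_bases": eff,
            "het_per_kbp": np.where(masked, np.nan, dens),
            "masked_out": masked,
        }
    )
    return df
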