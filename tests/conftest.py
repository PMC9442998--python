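import numpy as np
import pandas as pd
import pytest

from cnburden import GenomeBins, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def grch37_bins():
    return GenomeBins.grch37()


@pytest.fixture(scope="session")
def small_cohort(grch37_bins):
    """20-patient synthetic cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_patients=20, seed=3), grch37_bins)


def make_bins(chrom_bins: dict, bin_size: int = 500_000,
              sex: tuple = ()) -> GenomeBins:
    """Tiny custom bin frame: {chrom: n_bins}; chroms in ``sex`` flagged
    non-autosomal."""
    rows = []
    for chrom, n in chrom_bins.items():
        for i in range(n):
            rows.append((str(chrom), i * bin_size, (i + 1) * bin_size,
                         str(chrom) not in sex))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "autosome"])
    return GenomeBins(df=df, bin_size=bin_size)


@pytest.fixture
def bins5():
    return make_bins({"1": 5})


def rng(seed=0):
    return np.random.default_rng(seed)
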