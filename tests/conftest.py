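import numpy as np
import pandas as pd
import pytest

from cnvcohort import SimConfig, simulate_cohort, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_participants=300, n_genes=100, cnv_rate=2.0, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_genome):
    return simulate_cohort(small_config, small_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_calls(rows, columns=("participant_id", "chrom", "start", "end", "type", "caller")):
    return pd.DataFrame(list(rows), columns=list(columns))


@pytest.fixture
def toy_genes():
    return pd.DataFrame(
        {
            "symbol": ["A", "B", "C", "X1"],
            "chrom": ["chr1", "chr1", "chr1", "chrX"],
            "start": [0, 20_000, 40_000, 5_000],
            "end": [10_000, 30_000, 50_000, 15_000],
            "strand": ["+", "-", "+", "+"],
        }
    )
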