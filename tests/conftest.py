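import numpy as np
import pandas as pd
import pytest

from rhizocore.community_table import OtuTable, relative_abundance
from rhizocore.synthetic_data import SimulationConfig, simulate_community


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 5, 0, 3],
            [8, 6, 2, 2],
            [12, 3, 1, 2],
            [9, 4, 4, 1],
            [11, 2, 3, 2],
            [7, 8, 2, 1],
        ]
    )
    return OtuTable(
        counts=counts,
        sample_ids=[f"S{i}" for i in range(1, 7)],
        otu_ids=["OTU_A", "OTU_B", "OTU_C", "OTU_D"],
    )


@pytest.fixture
def small_rel(small_table):
    return relative_abundance(small_table)


@pytest.fixture
def recovery_config():
    """60-sample / 3x25-OTU planted design used for recovery tests."""
    return SimulationConfig(
        n_samples=60,
        n_modules=3,
        otus_per_module=25,
        n_background_otus=25,
        loading=0.9,
        noise_sd=0.3,
        sequencing_depth=5000,
        seed=7,
    )


@pytest.fixture
def planted_community(recovery_config):
    return simulate_community(recovery_config)


def spearman_oracle(x, y):
    """Independent brute-force Spearman: average ranks then Pearson on ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2  # mean of 1-based positions
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
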