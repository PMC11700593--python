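import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from bottlescan.simdata import SimConfig, make_fixture, simulate_population


@pytest.fixture
def toy_table():
    """3 samples x 5 sites on one chromosome, incl. one missing call."""
    return make_fixture(
        {"chr1": ([100, 200, 300, 400, 500],
                  {"a": "01120", "b": "0.120", "c": "21100"})}
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small bottlenecked simulation with pedigree pairs and all variant classes."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length=5_000_000,
        mu=2e-7,
        ne_trajectory=((10, 50), (None, 50)),
        sample_size=8,
        n_pedigree_pairs=2,
        class_probs={"NEUTRAL": 0.55, "LOW": 0.2, "MODERATE": 0.2, "HIGH": 0.05},
        outgroup_divergence=50_000,
        seed=11,
    )
    vt, truth = simulate_population(cfg)
    return cfg, vt, truth


def random_roh_fixture(rng, n_max=2000):
    """Random positions/dosages designed to contain homozygous stretches,
    noisy stretches, missing calls and occasional large gaps."""
    n = int(rng.integers(60, n_max + 1))
    gaps = rng.integers(500, 30_000, size=n).astype(np.int64)
    big = rng.random(n) < 0.005
    gaps[big] += rng.integers(900_000, 2_500_000, size=int(big.sum()))
    pos = np.cumsum(gaps) + 1
    dos = np.zeros(n, dtype=np.int8)
    i = 0
    while i < n:
        seg = int(rng.integers(30, 400))
        mode = rng.random()
        if mode < 0.45:  # homozygous stretch with rare hets/missing
            block = np.where(rng.random(seg) < 0.01, 1, 0)
            block = np.where(rng.random(seg) < 0.02, -1, block)
        elif mode < 0.8:  # heterozygous-rich stretch
            block = rng.choice([0, 1, 2, -1], size=seg, p=[0.45, 0.35, 0.15, 0.05])
        else:  # all homozygous alt
            block = np.full(seg, 2)
        dos[i:i + seg] = block[: n - i]
        i += seg
    return pos, dos
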