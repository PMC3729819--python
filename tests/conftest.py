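import logging

import numpy as np
import pandas as pd
import pytest

from dsbscape import ConditionParams, SimConfig, plant_truth, simulate_fragments

logging.disable(logging.INFO)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """Two short chromosomes, resolvable planted hotspots, clean reads."""
    return SimConfig(
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        n_hotspots=20,
        background_per_mb=10.0,
        duplicate_rate=0.0,
        low_quality_fraction=0.0,
        gal4_fraction=0.2,
        subtelomere_end_width=200_000,
        seed=7,
    )


@pytest.fixture
def small_truth(small_config):
    return plant_truth(small_config)


@pytest.fixture
def small_fragments(small_config, small_truth):
    frags, _ = simulate_fragments(
        small_config, small_truth, ConditionParams(), seed=11
    )
    return frags


def random_fragments(rng, n, chrom_lengths, qmax=60):
    """Unstructured fragment table for counting/filter oracles."""
    chroms = rng.choice(list(chrom_lengths), size=n)
    lengths = np.array([chrom_lengths[c] for c in chroms])
    start = (rng.random(n) * (lengths - 500)).astype(np.int64)
    return pd.DataFrame({
        "chrom": chroms,
        "start": start,
        "end": start + rng.integers(50, 500, size=n),
        "strand": rng.choice(["+", "-"], size=n),
        "q1": rng.integers(0, qmax + 1, size=n),
        "q2": rng.integers(0, qmax + 1, size=n),
        "replicate": "rep1",
    })
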