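"""Shared fixtures: small deterministic datasets and PWM libraries."""

from __future__ import annotations

import numpy as np
import pytest

from atacnet.intervals import GenomicInterval, IntervalSet
from atacnet.motifs import fixture_library
from atacnet.simulate import SimulationConfig, generate_dataset


def random_interval_set(rng: np.random.Generator, n: int, n_chroms: int = 3,
                        span: int = 100_000, max_len: int = 500, label: str = "rnd"):
    """Uniform random intervals for oracle comparisons."""
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len + 1))
        ivs.append(GenomicInterval(chrom, start, start + length, name=f"{label}_{i}"))
    return IntervalSet(ivs, label=label)


@pytest.fixture(scope="session")
def pwms():
    return fixture_library()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions used by most end-to-end tests."""
    return SimulationConfig(seed=2022)


@pytest.fixture(scope="session")
def dataset(small_config):
    return generate_dataset(small_config)
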