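"""Shared fixtures and brute-force oracles.

The interval oracles work on an explicit per-base boolean array over a
small chromosome, so every set operation can be checked positionally
against the interval implementations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from funcarch.annotate import IntervalSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from funcarch.simdata import ClassSpec, SimConfig, SnpPanel, generate_panel

CHROM_LEN = 10_000  # oracle chromosomes are small enough to enumerate


def base_array(ivset: IntervalSet, chrom: str = "1", length: int = CHROM_LEN) -> np.ndarray:
    """Per-base boolean membership array for one chromosome."""
    arr = np.zeros(length, dtype=bool)
    for c, s, e in ivset.intervals:
        if str(c) == chrom:
            arr[s:min(e, length)] = True
    return arr


def random_interval_set(rng: np.random.Generator, name: str, n: int = 20,
                        length: int = CHROM_LEN, chrom: str = "1") -> IntervalSet:
    starts = rng.integers(0, length - 1, size=n)
    lens = rng.integers(1, 200, size=n)
    ivs = tuple(
        (chrom, int(s), int(min(s + l, length))) for s, l in zip(starts, lens)
    )
    return IntervalSet(name, ivs)


def toy_panel(rng: np.random.Generator, M: int = 50, n_ref: int = 30,
              chrom_len: int = CHROM_LEN) -> SnpPanel:
    """A small panel with random (sorted, distinct) positions on one chromosome."""
    pos = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=M, replace=False))
    while True:
        g = rng.integers(0, 3, size=(n_ref, M))
        freq = g.mean(axis=0) / 2
        if ((freq > 0) & (freq < 1)).all():
            break
    return SnpPanel(
        snp_id=np.array([f"rs{i}" for i in range(M)]),
        chrom=np.ones(M, dtype=int),
        pos=pos,
        genotypes=g,
        maf=np.minimum(freq, 1 - freq).clip(0.01, 0.5),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        M=400,
        n_ref=120,
        n_gwas=2_000,
        block_len=10,
        rho=0.7,
        class_spec=(
            ClassSpec("base", 1.0, 0.05 / 400),
            ClassSpec("enh", 0.2, 0.4 / 400),
        ),
        spacing_bp=10_000,
        seed=99,
    )


@pytest.fixture
def small_panel(small_config) -> SnpPanel:
    return generate_panel(small_config)
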