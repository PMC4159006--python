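"""Shared fixtures: a small synthetic bundle and per-base oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from underrep.intervals import GenomicInterval, RegionSet
from underrep.simulate import SyntheticGenomeConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SyntheticGenomeConfig:
    return SyntheticGenomeConfig(
        seed=7,
        chromosomes=(("chr2", 3_000_000),),
        n_regions=3,
        region_length_range=(100_000, 200_000),
        n_loci=200,
        frac_loci_in_regions=0.3,
        alignment_flank=50_000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_genome(small_config)


def per_base_mask(intervals, length: int, chrom: str = "chr1") -> np.ndarray:
    """Boolean per-base membership oracle over [0, length)."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def random_region_set(rng: np.random.Generator, length: int, n: int, chrom: str = "chr1") -> RegionSet:
    starts = rng.integers(0, length - 1, size=n)
    lens = rng.integers(1, max(2, length // 10), size=n)
    ivs = [
        GenomicInterval(chrom, int(s), int(min(length, s + l)))
        for s, l in zip(starts, lens)
        if s + 1 <= length
    ]
    return RegionSet(ivs)
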