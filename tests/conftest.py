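"""Shared fixtures: small genomes, random interval sets, a tiny dataset."""

from __future__ import annotations

import numpy as np
import pytest

import barrierseq as bq
from barrierseq.core import Genome, GenomicInterval, IntervalSet


@pytest.fixture
def genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000})


def random_intervals(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    max_len: int = 500,
    prefix: str = "iv",
) -> IntervalSet:
    """n random intervals over the genome, named uniquely."""
    out = []
    chroms = genome.chrom_names
    sizes = [genome.chrom_sizes[c] for c in chroms]
    for i in range(n):
        ci = rng.integers(len(chroms))
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, sizes[ci] - length))
        out.append(
            GenomicInterval(chroms[ci], start, start + length, name=f"{prefix}{i}")
        )
    return IntervalSet(out)


def random_track(rng: np.random.Generator, genome: Genome) -> bq.CoverageTrack:
    return bq.CoverageTrack(
        genome,
        {c: rng.integers(0, 10, size=s).astype(float)
         for c, s in genome.chrom_sizes.items()},
    )


@pytest.fixture(scope="session")
def small_config() -> bq.SyntheticConfig:
    """A scaled-down landscape exercising every feature of the generator."""
    return bq.SyntheticConfig(
        n_chroms=1,
        chrom_length=1_500_000,
        n_peaks=60,
        fraction_motif_peaks=0.3,
        fraction_repeat_peaks=0.5,
        fraction_other=0.2,
        occupancy_shift=0.8,
        n_barrier_loss=15,
        n_barrier_gain=5,
        n_decoy_repeats=5,
        n_decoy_motifs=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> bq.SyntheticDataset:
    return bq.simulate(small_config)
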