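from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gbskaryo import AberrationSpec, GenomeDef, make_bins, simulate_cohort, wheat_like_genome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# toy analysis grid for the 1:10 wheat-like genome
TOY_BIN = 10_000_000
TOY_STEP = 5_000_000


@pytest.fixture(scope="session")
def small_genome() -> GenomeDef:
    """Hand-sized 3-chromosome genome for exact-arithmetic tests (Mb-scale units)."""
    return GenomeDef.from_items(
        [
            ("chr1", 250_000_000, 120_000_000),
            ("chr2", 80_000_000, None),
            ("chr3", 100_000_000, 40_000_000),
        ]
    )


@pytest.fixture(scope="session")
def toy_wheat() -> GenomeDef:
    return wheat_like_genome(0.1)


def make_tag_table(sample_id: str, records: list[tuple[str, int]]):
    from gbskaryo import TagPositionTable

    df = pd.DataFrame(records, columns=["chrom", "pos"]) if records else pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)}
    )
    return TagPositionTable(sample_id=sample_id, records=df, n_raw_alignments=len(df))


def complex_aneuploid_cohort(genome: GenomeDef, seed: int, n_euploid: int = 19, mean_tags: int = 100_000):
    """A majority-euploid cohort with one complex aberrant sample.

    The aberrant sample lacks both copies of 1A, carries four copies of 1B,
    and a single copy of 4A — the classic nullisomic/tetrasomic/monosomic
    combination.
    """
    specs = [AberrationSpec(sample_id=f"euploid{i:02d}") for i in range(n_euploid)]
    aberrant = AberrationSpec(sample_id="aberrant")
    for chrom, m in (("1A", 0.0), ("1B", 2.0), ("4A", 0.5)):
        aberrant = aberrant.whole_chromosome(genome, chrom, m)
    specs.append(aberrant)
    bins = make_bins(genome, TOY_BIN, TOY_STEP)
    tables, truth, manifest = simulate_cohort(
        genome,
        specs,
        bins,
        site_density=500.0,
        centromere_depletion=0.8,
        centromere_radius_bp=5_000_000,
        mean_tags=mean_tags,
        dispersion=0.5,
        seed=seed,
    )
    return tables, truth, manifest


@pytest.fixture(scope="session")
def aneuploid_cohort(toy_wheat):
    return complex_aneuploid_cohort(toy_wheat, seed=1)
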