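"""Synthetic GBS tag data with known dosage truth.

The generator emulates what reduced-representation sequencing of a large
cohort looks like to the read-depth karyotyper:

* a genome-wide set of candidate tag sites (restriction-site proxies) placed
  uniformly per chromosome, thinned near centromeres where methylation-
  sensitive enzymes cut rarely — the site list is a genome property shared by
  every sample;
* per-sample sequencing depth drawn log-normally, reproducing the heavy
  right-skew of per-sample tag totals seen across GBS batches;
* per-site Bernoulli observation with probability proportional to depth and
  to the local copy-number multiplier (1.0 = disomic baseline, 0 = deleted,
  0.5 = single copy, 1.5 = trisomic, 2.0 = tetrasomic).

Aberrations are expressed as sampling-rate multipliers relative to disomic,
so a heterozygous segmental deletion is simply multiplier 0.5 over a region.
A truth table maps every (sample, bin) to its true copy number (2 x the
effective multiplier) for parameter-recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import Bin, Chromosome, GenomeDef
from .ingest import TagPositionTable

__all__ = [
    "Region",
    "AberrationSpec",
    "wheat_like_genome",
    "place_tag_sites",
    "simulate_sample",
    "simulate_cohort",
    "truth_table",
    "truth_classes",
    "write_sam",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


class SynthError(ValueError):
    pass


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise SynthError(f"invalid region [{self.start}, {self.end}) on {self.chrom}")
        if self.multiplier < 0:
            raise SynthError(f"multiplier must be >= 0, got {self.multiplier}")


@dataclass
class AberrationSpec:
    """Copy-number plan for one simulated sample.

    ``default_multiplier`` applies everywhere not covered by ``regions``;
    multiplier m means tag-sampling rate m x the disomic rate, i.e. true copy
    number 2m.
    """

    sample_id: str
    default_multiplier: float = 1.0
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.default_multiplier < 0:
            raise SynthError("default_multiplier must be >= 0")
        by_chrom: dict[str, list[Region]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, regs in by_chrom.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise SynthError(
                        f"sample {self.sample_id!r}: overlapping regions on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    def validate_against(self, genome: GenomeDef) -> None:
        for r in self.regions:
            if r.chrom not in genome:
                raise SynthError(f"sample {self.sample_id!r}: unknown chromosome {r.chrom!r}")
            if r.end > genome.length_of(r.chrom):
                raise SynthError(
                    f"sample {self.sample_id!r}: region end {r.end} beyond {r.chrom} "
                    f"length {genome.length_of(r.chrom)}"
                )

    def whole_chromosome(self, genome: GenomeDef, chrom: str, multiplier: float) -> "AberrationSpec":
        """Return a copy with one whole chromosome set to ``multiplier``."""
        return AberrationSpec(
            sample_id=self.sample_id,
            default_multiplier=self.default_multiplier,
            regions=self.regions + [Region(chrom, 0, genome.length_of(chrom), multiplier)],
        )

    def multiplier_at(self, chrom: str, pos: Union[int, np.ndarray]) -> np.ndarray:
        """Effective multiplier for position(s) on a chromosome."""
        pos = np.atleast_1d(np.asarray(pos))
        out = np.full(pos.shape, float(self.default_multiplier))
        for r in self.regions:
            if r.chrom == chrom:
                out[(pos >= r.start) & (pos < r.end)] = r.multiplier
        return out


# Chromosome lengths (Mb) and approximate centromere midpoints for a
# 21-chromosome hexaploid-wheat-like genome; intended as a realistic toy, not
# as reference-assembly coordinates.
_WHEAT_LIKE_MB = [
    ("1A", 594, 213), ("1B", 690, 240), ("1D", 495, 170),
    ("2A", 781, 330), ("2B", 801, 350), ("2D", 652, 270),
    ("3A", 751, 320), ("3B", 831, 350), ("3D", 616, 240),
    ("4A", 745, 280), ("4B", 674, 300), ("4D", 510, 190),
    ("5A", 710, 250), ("5B", 713, 200), ("5D", 566, 190),
    ("6A", 618, 290), ("6B", 721, 330), ("6D", 474, 210),
    ("7A", 737, 360), ("7B", 751, 300), ("7D", 638, 340),
]


def wheat_like_genome(scale: float = 1.0) -> GenomeDef:
    """A 21-chromosome wheat-like genome (1A..7D), optionally scaled down.

    ``scale=0.1`` gives a 1:10 toy (chromosomes ~47-83 Mb) for fast tests
    with 10 Mb / 5 Mb bins in place of the full-scale 100 Mb / 50 Mb grid.
    """
    if scale <= 0:
        raise SynthError("scale must be positive")
    return GenomeDef(
        tuple(
            Chromosome(name, int(round(length_mb * 1e6 * scale)), int(round(cen_mb * 1e6 * scale)))
            for name, length_mb, cen_mb in _WHEAT_LIKE_MB
        )
    )


def place_tag_sites(
    genome: GenomeDef,
    site_density: float = 50.0,
    centromere_depletion: float = 0.8,
    centromere_radius_bp: int = 50_000_000,
    seed: SeedLike = 0,
) -> dict[str, np.ndarray]:
    """Place candidate tag sites uniformly per chromosome, thinned at centromeres.

    ``site_density`` is sites per Mb; the expected site count per chromosome is
    density x length(Mb) before depletion. Within ``centromere_radius_bp`` of a
    centromere, each site is retained with probability 1 - centromere_depletion.
    The returned mapping (chrom -> sorted positions) is shared by all samples:
    restriction sites are genome properties, so per-bin site-count variation
    cancels in the across-sample median normalization.
    """
    if site_density <= 0:
        raise SynthError("site_density must be positive")
    if not (0 <= centromere_depletion <= 1):
        raise SynthError("centromere_depletion must be in [0, 1]")
    rng = _rng(seed)
    sites: dict[str, np.ndarray] = {}
    for chrom in genome:
        n = rng.poisson(site_density * chrom.length / 1e6)
        pos = np.sort(rng.integers(0, chrom.length, size=n))
        if chrom.centromere is not None and centromere_depletion > 0 and n > 0:
            near = np.abs(pos - chrom.centromere) <= centromere_radius_bp
            keep = ~near | (rng.random(n) < 1 - centromere_depletion)
            pos = pos[keep]
        if len(pos) == 0:
            warnings.warn(f"chromosome {chrom.name}: no tag sites placed", stacklevel=2)
        sites[chrom.name] = pos
    return sites


def simulate_sample(
    sites: dict[str, np.ndarray],
    spec: AberrationSpec,
    genome: GenomeDef,
    mean_tags: int = 200_000,
    dispersion: float = 0.5,
    seed: SeedLike = 0,
) -> TagPositionTable:
    """Draw one sample's observed tags from the shared site list.

    The sample's depth factor is log-normal with median-unbiased mean 1 and
    log-sd ``dispersion``; each site is observed independently with
    probability ``min(1, base_rate * depth_factor * multiplier)``, where
    ``base_rate`` is calibrated so a euploid sample at depth factor 1 yields
    ~``mean_tags`` tags.
    """
    if mean_tags <= 0:
        raise SynthError("mean_tags must be positive")
    spec.validate_against(genome)
    rng = _rng(seed)
    n_sites = sum(len(v) for v in sites.values())
    if n_sites == 0:
        raise SynthError("empty site list")
    base_rate = mean_tags / n_sites
    depth_factor = float(np.exp(rng.normal(-0.5 * dispersion**2, dispersion))) if dispersion > 0 else 1.0
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for name in genome.names:
        pos = sites.get(name)
        if pos is None or len(pos) == 0:
            continue
        p = np.minimum(1.0, base_rate * depth_factor * spec.multiplier_at(name, pos))
        observed = pos[rng.random(len(pos)) < p]
        chroms.append(np.repeat(name, len(observed)))
        positions.append(observed)
    records = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms) if chroms else np.array([], dtype=str),
            "pos": np.concatenate(positions).astype(np.int64) if positions else np.array([], dtype=np.int64),
        }
    )
    return TagPositionTable(sample_id=spec.sample_id, records=records, n_raw_alignments=len(records))


def truth_table(genome: GenomeDef, bins: Sequence[Bin], specs: Sequence[AberrationSpec]) -> pd.DataFrame:
    """True copy number (2 x effective multiplier) per (bin, sample).

    A bin straddling a region boundary takes the length-weighted majority
    multiplier. Returns a DataFrame with chrom/start/end columns followed by
    one column per sample.
    """
    data: dict[str, list[float]] = {s.sample_id: [] for s in specs}
    for b in bins:
        for s in specs:
            cover: dict[float, int] = {}
            edges = sorted(
                {b.start, b.end}
                | {r.start for r in s.regions if r.chrom == b.chrom and r.start > b.start and r.start < b.end}
                | {r.end for r in s.regions if r.chrom == b.chrom and r.end > b.start and r.end < b.end}
            )
            for lo, hi in zip(edges, edges[1:]):
                m = float(s.multiplier_at(b.chrom, (lo + hi) // 2)[0])
                cover[m] = cover.get(m, 0) + (hi - lo)
            majority = max(cover.items(), key=lambda kv: kv[1])[0]
            data[s.sample_id].append(2.0 * majority)
    out = pd.DataFrame(data)
    out.insert(0, "chrom", [b.chrom for b in bins])
    out.insert(1, "start", [b.start for b in bins])
    out.insert(2, "end", [b.end for b in bins])
    return out


def truth_classes(truth: pd.DataFrame) -> pd.DataFrame:
    """Expected dosage class per (bin, sample) implied by the truth table."""
    from .dosage import classify_values

    meta = truth[["chrom", "start", "end"]]
    samples = [c for c in truth.columns if c not in ("chrom", "start", "end")]
    classes = pd.DataFrame(
        {s: classify_values(truth[s].to_numpy() / 2.0) for s in samples}
    )
    return pd.concat([meta, classes], axis=1)


def simulate_cohort(
    genome: GenomeDef,
    specs: Sequence[AberrationSpec],
    bins: Sequence[Bin],
    site_density: float = 50.0,
    centromere_depletion: float = 0.8,
    centromere_radius_bp: int = 50_000_000,
    mean_tags: int = 200_000,
    dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[list[TagPositionTable], pd.DataFrame, dict]:
    """Simulate a cohort sharing one site list; returns (tables, truth, manifest).

    The across-sample median normalization assumes most samples are disomic at
    every bin; a warning is emitted when any bin violates that, since dosage
    there will be mis-scaled for the whole cohort.
    """
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise SynthError("duplicate sample ids in cohort")
    if len(specs) < 3:
        warnings.warn("fewer than 3 samples: per-bin medians are fragile", stacklevel=2)
    truth = truth_table(genome, bins, specs)
    sample_cols = truth[ids]
    aberrant_frac = (sample_cols != 2.0).sum(axis=1) / len(ids)
    if (aberrant_frac > 0.5).any():
        n_bad = int((aberrant_frac > 0.5).sum())
        warnings.warn(
            f"{n_bad} bin(s) are non-disomic in a majority of samples; "
            "the median-normalization assumption is violated there",
            stacklevel=2,
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) + 1)
    sites = place_tag_sites(
        genome,
        site_density=site_density,
        centromere_depletion=centromere_depletion,
        centromere_radius_bp=centromere_radius_bp,
        seed=children[0],
    )
    tables = [
        simulate_sample(
            sites, spec, genome, mean_tags=mean_tags, dispersion=dispersion, seed=child
        )
        for spec, child in zip(specs, children[1:])
    ]
    manifest = {
        "seed": int(seed),
        "n_samples": len(specs),
        "site_density_per_mb": float(site_density),
        "centromere_depletion": float(centromere_depletion),
        "centromere_radius_bp": int(centromere_radius_bp),
        "mean_tags": int(mean_tags),
        "dispersion": float(dispersion),
        "n_sites": int(sum(len(v) for v in sites.values())),
        "samples": {
            s.sample_id: {
                "default_multiplier": s.default_multiplier,
                "regions": [
                    {"chrom": r.chrom, "start": r.start, "end": r.end, "multiplier": r.multiplier}
                    for r in s.regions
                ],
            }
            for s in specs
        },
    }
    return tables, truth, manifest


def write_sam(
    table: TagPositionTable,
    genome: GenomeDef,
    path: Union[str, Path],
    multimapper_fraction: float = 0.0,
    seed: SeedLike = 0,
) -> None:
    """Emit a plain-text SAM with one mapped primary record per observed tag.

    With ``multimapper_fraction`` r > 0, an extra ~r fraction of records
    carrying an ``XS:i`` optional field (multi-mapper signature) is appended
    to exercise the unique-mapping filter; the ingest stage must drop them.
    """
    if not (0 <= multimapper_fraction < 1):
        raise SynthError("multimapper_fraction must be in [0, 1)")
    rng = _rng(seed)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in genome:
            fh.write(f"@SQ\tSN:{chrom.name}\tLN:{chrom.length}\n")
        i = 0
        for chrom, pos in zip(table.records["chrom"], table.records["pos"]):
            fh.write(f"tag{i}\t0\t{chrom}\t{pos + 1}\t42\t64M\t*\t0\t0\t*\t*\tAS:i:0\n")
            i += 1
            if multimapper_fraction > 0 and rng.random() < multimapper_fraction:
                mm_pos = int(rng.integers(0, genome.length_of(chrom) - 64))
                fh.write(
                    f"mm{i}\t0\t{chrom}\t{mm_pos + 1}\t1\t64M\t*\t0\t0\t*\t*\tAS:i:0\tXS:i:0\n"
                )
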