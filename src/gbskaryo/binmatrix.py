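"""Per-bin tag counting and the two-stage count normalization.

Stage 1 rescales every sample column to a common total (the median of
per-sample totals), removing library-size differences. Stage 2 divides each
bin by its across-sample median, so a bin in a sample with the cohort-typical
two copies sits at 1.0 and dosage scales linearly: 0.5 for one copy, 1.5 for
three, 2.0 for four. Stage 2 assumes the majority of samples are disomic at
any given bin; bins whose across-sample median is zero cannot be normalized
and are masked (no-call), not divided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import Bin, GenomeDef
from .ingest import TagPositionTable

__all__ = [
    "BinCountMatrix",
    "NormalizedMatrix",
    "count_bins",
    "normalize_sample_totals",
    "normalize_bin_medians",
    "normalize",
    "read_counts_tsv",
    "read_normalized_tsv",
]


class NormalizationError(ValueError):
    pass


@dataclass
class BinCountMatrix:
    """Raw tag counts per (bin, sample). A tag in a window-overlap region counts in both bins."""

    bins: list[Bin]
    samples: list[str]
    counts: np.ndarray  # int64, shape (n_bins, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.bins), len(self.samples)):
            raise NormalizationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.bins)} bins x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise NormalizationError("negative counts")

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "chrom", [b.chrom for b in self.bins])
        df.insert(1, "start", [b.start for b in self.bins])
        df.insert(2, "end", [b.end for b in self.bins])
        return df

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedMatrix:
    """Normalized tag counts; euploid expectation 1.0. Masked bins carry NaN."""

    bins: list[Bin]
    samples: list[str]
    values: np.ndarray  # float64, NaN on masked rows
    mask: np.ndarray  # bool per bin; True = undefined normalization

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.bins), len(self.samples)):
            raise NormalizationError("values shape mismatch")
        if self.mask.shape != (len(self.bins),):
            raise NormalizationError("mask shape mismatch")

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "chrom", [b.chrom for b in self.bins])
        df.insert(1, "start", [b.start for b in self.bins])
        df.insert(2, "end", [b.end for b in self.bins])
        return df

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def _bins_from_frame(df: pd.DataFrame) -> list[Bin]:
    bins: list[Bin] = []
    counters: dict[str, int] = {}
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        idx = counters.get(chrom, 0)
        bins.append(Bin(str(chrom), int(start), int(end), idx))
        counters[chrom] = idx + 1
    return bins


def read_counts_tsv(path: Union[str, Path]) -> BinCountMatrix:
    """Load a bin-count matrix written by :meth:`BinCountMatrix.write_tsv`."""
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return BinCountMatrix(
        bins=_bins_from_frame(df),
        samples=samples,
        counts=df[samples].to_numpy(dtype=np.int64),
    )


def read_normalized_tsv(path: Union[str, Path]) -> NormalizedMatrix:
    """Load a normalized matrix written by :meth:`NormalizedMatrix.write_tsv`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
    values = df[samples].to_numpy(dtype=float)
    mask = np.all(~np.isfinite(values), axis=1)
    return NormalizedMatrix(bins=_bins_from_frame(df), samples=samples, values=values, mask=mask)


def count_bins(tags: Sequence[TagPositionTable], bins: Sequence[Bin], genome: Optional[GenomeDef] = None) -> BinCountMatrix:
    """Count retained tags of each sample within each sliding-window bin.

    Counting is by half-open membership ``start <= pos < end``; with 50%
    overlapping windows an interior tag increments two bins. A tag position
    outside its chromosome is corrupt input and raises.
    """
    bins = list(bins)
    chrom_bins: dict[str, list[tuple[int, Bin]]] = {}
    for i, b in enumerate(bins):
        chrom_bins.setdefault(b.chrom, []).append((i, b))
    samples = [t.sample_id for t in tags]
    if len(set(samples)) != len(samples):
        raise NormalizationError("duplicate sample ids")
    counts = np.zeros((len(bins), len(samples)), dtype=np.int64)
    for j, t in enumerate(tags):
        if genome is not None:
            t.validate_against(genome)
        for chrom, sub in t.records.groupby("chrom", sort=False):
            if chrom not in chrom_bins:
                raise NormalizationError(
                    f"sample {t.sample_id!r}: chromosome {chrom!r} has no bins in the grid"
                )
            pos = np.sort(sub["pos"].to_numpy())
            chrom_len = max(b.end for _, b in chrom_bins[chrom])
            if len(pos) and (pos[0] < 0 or pos[-1] >= chrom_len):
                raise NormalizationError(
                    f"sample {t.sample_id!r}: tag position outside [0, {chrom_len}) on {chrom}"
                )
            for i, b in chrom_bins[chrom]:
                lo = np.searchsorted(pos, b.start, side="left")
                hi = np.searchsorted(pos, b.end, side="left")
                counts[i, j] = hi - lo
    return BinCountMatrix(bins=bins, samples=samples, counts=counts)


def normalize_sample_totals(m: BinCountMatrix) -> np.ndarray:
    """Rescale each sample column so all column totals equal the median total.

    Samples with a zero column total cannot be rescaled; they must be excluded
    by QC before normalization.
    """
    totals = m.column_totals().astype(float)
    if (totals == 0).any():
        bad = [s for s, t in zip(m.samples, totals) if t == 0]
        raise NormalizationError(
            f"sample(s) with zero total tag count: {bad}; exclude them via QC before normalizing"
        )
    target = float(np.median(totals))
    return m.counts * (target / totals)[np.newaxis, :]


def normalize_bin_medians(scaled: np.ndarray, bins: Sequence[Bin], samples: Sequence[str]) -> NormalizedMatrix:
    """Divide each bin row by its across-sample median; zero-median bins are masked."""
    scaled = np.asarray(scaled, dtype=float)
    medians = np.median(scaled, axis=1)
    mask = medians == 0
    values = np.full_like(scaled, np.nan)
    ok = ~mask
    values[ok, :] = scaled[ok, :] / medians[ok, np.newaxis]
    return NormalizedMatrix(bins=list(bins), samples=list(samples), values=values, mask=mask)


def normalize(m: BinCountMatrix) -> NormalizedMatrix:
    """Both normalization stages: sample totals, then per-bin medians."""
    return normalize_bin_medians(normalize_sample_totals(m), m.bins, m.samples)
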