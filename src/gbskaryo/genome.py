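"""Genome coordinate frame: chromosomes, centromeres, and the sliding-window bin grid.

All internal coordinates are 0-based, half-open ``[start, end)``. SAM input
(1-based) is converted once at the ingest boundary and never again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

__all__ = ["Chromosome", "GenomeDef", "Bin", "load_genome", "make_bins", "write_bins_bed"]


class GenomeError(ValueError):
    """Invalid genome definition or bin-grid parameters."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, length in bp, and optional centromere midpoint."""

    name: str
    length: int
    centromere: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise GenomeError("chromosome name must be non-empty")
        if self.length <= 0:
            raise GenomeError(f"chromosome {self.name!r}: length must be positive, got {self.length}")
        if self.centromere is not None and not (0 < self.centromere < self.length):
            raise GenomeError(
                f"chromosome {self.name!r}: centromere {self.centromere} outside (0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeDef:
    """Ordered set of chromosomes; the single source of valid chromosome names.

    Downstream stages use membership in this definition as the whitelist that
    drops alignments to unanchored scaffolds.
    """

    chromosomes: tuple[Chromosome, ...]
    _by_name: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name = {}
        for c in self.chromosomes:
            if c.name in by_name:
                raise GenomeError(f"duplicate chromosome name {c.name!r}")
            by_name[c.name] = c
        object.__setattr__(self, "_by_name", by_name)

    @classmethod
    def from_items(cls, items: Iterable[tuple]) -> "GenomeDef":
        """Build from ``(name, length)`` or ``(name, length, centromere)`` tuples."""
        return cls(tuple(Chromosome(*item) for item in items))

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def length_of(self, name: str) -> int:
        return self._by_name[name].length


@dataclass(frozen=True, order=True)
class Bin:
    """A sliding-window bin, half-open [start, end), with its ordinal on the chromosome."""

    chrom: str
    start: int
    end: int
    index: int

    @property
    def width(self) -> int:
        return self.end - self.start


def load_genome(path: Union[str, Path]) -> GenomeDef:
    """Read a genome definition from a TSV with columns chrom, length, centromere.

    The centromere column may be blank or missing entirely. Lines starting with
    ``#`` are comments; a ``chrom<TAB>length...`` header row is skipped if present.
    File order is preserved.
    """
    chroms: list[Chromosome] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 or (not chroms and fields[0] == "chrom"):
                if fields[0].strip().lower() == "chrom":
                    continue
            if len(fields) < 2:
                raise GenomeError(f"{path}: line {lineno}: expected at least 2 tab-separated columns")
            name = fields[0].strip()
            try:
                length = int(fields[1])
            except ValueError:
                raise GenomeError(f"{path}: line {lineno}: length {fields[1]!r} is not an integer") from None
            cen: Optional[int] = None
            if len(fields) >= 3 and fields[2].strip() not in ("", "NA", "."):
                try:
                    cen = int(fields[2])
                except ValueError:
                    raise GenomeError(
                        f"{path}: line {lineno}: centromere {fields[2]!r} is not an integer"
                    ) from None
            try:
                chroms.append(Chromosome(name, length, cen))
            except GenomeError as e:
                raise GenomeError(f"{path}: line {lineno}: {e}") from None
    if not chroms:
        raise GenomeError(f"{path}: no chromosomes found")
    return GenomeDef(tuple(chroms))


def write_genome(genome: GenomeDef, path: Union[str, Path]) -> None:
    """Write a genome definition TSV readable by :func:`load_genome`."""
    with open(path, "w") as fh:
        fh.write("chrom\tlength\tcentromere\n")
        for c in genome:
            cen = "" if c.centromere is None else str(c.centromere)
            fh.write(f"{c.name}\t{c.length}\t{cen}\n")


def make_bins(genome: GenomeDef, bin_size: int = 100_000_000, step_size: int = 50_000_000) -> list[Bin]:
    """Tile every chromosome with sliding windows of ``bin_size`` stepping by ``step_size``.

    Bin starts are 0, step, 2*step, ... for every start strictly below the
    chromosome length; each end is clipped to the chromosome. With the default
    100 Mb / 50 Mb grid, interior positions are covered by exactly two bins.
    Terminal bins shorter than ``bin_size`` are kept: the per-bin median
    normalization cancels their smaller expected counts.
    """
    if bin_size <= 0 or step_size <= 0:
        raise GenomeError(f"bin_size and step_size must be positive, got {bin_size}, {step_size}")
    if step_size > bin_size:
        raise GenomeError(f"step_size ({step_size}) must not exceed bin_size ({bin_size})")
    bins: list[Bin] = []
    for chrom in genome:
        index = 0
        start = 0
        while start < chrom.length:
            bins.append(Bin(chrom.name, start, min(start + bin_size, chrom.length), index))
            index += 1
            start += step_size
    return bins


def write_bins_bed(bins: Iterable[Bin], path: Union[str, Path]) -> None:
    """Export the bin grid as BED3 plus a bin-index column, for audit."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.index}\n")
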