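"""Convert aligned GBS tags (SAM/BAM) into per-sample tag-position tables.

A "tag" is a valid GBS read (unique barcode + enzyme cut site, trimmed
upstream by the demultiplexing pipeline); one primary alignment record is one
tag. The filter keeps a record only when it is uniquely and unambiguously
anchored:

* mapped (no 0x4 flag), primary (no 0x100/0x800);
* no ``XS:i`` optional field — aligners emit XS only when a secondary
  alignment score exists, so its absence marks a uniquely mapped read;
* reference name present in the genome definition (drops unanchored
  scaffolds);
* valid leftmost position.

MAPQ is deliberately not thresholded by default; an optional ``min_mapq`` is
available for stricter runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeDef

__all__ = [
    "TagPositionTable",
    "filter_alignments",
    "count_unique_tags",
    "read_tag_table",
    "write_tag_table",
    "read_sample_map",
]


class SamIngestError(ValueError):
    pass


@dataclass
class TagPositionTable:
    """Retained tag positions for one sample.

    ``records`` has columns ``chrom`` (str) and ``pos`` (int64, 0-based),
    one row per retained alignment record.
    """

    sample_id: str
    records: pd.DataFrame
    n_raw_alignments: int = 0
    n_retained: int = field(default=-1)

    def __post_init__(self) -> None:
        if list(self.records.columns) != ["chrom", "pos"]:
            self.records = self.records.loc[:, ["chrom", "pos"]]
        if self.n_retained < 0:
            self.n_retained = len(self.records)
        if self.n_retained != len(self.records):
            raise SamIngestError(
                f"sample {self.sample_id!r}: n_retained={self.n_retained} "
                f"but {len(self.records)} records"
            )
        if self.n_retained > self.n_raw_alignments:
            self.n_raw_alignments = max(self.n_raw_alignments, self.n_retained)

    def validate_against(self, genome: GenomeDef) -> None:
        """Raise if any record falls outside the genome's coordinate frame."""
        for chrom, sub in self.records.groupby("chrom", sort=False):
            if chrom not in genome:
                raise SamIngestError(f"sample {self.sample_id!r}: unknown chromosome {chrom!r}")
            pos = sub["pos"].to_numpy()
            if len(pos) and (pos.min() < 0 or pos.max() >= genome.length_of(chrom)):
                raise SamIngestError(
                    f"sample {self.sample_id!r}: tag position outside [0, {genome.length_of(chrom)}) on {chrom}"
                )


def filter_alignments(
    sam: Union[str, Path],
    genome: GenomeDef,
    sample_id: Optional[str] = None,
    min_mapq: Optional[int] = None,
) -> TagPositionTable:
    """Filter a SAM/BAM file down to uniquely-mapped, anchored tag positions.

    Parameters
    ----------
    sam
        Path to a SAM (plain text) or BAM file.
    genome
        Whitelist of anchored chromosomes; records aligned elsewhere are dropped.
    sample_id
        Defaults to the file name stem.
    min_mapq
        Optional MAPQ floor (off by default; the unique-mapping criterion is
        the absence of XS:i, not MAPQ).
    """
    path = Path(sam)
    if sample_id is None:
        sample_id = path.stem
    chroms: list[str] = []
    positions: list[int] = []
    n_raw = 0
    unknown_refs: set[str] = set()
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            header_refs = set(fh.references or ())
            for rec in fh:
                n_raw += 1
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.reference_id < 0 or rec.reference_start < 0:
                    continue
                if rec.has_tag("XS"):
                    continue
                rname = rec.reference_name
                if rname not in genome:
                    unknown_refs.add(rname)
                    continue
                if min_mapq is not None and rec.mapping_quality < min_mapq:
                    continue
                chroms.append(rname)
                positions.append(rec.reference_start)  # already 0-based
    except (ValueError, OSError) as e:
        raise SamIngestError(f"{path}: failed to parse SAM ({e})") from e
    missing_from_header = {r for r in unknown_refs if r not in header_refs}
    if missing_from_header:
        warnings.warn(
            f"{path}: reference name(s) absent from SAM header treated as unanchored: "
            f"{sorted(missing_from_header)[:5]}",
            stacklevel=2,
        )
    records = pd.DataFrame({"chrom": pd.Series(chroms, dtype=str), "pos": pd.Series(positions, dtype=np.int64)})
    table = TagPositionTable(sample_id=sample_id, records=records, n_raw_alignments=n_raw)
    table.validate_against(genome)
    return table


def count_unique_tags(tables: Sequence[TagPositionTable]) -> pd.Series:
    """Per-sample retained-tag totals, used for QC and normalization scaling."""
    return pd.Series(
        {t.sample_id: t.n_retained for t in tables},
        name="retained_tags",
        dtype=np.int64,
    )


def write_tag_table(tables: Iterable[TagPositionTable], path: Union[str, Path]) -> None:
    """Serialize tag positions as a long TSV: sample, chrom, pos."""
    frames = []
    for t in tables:
        df = t.records.copy()
        df.insert(0, "sample", t.sample_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["sample", "chrom", "pos"])
    out.to_csv(path, sep="\t", index=False)


def read_tag_table(path: Union[str, Path], genome: Optional[GenomeDef] = None) -> list[TagPositionTable]:
    """Load a long tag-position TSV back into per-sample tables (file order kept)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "pos": np.int64})
    tables = []
    for sample, sub in df.groupby("sample", sort=False):
        t = TagPositionTable(
            sample_id=str(sample),
            records=sub[["chrom", "pos"]].reset_index(drop=True),
            n_raw_alignments=len(sub),
        )
        if genome is not None:
            t.validate_against(genome)
        tables.append(t)
    return tables


def write_qc_summary(tables: Iterable[TagPositionTable], path: Union[str, Path]) -> None:
    """Per-sample raw/retained accounting TSV."""
    rows = [(t.sample_id, t.n_raw_alignments, t.n_retained) for t in tables]
    pd.DataFrame(rows, columns=["sample", "raw", "retained"]).to_csv(path, sep="\t", index=False)


def read_sample_map(path: Union[str, Path]) -> list[tuple[str, Path]]:
    """Read a two-column TSV mapping sample_id to a SAM/BAM path."""
    pairs: list[tuple[str, Path]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise SamIngestError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            sample, sam_path = fields
            if sample in seen:
                raise SamIngestError(f"{path}: line {lineno}: duplicate sample id {sample!r}")
            seen.add(sample)
            pairs.append((sample, Path(sam_path)))
    return pairs
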