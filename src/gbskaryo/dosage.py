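"""Dosage classification, sample QC, and aberration event calling.

Normalized tag counts are mapped to integer copy-number classes with a fixed
piecewise threshold table (lower-inclusive, upper-exclusive):

    [0, 0.25) -> 0x   [0.25, 0.75) -> 1x   [0.75, 1.25) -> 2x
    [1.25, 1.75) -> 3x   [1.75, 2.25) -> 4x   [2.25, 2.75) -> 5x
    [2.75, inf) -> 6x (six or more copies)

Event calling turns maximal runs of equal non-disomic class into whole-
chromosome aneuploidy calls (nullisomic/monosomic/trisomic/tetrasomic),
terminal deletions, or interior segmental calls. No-call bins are transparent
for run merging; isolated single-bin aberrations (typical of centromeric
undersampling noise) are suppressed by the default minimum run length of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .binmatrix import NormalizedMatrix
from .genome import Bin, GenomeDef

__all__ = [
    "DOSAGE_EDGES",
    "NO_CALL",
    "classify_dosage",
    "classify_values",
    "DosageTrack",
    "classify_tracks",
    "SampleQC",
    "qc_samples",
    "EventCall",
    "call_events",
    "write_tracks_tsv",
    "write_events_tsv",
]

#: Upper boundaries of classes 0..5; values >= the last edge are class 6.
DOSAGE_EDGES = np.array([0.25, 0.75, 1.25, 1.75, 2.25, 2.75])

#: Sentinel class for masked / no-call bins in integer class arrays.
NO_CALL = -1

WHOLE_CHROMOSOME_LABELS = {
    0: "nullisomic",
    1: "monosomic",
    3: "trisomic",
    4: "tetrasomic",
    5: "pentasomic",
    6: "polysomic (6x+)",
}


class DosageError(ValueError):
    pass


def classify_dosage(value: float) -> int:
    """Map one normalized tag count to its copy-number class (0-6).

    Boundaries are lower-inclusive: 0.25 -> 1, 0.75 -> 2, 2.75 -> 6.
    """
    if not np.isfinite(value) or value < 0:
        raise DosageError(f"normalized value must be finite and >= 0, got {value}")
    return int(np.searchsorted(DOSAGE_EDGES, value, side="right"))


def classify_values(values: np.ndarray) -> np.ndarray:
    """Vectorized classification; NaN maps to NO_CALL."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if (values[finite] < 0).any():
        raise DosageError("negative normalized values")
    out = np.full(values.shape, NO_CALL, dtype=np.int64)
    out[finite] = np.searchsorted(DOSAGE_EDGES, values[finite], side="right")
    return out


@dataclass
class DosageTrack:
    """Per-bin normalized values and dosage classes for one sample."""

    sample_id: str
    bins: list[Bin]
    values: np.ndarray  # float, NaN = no-call
    classes: np.ndarray  # int, NO_CALL = no-call

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.classes = np.asarray(self.classes, dtype=np.int64)
        n = len(self.bins)
        if self.values.shape != (n,) or self.classes.shape != (n,):
            raise DosageError("track arrays must match bin count")
        if ((self.classes == NO_CALL) != ~np.isfinite(self.values)).any():
            raise DosageError("dosage class must be defined exactly where the value is defined")


def classify_tracks(norm: NormalizedMatrix) -> list[DosageTrack]:
    """Classify every sample column of a normalized matrix into a dosage track."""
    tracks = []
    for j, sample in enumerate(norm.samples):
        col = norm.values[:, j]
        tracks.append(
            DosageTrack(sample_id=sample, bins=norm.bins, values=col, classes=classify_values(col))
        )
    return tracks


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    retained_tags: int
    passed: bool
    reason: str = ""


def qc_samples(totals: pd.Series, min_tags: int = 10_000) -> list[SampleQC]:
    """Flag samples whose retained-tag total is too low for reliable calls.

    Failed samples are still normalized (their contribution to per-bin medians
    is negligible) but their downstream calls are marked unreliable.
    """
    out = []
    for sample, total in totals.items():
        ok = int(total) >= min_tags
        out.append(
            SampleQC(
                sample_id=str(sample),
                retained_tags=int(total),
                passed=ok,
                reason="" if ok else f"retained tags {int(total)} < min_tags {min_tags}",
            )
        )
    return out


def write_qc_tsv(qcs: Iterable[SampleQC], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(q.sample_id, q.retained_tags, q.passed, q.reason) for q in qcs],
        columns=["sample", "retained_tags", "pass", "reason"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EventCall:
    """One contiguous non-disomic run on one chromosome of one sample."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    dosage_class: int
    n_bins: int
    terminal: bool
    whole_chromosome: bool
    label: str

    def __post_init__(self) -> None:
        if self.dosage_class == 2:
            raise DosageError("an event cannot have the disomic class")
        if self.whole_chromosome and not self.terminal:
            raise DosageError("a whole-chromosome event is terminal by definition")


def _label_event(
    cls: int,
    touches_start: bool,
    touches_end: bool,
    arm_level: bool,
) -> str:
    whole = touches_start and touches_end
    if whole:
        return WHOLE_CHROMOSOME_LABELS.get(cls, f"{cls}x whole-chromosome")
    if (touches_start ^ touches_end) and cls in (0, 1):
        label = "terminal deletion"
        if arm_level:
            label += " (arm-level)"
        if cls == 1:
            label += " (heterozygous/single-copy)"
        return label
    return "segmental"


def call_events(
    track: DosageTrack,
    genome: GenomeDef,
    min_run_length: int = 2,
) -> list[EventCall]:
    """Summarize a classified track into aberration events.

    A run is a maximal stretch of called bins sharing one class != 2 within a
    chromosome; no-call bins neither break runs nor count towards ``n_bins``.
    Runs shorter than ``min_run_length`` called bins are suppressed. A run is
    terminal when every bin between it and a chromosome end is no-call; a run
    terminal at both ends is a whole-chromosome event. When a centromere
    position is available and a terminal deletion's interior boundary lies
    within one bin step of it, the event is annotated as arm-level.
    """
    if min_run_length < 1:
        raise DosageError("min_run_length must be >= 1")
    events: list[EventCall] = []
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(track.bins):
        by_chrom.setdefault(b.chrom, []).append(i)

    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: track.bins[i].start)
        called = [i for i in idxs if track.classes[i] != NO_CALL]
        if not called:
            continue
        # maximal equal-class runs over the called-only sequence
        runs: list[tuple[int, list[int]]] = []
        for i in called:
            c = int(track.classes[i])
            if runs and runs[-1][0] == c:
                runs[-1][1].append(i)
            else:
                runs.append((c, [i]))
        chrom_len = genome.length_of(chrom) if chrom in genome else max(track.bins[i].end for i in idxs)
        centromere = genome[chrom].centromere if chrom in genome else None
        step = (
            track.bins[idxs[1]].start - track.bins[idxs[0]].start
            if len(idxs) > 1
            else track.bins[idxs[0]].width
        )
        for cls, members in runs:
            if cls == 2 or len(members) < min_run_length:
                continue
            touches_start = members[0] == called[0]
            touches_end = members[-1] == called[-1]
            start_bp = track.bins[members[0]].start if not touches_start else 0
            end_bp = track.bins[members[-1]].end if not touches_end else chrom_len
            arm_level = False
            if centromere is not None and (touches_start ^ touches_end):
                interior_bp = end_bp if touches_start else start_bp
                arm_level = abs(interior_bp - centromere) <= step
            events.append(
                EventCall(
                    sample_id=track.sample_id,
                    chrom=chrom,
                    start_bp=int(start_bp),
                    end_bp=int(min(end_bp, chrom_len)),
                    dosage_class=cls,
                    n_bins=len(members),
                    terminal=touches_start or touches_end,
                    whole_chromosome=touches_start and touches_end,
                    label=_label_event(cls, touches_start, touches_end, arm_level),
                )
            )
    return events


def write_tracks_tsv(tracks: Sequence[DosageTrack], path: Union[str, Path]) -> None:
    """Long-form TSV: sample, chrom, start, end, normalized, dosage (NA = no-call)."""
    rows = []
    for t in tracks:
        for b, v, c in zip(t.bins, t.values, t.classes):
            rows.append(
                (
                    t.sample_id,
                    b.chrom,
                    b.start,
                    b.end,
                    np.nan if not np.isfinite(v) else round(float(v), 6),
                    np.nan if c == NO_CALL else int(c),
                )
            )
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "normalized", "dosage"]).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def write_events_tsv(events: Iterable[EventCall], path: Union[str, Path]) -> None:
    """BED-like events TSV."""
    pd.DataFrame(
        [
            (
                e.chrom,
                e.start_bp,
                e.end_bp,
                e.sample_id,
                e.dosage_class,
                e.label,
                e.n_bins,
                e.terminal,
                e.whole_chromosome,
            )
            for e in events
        ],
        columns=["chrom", "start", "end", "sample", "dosage", "label", "n_bins", "terminal", "whole_chromosome"],
    ).to_csv(path, sep="\t", index=False)
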