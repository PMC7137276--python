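"""End-to-end chaining of the analysis stages.

``run_pipeline`` takes per-sample tag tables and a genome definition and
produces bin counts, the normalized matrix, per-sample dosage tracks, QC
flags, and event calls — the same composition the command-line ``pipeline``
subcommand executes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .binmatrix import BinCountMatrix, NormalizedMatrix, count_bins, normalize
from .dosage import DosageTrack, EventCall, SampleQC, call_events, classify_tracks, qc_samples
from .genome import Bin, GenomeDef, make_bins
from .ingest import TagPositionTable, count_unique_tags

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    genome: GenomeDef
    bins: list[Bin]
    counts: BinCountMatrix
    normalized: NormalizedMatrix
    tracks: list[DosageTrack]
    qc: list[SampleQC]
    events: list[EventCall]
    accounting: pd.DataFrame = field(default_factory=pd.DataFrame)

    def track(self, sample_id: str) -> DosageTrack:
        for t in self.tracks:
            if t.sample_id == sample_id:
                return t
        raise KeyError(sample_id)


def run_pipeline(
    tables: Sequence[TagPositionTable],
    genome: GenomeDef,
    bin_size: int = 100_000_000,
    step_size: int = 50_000_000,
    min_tags: int = 10_000,
    min_run_length: int = 2,
) -> PipelineResult:
    """Counts -> normalization -> classification -> QC -> event calls.

    Samples failing the tag-count QC still pass through normalization (their
    weight in per-bin medians is negligible) but contribute no event calls;
    their tracks remain available for inspection.
    """
    bins = make_bins(genome, bin_size=bin_size, step_size=step_size)
    counts = count_bins(tables, bins, genome=genome)
    normalized = normalize(counts)
    tracks = classify_tracks(normalized)
    totals = count_unique_tags(tables)
    qc = qc_samples(totals, min_tags=min_tags)
    passed = {q.sample_id for q in qc if q.passed}
    events: list[EventCall] = []
    for t in tracks:
        if t.sample_id in passed:
            events.extend(call_events(t, genome, min_run_length=min_run_length))
    accounting = pd.DataFrame(
        [
            (t.sample_id, t.n_raw_alignments, t.n_retained, t.sample_id in passed)
            for t in tables
        ],
        columns=["sample", "raw_alignments", "retained_tags", "qc_pass"],
    )
    return PipelineResult(
        genome=genome,
        bins=bins,
        counts=counts,
        normalized=normalized,
        tracks=tracks,
        qc=qc,
        events=events,
        accounting=accounting,
    )
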