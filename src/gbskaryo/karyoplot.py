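"""Karyotype ideograms colored by per-bin dosage class.

Each sample is drawn as one vertical bar per chromosome (chromosome names on
the top axis, position in Mb down the bar), every plotting interval filled
with the color of its dosage class, and centromeres marked with a black
line-plus-diamond. The 50%-overlapping analysis bins are first reduced to
non-overlapping step-sized plotting intervals; that geometry is computed in
data coordinates by :func:`plot_segments` and is unit-testable without
touching the rendering backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dosage import NO_CALL, DosageTrack, call_events, write_events_tsv
from .genome import GenomeDef

__all__ = [
    "DEFAULT_COLOR_MAP",
    "KaryotypePlotSpec",
    "plot_segments",
    "render_karyotype",
    "render_cohort_report",
]

#: Colorblind-friendly 7-class palette; disomic (2x) in neutral grey so
#: aberrations stand out. NO_CALL is drawn white with hatching.
DEFAULT_COLOR_MAP = {
    0: "#b2182b",
    1: "#ef8a62",
    2: "#c8c8c8",
    3: "#92c5de",
    4: "#2166ac",
    5: "#8073ac",
    6: "#1b7837",
    NO_CALL: "#ffffff",
}

MB = 1_000_000


class KaryoplotError(ValueError):
    pass


@dataclass
class KaryotypePlotSpec:
    """Everything needed to draw one sample's karyotype."""

    sample_id: str
    track: DosageTrack
    genome: GenomeDef
    color_map: dict = field(default_factory=lambda: dict(DEFAULT_COLOR_MAP))
    scale: float = MB  # bp per axis unit (default: axis in Mb)
    reduce: str = "start"  # how overlapping bins map to plotting intervals

    def __post_init__(self) -> None:
        missing = [c for c in list(range(7)) + [NO_CALL] if c not in self.color_map]
        if missing:
            raise KaryoplotError(f"color_map missing classes: {missing}")
        for b in self.track.bins:
            if b.chrom not in self.genome:
                raise KaryoplotError(f"track chromosome {b.chrom!r} not in genome")


def plot_segments(track: DosageTrack, genome: GenomeDef, reduce: str = "start") -> pd.DataFrame:
    """Reduce overlapping bins to non-overlapping plotting intervals.

    Each step interval ``[k*step, (k+1)*step)`` takes the class of the bin
    starting at ``k*step`` when one exists (``reduce="start"``), or the
    maximum class among covering bins (``reduce="max"``); intervals with no
    covering call are NO_CALL. Returns columns chrom, start, end, dosage;
    per chromosome the intervals tile ``[0, length)`` exactly.
    """
    if reduce not in ("start", "max"):
        raise KaryoplotError(f"unknown reduction {reduce!r}")
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(track.bins):
        by_chrom.setdefault(b.chrom, []).append(i)
    rows = []
    for chrom, idxs in by_chrom.items():
        if chrom not in genome:
            raise KaryoplotError(f"unknown chromosome {chrom!r}")
        length = genome.length_of(chrom)
        idxs = sorted(idxs, key=lambda i: track.bins[i].start)
        starts = [track.bins[i].start for i in idxs]
        step = starts[1] - starts[0] if len(starts) > 1 else track.bins[idxs[0]].width
        k = 0
        while k * step < length:
            seg_start = k * step
            seg_end = min((k + 1) * step, length)
            covering = [
                i
                for i in idxs
                if track.bins[i].start <= seg_start and track.bins[i].end >= seg_end
            ]
            starting = [i for i in covering if track.bins[i].start == seg_start]
            if reduce == "start" and starting:
                cls = int(track.classes[starting[0]])
            else:
                called = [int(track.classes[i]) for i in covering if track.classes[i] != NO_CALL]
                cls = max(called) if called else NO_CALL
            rows.append((chrom, seg_start, seg_end, cls))
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dosage"])


def render_karyotype(spec: KaryotypePlotSpec, out_path: Union[str, Path]) -> Path:
    """Render one sample's karyotype ideogram to an image file (PNG/SVG/PDF)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch, Rectangle

    segments = plot_segments(spec.track, spec.genome, reduce=spec.reduce)
    if segments.empty:
        raise KaryoplotError(f"sample {spec.sample_id!r}: no classified bins to plot")
    chrom_names = [c.name for c in spec.genome if c.name in set(segments["chrom"])]
    scale = spec.scale

    fig, ax = plt.subplots(figsize=(max(6.0, 0.55 * len(chrom_names) + 1.5), 5.0))
    bar_width = 0.62
    for x, chrom in enumerate(chrom_names):
        sub = segments[segments["chrom"] == chrom]
        for _, seg in sub.iterrows():
            cls = int(seg["dosage"])
            ax.add_patch(
                Rectangle(
                    (x - bar_width / 2, seg["start"] / scale),
                    bar_width,
                    (seg["end"] - seg["start"]) / scale,
                    facecolor=spec.color_map[cls],
                    edgecolor="none",
                    hatch="////" if cls == NO_CALL else None,
                )
            )
        length = spec.genome.length_of(chrom)
        ax.add_patch(
            Rectangle(
                (x - bar_width / 2, 0),
                bar_width,
                length / scale,
                facecolor="none",
                edgecolor="black",
                linewidth=0.6,
            )
        )
        cen = spec.genome[chrom].centromere
        if cen is not None:
            y = cen / scale
            ax.plot([x - bar_width / 2, x + bar_width / 2], [y, y], color="black", linewidth=1.2)
            ax.plot([x], [y], marker="D", color="black", markersize=4)

    max_len = max(spec.genome.length_of(c) for c in chrom_names)
    ax.set_xlim(-0.75, len(chrom_names) - 0.25)
    ax.set_ylim(max_len / scale * 1.02, -max_len / scale * 0.02)  # position increases downward
    ax.set_xticks(range(len(chrom_names)))
    ax.set_xticklabels(chrom_names, fontsize=8)
    ax.xaxis.tick_top()
    ax.set_ylabel("Position (Mb)")
    ax.set_title(spec.sample_id, pad=28)
    handles = [
        Patch(facecolor=spec.color_map[c], edgecolor="black", linewidth=0.3, label=f"{c}x")
        for c in range(7)
    ]
    handles.append(
        Patch(facecolor=spec.color_map[NO_CALL], edgecolor="black", hatch="////", label="no call")
    )
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=7, frameon=False)
    for side in ("left", "right", "bottom"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def render_cohort_report(
    tracks: Sequence[DosageTrack],
    genome: GenomeDef,
    out_dir: Union[str, Path],
    fmt: str = "png",
    min_run_length: int = 2,
    color_map: Optional[dict] = None,
) -> pd.DataFrame:
    """Render one karyotype image per sample plus a cohort-wide event summary TSV.

    Returns the event summary as a DataFrame; the TSV is written to
    ``<out_dir>/events_summary.tsv`` and images as ``<out_dir>/<sample>.<fmt>``.
    """
    if not tracks:
        raise KaryoplotError("no tracks to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_events = []
    for track in tracks:
        spec = KaryotypePlotSpec(
            sample_id=track.sample_id,
            track=track,
            genome=genome,
            color_map=dict(color_map) if color_map else dict(DEFAULT_COLOR_MAP),
        )
        render_karyotype(spec, out_dir / f"{track.sample_id}.{fmt}")
        all_events.extend(call_events(track, genome, min_run_length=min_run_length))
    write_events_tsv(all_events, out_dir / "events_summary.tsv")
    return pd.read_csv(out_dir / "events_summary.tsv", sep="\t")
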