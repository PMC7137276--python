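# gbskaryo

Read-depth karyotyping from genotyping-by-sequencing (GBS) tag alignments:
detect whole-chromosome aneuploidy (nullisomic, monosomic, trisomic,
tetrasomic) and terminal or segmental chromosome deletions from low-coverage
reduced-representation sequencing, and draw color-coded karyotype ideograms.

It is aimed at curators of plant genetic stocks — wheat aneuploid and
deletion lines in particular — who want a fast in-silico alternative to
C-banding/FISH/GISH cytogenetics: a cohort of GBS libraries aligned to a
reference is enough to read off chromosome dosage per sample.

## Method

For each sample, uniquely mapped GBS tags (primary alignments with no `XS:i`
auxiliary field, anchored to a named chromosome) are counted in sliding
windows (default 100 Mb bins stepping by 50 Mb). Counts are normalized in two
stages:

1. **Library size** — every sample column is scaled to the median per-sample
   total, removing sequencing-depth differences;
2. **Per-bin median** — each bin is divided by its across-sample median, so a
   bin at the cohort-typical two copies sits at 1.0.

The normalized count *x* of a bin is then linear in copy number:
*x* ≈ *c*/2 for *c* copies. Bins are classified with fixed thresholds

| normalized value | [0, 0.25) | [0.25, 0.75) | [0.75, 1.25) | [1.25, 1.75) | [1.75, 2.25) | [2.25, 2.75) | ≥ 2.75 |
|---|---|---|---|---|---|---|---|
| dosage | 0x | 1x | 2x | 3x | 4x | 5x | 6x+ |

and maximal runs of equal non-disomic class become event calls
(whole-chromosome aneuploidy, terminal deletion, or interior segmental
change). Isolated single-bin deviations — typical of centromeric regions,
which methylation-sensitive GBS enzymes undersample — are suppressed by a
minimum run length of 2 bins. Samples with too few tags (default < 10,000)
are flagged as unreliable.

The assumption behind stage 2 is that **most samples are disomic at every
bin**; a deletion shared by more than half the cohort is invisible (see
`docs/methods.md` for this and other limitations).

A seeded simulator (`gbskaryo.synth`) generates cohorts with known
copy-number truth — shared tag-site lists, log-normal per-sample depth,
centromeric site depletion, arbitrary per-region multipliers — so the whole
pipeline is verifiable without any external data.

## Worked example

Simulate a 20-sample cohort on a 1:10-scale 21-chromosome wheat-like genome
(10 Mb bins / 5 Mb step, mean 100,000 tags per sample) in which one sample
lacks both copies of 1A, carries four copies of 1B and a single copy of 4A:

```python
from gbskaryo import (AberrationSpec, make_bins, run_pipeline,
                      simulate_cohort, wheat_like_genome)

genome = wheat_like_genome(0.1)
specs = [AberrationSpec(f"euploid{i:02d}") for i in range(19)]
ab = AberrationSpec("aberrant")
for chrom, m in (("1A", 0.0), ("1B", 2.0), ("4A", 0.5)):
    ab = ab.whole_chromosome(genome, chrom, m)
specs.append(ab)

bins = make_bins(genome, 10_000_000, 5_000_000)
tables, truth, manifest = simulate_cohort(
    genome, specs, bins, site_density=500.0, centromere_depletion=0.8,
    centromere_radius_bp=5_000_000, mean_tags=100_000, dispersion=0.5, seed=1)

result = run_pipeline(tables, genome, bin_size=10_000_000, step_size=5_000_000)
for e in result.events:
    print(f"{e.sample_id}\t{e.chrom}:{e.start_bp}-{e.end_bp}\t{e.dosage_class}x\t{e.label}")
```

prints

```
aberrant	1A:0-59400000	0x	nullisomic
aberrant	1B:0-69000000	4x	tetrasomic
aberrant	4A:0-74500000	1x	monosomic
```

i.e. the three engineered aberrations, and nothing else, are called. The
per-chromosome mean normalized values behind those calls are 0.000 (1A),
2.022 (1B), 0.525 (4A) and 1.013 on an unaffected chromosome (2D) — right at
the c/2 expectations of 0, 2, 0.5 and 1. Karyotype ideograms come from
`render_cohort_report(result.tracks, genome, "karyotypes/")`.

The same run from a shell, starting from SAM files:

```sh
gbskaryo simulate --out-dir sim --sam --seed 1       # or bring your own SAMs
gbskaryo pipeline --genome sim/genome.tsv sim/sam/*.sam --out-dir run \
    --bin-size 10000000 --step-size 5000000
```

`run/` then contains `bin_counts.tsv`, `normalized.tsv`, `dosage_tracks.tsv`,
`events.tsv`, `sample_qc.tsv`, per-sample karyotype images and an
`accounting.tsv` tracing raw alignments → uniquely mapped anchored tags →
QC-passing samples per sample.

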