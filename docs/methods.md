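# Methods

## Model

The pipeline infers chromosome and segment dosage from the depth of
genotyping-by-sequencing (GBS) tags. GBS samples a reproducible subset of
genomic sites (restriction-enzyme cut sites), so for a fixed cohort the set
of mappable tag positions is essentially a genome property; what varies is
how many tags each sample recovers at each site. If a sample carries *c*
copies of a region instead of the typical two, its expected tag count there
scales by *c*/2. The method turns that proportionality into per-bin dosage
calls:

1. **Ingest.** Keep one tag per primary SAM record that is mapped, not
   secondary/supplementary, carries no `XS:i` auxiliary field (aligners only
   emit a secondary-alignment score when one exists, so its absence marks a
   uniquely mapped read), and is anchored to a chromosome listed in the
   genome definition. 1-based SAM positions are converted to the internal
   0-based half-open frame at this boundary and nowhere else. MAPQ is not
   thresholded by default — uniqueness is decided by `XS:i` alone — but an
   optional `min_mapq` exists for stricter runs.
2. **Binning.** Tags are counted in sliding windows, by default 100 Mb wide
   stepping 50 Mb, so interior positions fall in exactly two windows.
   Terminal windows shorter than the bin size are kept: their smaller
   expected counts are shared by all samples and cancel in step 4.
3. **Library-size normalization.** Each sample column is rescaled to the
   median per-sample total. The median was chosen for robustness to the
   heavy right-skew of per-sample totals across GBS batches; the choice of
   target is provably immaterial to the final calls (scale invariance: the
   per-bin division below absorbs any per-sample constant — asserted as a
   test).
4. **Per-bin median normalization.** Each bin row is divided by its
   across-sample median. Under the assumption that most samples are disomic
   at every bin, the result is centred at 1.0 for two copies and is linear
   in dosage (0.5 ↔ 1x, 1.5 ↔ 3x, 2.0 ↔ 4x). Bins with a zero median
   cannot be normalized and are masked (no-call) rather than divided.
5. **Classification.** Fixed thresholds partition [0, ∞) into classes 0x–6x
   at 0.25, 0.75, 1.25, 1.75, 2.25, 2.75. Intervals are lower-inclusive /
   upper-exclusive (the top class closed below), which makes the mapping a
   total, monotone partition; exact boundary hits are measure-zero in
   practice, so the convention never matters for data.
6. **Event calling.** Within each chromosome, maximal runs of called bins
   sharing one class ≠ 2 become events; no-call bins bridge runs of equal
   class but do not count toward run length. Runs shorter than
   `min_run_length` (default 2 bins, i.e. ≥ one full bin width of signal)
   are suppressed — this operationalizes the rule of thumb that isolated
   centromere-adjacent deviations should not be trusted unless they connect
   to a terminal aberration. Runs reaching both chromosome ends are labeled
   by the classical nomenclature (nullisomic / monosomic / trisomic /
   tetrasomic; 5x/6x get "pentasomic"/"polysomic"); runs reaching exactly
   one end with class 0 or 1 are terminal deletions (class 1 annotated
   heterozygous/single-copy, and annotated arm-level when the interior
   boundary lies within one bin step of a supplied centromere); everything
   else is segmental. Terminal gains (class ≥ 3 touching one end) also fall
   under "segmental" — the terminal-deletion label is reserved for losses.
7. **QC.** Samples with fewer than `min_tags` retained tags (default
   10,000) are flagged; they still enter normalization (their weight in a
   cohort-sized median is negligible) but contribute no event calls. The
   default sits between the documented failure regime (tag totals in the
   tens to low thousands) and typical libraries (~2×10^5 tags).

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `bin_size` / `step_size` | 100 Mb / 50 Mb | bp | resolution vs. counting noise trade-off; ~700 bins over a 14 Gb genome. Scaled runs (e.g. 10/5 Mb on a 1:10 genome) are equivalent because the whole method is scale-free. |
| `min_tags` | 10,000 | tags | QC gate on retained tags per sample |
| `min_run_length` | 2 | bins | 1 reproduces raw per-bin classification |
| thresholds | 0.25 + 0.5k | normalized count | midpoints at c/2 for class c |

## The simulator

`gbskaryo.synth` emulates exactly the features the method relies on:

* **shared site list** — candidate sites are placed uniformly per chromosome
  (Poisson count, expectation `site_density` × length); near centromeres
  sites are retained with probability 1 − `centromere_depletion` within
  `centromere_radius_bp`, mimicking the scarcity of methylation-sensitive
  cut sites there. Because all samples share the list, per-bin site-count
  variation cancels in normalization — as it does for real cohorts.
* **depth skew** — each sample draws a log-normal depth factor
  (mean-one parameterization, log-sd `dispersion`, default 0.5), matching
  the skewed, batch-dependent per-sample totals of multiplexed GBS runs.
* **dosage** — each site is observed with probability
  min(1, base_rate × depth × multiplier), where the multiplier comes from
  the sample's aberration spec (1 = disomic) and base_rate is calibrated so
  a euploid sample at depth 1 yields `mean_tags` tags. Defaults (500
  sites/Mb at 1:10 scale ≈ 7×10^5 sites; 1–2×10^5 tags/sample) keep the
  per-site rate ≈ 0.15, well inside the linear Bernoulli regime.

What it does **not** model: PCR duplicates and amplification bias beyond the
centromere knob, flowcell/batch covariates (only the marginal depth skew),
read sequences (positions suffice), and mapping error beyond explicit
`XS:i`-tagged decoy records. Passing recovery tests therefore demonstrate
correctness of the counting/normalization/classification machinery under a
faithful depth model — not robustness to PCR artifacts, which real cohorts
are known to exhibit (interpreted there as unreliable karyotypes).

The bundled `wheat_like_genome()` has 21 chromosomes whose lengths match
common wheat to the Mb; tests use it at 1:10 scale. Chromosomes whose length
leaves a sub-step remainder (2B, 2D, 3A, 7B) end in a "sliver" bin of < 2 Mb
(full scale) with only tens of expected tags; these bins are classified
noisily and account for all residual misclassification in the recovery
tests (99.2% of unmasked non-centromeric bins recover their true class
across ten seeded cohorts, and every miss is a sliver bin). Event calls are
immune because of the run-length filter.

## Numerical choices and degenerate inputs

* Medians use the standard even-count convention (mean of central order
  statistics). Per-bin medians after both stages equal 1 to 1e-9 by
  construction and are asserted exactly.
* A sample with zero total tags makes total-normalization undefined; the
  pipeline raises and directs the caller to QC exclusion rather than
  silently dropping it.
* A chromosome shorter than one step yields exactly one bin [0, length).
* Truth bins straddling an aberration boundary take the length-weighted
  majority multiplier.
* Matrices are dense float64 (~1,000 bins × ~600 samples is tiny).
* Karyotype geometry (the reduction of 50%-overlapping bins to step-sized
  plotting intervals — each interval takes the class of the bin starting at
  its left edge, with a max-class alternative) is computed in data
  coordinates and tested independently of matplotlib.

## Known limitations

* A deletion shared by > 50% of the cohort shifts the bin median and becomes
  invisible (or mis-scales everyone else); the cohort-median design trades
  absolute calibration for reference-free operation.
* No sub-bin breakpoint refinement and no statistical confidence on calls;
  dosage is called per bin independently (no HMM smoothing).
* Centromeric bins are intrinsically noisy; single-bin deviations there are
  suppressed, not resolved.
* Double-ditelosomic stocks are reported as arm-level terminal deletions
  (when a centromere is supplied), not as a distinct genotype class.
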