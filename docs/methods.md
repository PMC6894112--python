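# Methods

This note documents the models, rules and numerical choices behind
`meiomap`, and what the synthetic test bed does and does not establish
about real data.

## Coordinates and genome model

All coordinates are 1-based and inclusive, matching the CBS7435 reference
assembly used for the *K. phaffii* GS115 × Pp4 cross; BED output converts
to 0-based half-open at the file boundary. The default
`ChromosomeSet` hard-codes the four chromosomes (lengths 2,895,354 /
2,396,458 / 2,263,458 / 1,827,941 bp; centromere midpoints 1,404,539 /
847,809 / 37,576 / 61,908 — the midpoints of the unique central region
between the centromeric inverted repeats) and the subtelomere masks
excluded from event calling (chr1 < 8 kb and > 2861 kb; chr2 < 12 kb and
> 2373 kb; chr3 > 2168 kb; chr4 < 2 kb and > 1795 kb). Mask boundaries are
closed intervals: a marker at 8,000 is masked, one at 8,001 is not.

The *ARG4*–*HIS4* selection interval (421 kb, spanning *CEN1*) has no
published coordinates; `default_marked_interval()` is a synthetic
placement (*ARG4* 100 kb left of *CEN1*, inside the pericentromeric
low-diversity region where the gene lies) and real analyses should
configure the true positions. The 138-kb invertible *MAT* region on
chromosome 4 likewise has no published boundaries and is configurable
only.

## Event calling

A chromosome is segmented into maximal runs of markers sharing a
segregation vector. Runs with Mendelian allele sum (2 of 4 in a tetrad;
1 or 2 of 3 in a trio) and ≥ 2 supporting markers — or contact with the
unmasked chromosome end — are *anchors*; material between consecutive
anchors is classified deterministically:

1. a reciprocal two-spore switch between anchors is one crossover, its
   interval bracketed by the flanking informative markers;
2. a run bounded by identical anchors in which one spore deviates is a
   conversion tract (3:1/1:3); allele sums 0/4 give 4:0 tracts;
3. a single-spore deviation between anchors that differ reciprocally, or
   one persisting to the unmasked chromosome end, is one
   crossover-with-associated-conversion, counted once as a crossover;
4. conversion tracts supported by a single marker are discarded (the
   single-SNP noncrossover filter), and the anchor-support requirement
   applies the same single-marker skepticism symmetrically to crossovers;
5. everything else is flagged as a *complex region*, reported separately
   and never silently dropped or guessed into a count.

Rationale: the original study scored events manually after locating
segregation-pattern changes; these rules fix an explicit minimal-event
parsimony so results are reproducible. Design points worth noting:

* **Missing data** are handled by dropping, per ascus, every marker with
  any missing spore call (after subtelomere masking), so segmentation never
  compares vectors of unequal information. On a fixture this is verified to
  call the same events as a keep-and-skip oracle.
* **Trios.** Expected visible sums are 1 or 2. A persistent switch of one
  visible spore is a crossover with the `unsampled` chromatid. A bounded
  single-spore deviation is ambiguous — one conversion or two exchanges
  with the unsampled chromatid. It is scored as a conversion only when the
  deviant run spans ≤ `max_tract_span_bp` (default 25 kb, an order of
  magnitude above the modeled mean tract length); beyond that it is scored
  as two crossovers. Without the span limit, genuine distant double
  crossovers collapse into "tracts" and trio counts fall far below tetrad
  counts, contradicting the comparability observed in the real cross. A
  whole-chromosome non-Mendelian sweep (as in one real trio) yields zero
  crossovers and a single chromosome-length tract.
* **Terminal events.** A single-spore deviation persisting to the unmasked
  end is reported as a crossover-with-conversion whose partner is
  `unknown` (tetrads) or `unsampled` (trios); its interval extends to the
  edge of unmasked territory because the exchange point may lie beyond the
  outermost marker. A mask-truncated conversion tract is observationally
  indistinguishable from this configuration; rule 3 resolves the
  ambiguity in favor of the crossover, and the single-marker filter also
  applies to these terminal runs.
* **No merging window**: two same-pair crossovers separated by ≥ 2 markers
  are distinct events.

Two-locus classification (`classify_two_locus`) assigns each locus the
genotype of its nearest marker (ties toward the smaller coordinate) and
returns PD / NPD / TT, or `unclassifiable` for non-2:2 segregation; over
the 36 two-locus assignments with 2:2 at both loci the pattern counts are
6 PD, 6 NPD, 24 TT (verified by enumeration).

`designate_obligatory` implements the experimental-design rule for the
marked interval: among crossovers with midpoint inside the interval, the
one farthest from the centromere midpoint is the obligatory one; if the
interval contains none, a warning is recorded (the selection design
guarantees an odd number of exchanges there in real data).

## Landscape statistics

* The count-vs-length regression uses **one point per chromosome** — the
  chromosome total divided by the number of asci, unrounded — against
  length in kb; with the published 11-ascus table this yields the printed
  intercept of 1.37 crossovers. Rounding conventions elsewhere follow the
  printed precision: means 1 dp, crossovers/kb 5 dp, kb/crossover 1 dp,
  intercept 2 dp.
* Crossover–centromere distance uses the crossover interval midpoint (the
  point used by the source data is unstated; the interval is ~0.1–1 kb, so
  the choice is immaterial at the 100-kb scales of interest).
* The Kolmogorov–Smirnov uniformity test uses the exact small-sample
  p-value for n ≤ 100 (scipy's exact method) and the asymptotic form
  beyond; D is verified against a brute-force maximum over empirical-CDF
  corners, and the n = 1 midpoint case gives D = 0.5 analytically.
* `compare_reference_ratio` divides a reference mean by this cross's mean
  with both at 1-dp printed precision (90.5 / 25.5 → 3.5).

## Diversity scan

SNP positions are histogrammed in 1-kb bins (`bin i` covers
`[(i−1)·1000+1, i·1000]`; the last partial bin's density uses its true
width). A low-diversity region is called per centromere as the maximal
contiguous run of bins containing the centromere's bin whose smoothed
density is below the threshold (default 1 SNP/kb, against the ~4.5/kb
genome average of the divergent isolates). Smoothing is a centered moving
average over `smooth_window_kb` bins (default 21, edge-truncated); the
source analysis did not state its delimitation procedure, so boundaries
are comparable only to within roughly the smoothing window, and the
package treats published extents (362 kb around *CEN1*, 240 kb around
*CEN2*) as tolerance-level targets. Window 1 reproduces the raw profile
exactly, and raising the threshold can only grow a region.

## The meiosis simulator

Each chromosome is modeled as four chromatids (two per parental homolog).

* **Crossover counts** are Poisson with mean `co_rate_per_kb ×` the
  integral of a relative intensity over the chromosome; with
  `obligate_crossover` the count is zero-truncated (sampled by
  inverse-CDF, so the rate-0 limit is exactly one crossover).
* **Intensity shape**: zero within `suppression_radius_bp` of the
  centromere midpoint (default 150 kb), rising linearly to full over
  `ramp_bp` (default 50 kb) — matching the observed inflection of the
  distance distribution at ~150–200 kb — and zero inside subtelomere
  masks (optionally inside the *MAT* inversion). On the acrocentric
  chromosomes the suppression zone swallows the short arm entirely, as in
  the real genome; validation therefore requires only that some intensity
  mass remains per chromosome. Positions are sampled by inverse-CDF on a
  100-bp grid and clamped so no position falls inside the radius or a
  mask.
* **Chromatid choice**: each crossover links one chromatid drawn uniformly
  from each homolog (2 × 2 pairs). Sister-chromatid exchanges are not
  modeled (they are genetically invisible). No crossover or chromatid
  interference is modeled — no interference estimates exist for this
  cross; this is a known limitation.
* **Visibility.** After earlier exchanges, a crossover can link two
  chromatids identical-by-state distal to the exchange point (e.g. the
  second exchange of a three-strand double); it then changes no genotype
  and is unrecoverable in principle. The truth record flags each crossover
  `visible` accordingly. Because published per-meiosis counts are
  necessarily visible counts, `SimParams.calibrated` targets the expected
  number of *visible* crossovers (default 25.5 per meiosis), computed
  exactly from a two-state Markov chain over the chromatid-origin
  configuration; under this model the long-run visible fraction is 2/3,
  so the underlying true rate is calibrated ~1.5× higher.
* **Conversions**: Poisson(`nco_rate_per_chromosome`, default 1.5) per
  chromosome, uniform starts, geometric lengths with mean
  `conversion_tract_mean_bp` (default 2,000 bp). Both values are package
  choices — the source cross reports no tract statistics — stated here as
  such. Conversion is implemented as an allele flip of the recipient
  chromatid across the tract; conversions are not suppressed near
  centromeres (unknown in this species).
* **Markers**: inter-marker gaps are drawn i.i.d. from a two-component
  exponential mixture (weight 0.6 on a short-gap component; component
  means 80/224 and 440/224 of the overall mean gap). At the default
  4.46 SNP/kb this reproduces both the ~224-bp mean and the ~96-bp median
  gap of the real cross — real SNPs are clumped, and a homogeneous Poisson
  map (available as `clustered=False`) would have a 155-bp median.
* **Draw order** per chromosome is fixed (crossover count, positions,
  chromatid pairs, conversion count, per-tract start/length/recipient,
  missingness), making any (params, seed) pair bit-reproducible.
* **Study design**: `simulate_experiment` defaults to 5 tetrads + 6 trios,
  with trios alternately lacking spore `a` and spore `d` (the two
  phenotype classes that failed to germinate in the real cross).
* The synthetic SNP-density track is an inhomogeneous Poisson process;
  `default_low_diversity_regions()` places stand-ins for the two real
  pericentromeric regions (230+132 kb around *CEN1*, 110+130 kb around
  *CEN2*) at 0.4 SNP/kb inside (a package choice consistent with
  "below 1/kb") against a 4.75/kb background.

### What the simulator does not capture

Crossover/chromatid interference; conversion-tract length structure and
CO-associated conversion placement (real conversions cluster at crossover
sites); sequencing artifacts beyond uniform missingness (no genotyping
errors, no clustered dropout); marker ascertainment structure beyond the
gap mixture; selection effects in trios (spore death is genotype-linked in
reality, random here). Passing round-trip tests therefore demonstrates the
caller's correctness on the modeled signal classes, not robustness to
every artifact of real sequencing data.

## Validation against ground truth

Detector recovery is scored on *detectable* crossovers: visible ones
separated from every adjacent true event boundary by ≥ 2 unmasked markers
and lying ≥ 2 markers inside unmasked territory. On 50 simulated meioses
at study-scale parameters the caller recovers ≥ 99% of detectable
crossovers and every conversion-free call brackets a true crossover
position (`left_pos ≤ truth < right_pos`). Crossover-with-conversion
calls, and calls whose partner chromatid is undetermined (`unsampled` /
`unknown`), are additionally accepted when they overlap a true conversion
tract: a mask-truncated tract, overlapping opposite-direction tracts on
homologous chromatids, or (in trios) a tract boundary on a visible spore
are each observationally indistinguishable from such a crossover.

## Problem sizes

Test and acceptance runs use the study-scale genome (9.38 Mb, ~42,000
markers) with 11–50 simulated meioses for round-trip checks and 200
meioses at reduced marker density (1/kb) for parameter-recovery checks;
these sizes give tight stochastic bounds (3 SE) while keeping the full
suite fast.
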