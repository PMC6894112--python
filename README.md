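# meiomap

Tetrad analysis of meiotic recombination in the biotech yeast
*Komagataella phaffii* (formerly *Pichia pastoris*): from per-ascus SNP
genotype matrices to crossover and gene-conversion calls,
recombination-landscape statistics, and SNP-density low-diversity-region
calling — with a seedable meiosis simulator as a download-free test bed.

## The problem

*K. phaffii* grows as a haploid with four chromosomes. A cross between two
divergent isolates (the lab strain GS115 and the natural isolate Pp4,
~42,000 SNPs apart) produces asci of four spores; sequencing the spores of
each ascus genotypes every meiosis at every SNP marker. This package turns
those genotypes into biology:

* **Crossovers (COs)** — reciprocal exchanges between two of the four
  chromatids, visible as a persistent reciprocal switch of parental origin
  in two spores.
* **Gene conversions (NCOs)** — bounded tracts of 3:1 (or 4:0) segregation
  where one chromatid copied its homolog.
* **Landscape statistics** — crossovers per meiosis and per kb, the
  crossover-count vs chromosome-length regression (whose intercept ≈ 1
  reflects the obligate crossover each chromosome pair needs to segregate),
  crossover distances from centromeres (recombination is suppressed for
  ~150 kb around each *K. phaffii* centromere), and a Kolmogorov–Smirnov
  test of crossover-position uniformity in a marked interval.
* **Diversity scanning** — SNP counts in 1-kb bins against a reference,
  and the large low-diversity regions (< 1 SNP/kb) anchored on *CEN1* and
  *CEN2*.

Genotypes are coded per marker and spore as 0 (GS115/parent-0 allele) or
1 (Pp4/parent-1 allele); 2:2 segregation is the Mendelian expectation in a
tetrad. Asci that yielded only three spores ("trios") are handled
throughout, with crossover partners reported as `unsampled`.

## Worked example

Simulate an 11-ascus cross at the study design (5 tetrads + 6 trios,
~4.5 SNP/kb markers, pericentromeric crossover suppression), call events,
and summarize:

```python
from meiomap import simulate as sim, events as ev, landscape as ls, default_genome

genome = default_genome()                      # the four K. phaffii chromosomes
params = sim.SimParams.calibrated(genome)      # ~25.5 observable COs / meiosis
markers, asci = sim.simulate_experiment(genome, params, n_tetrads=5, n_trios=6, seed=1)

eventsets = [ev.call_ascus(a, markers, genome) for a, _ in asci]
summary = ls.summarize_counts(eventsets, genome)
fit = ls.fit_count_vs_length(summary)
print(summary.genome_total, round(summary.mean_per_meiosis, 1), round(fit.intercept, 2))
```

prints

```
294 26.7 2.86
```

— 294 crossovers over 11 meioses (26.7 per meiosis; each run of the
simulator fluctuates around the calibration target of 25.5). The
regression intercept from a single batch of 11 meioses is noisy (here
2.86; the real cross gives 1.37, and over hundreds of simulated meioses
with vanishing crossover rate the estimate converges to the obligate-
crossover value of 1).

The same arithmetic applied to the published count table of the real cross
is deterministic:

```python
from meiomap import datasets
summary = ls.summary_from_counts(datasets.cross_crossover_counts(), genome)
print(round(summary.mean_per_meiosis, 1),          # 25.5 COs per meiosis
      round(summary.crossovers_per_kb, 5),         # 0.00271
      round(summary.kb_per_crossover, 1),          # 368.6
      round(ls.fit_count_vs_length(summary).intercept, 2))   # 1.37
```

The command line mirrors the library:

```sh
meiomap simulate --seed 7 --tetrads 5 --trios 6 --out-dir run/
meiomap detect   --table run/genotypes.tsv --out-dir run/
meiomap landscape --events run/events.tsv --out-dir run/
meiomap plot     --table run/genotypes.tsv --ascus Tetrad1 --out-dir run/
```

`detect` writes an event table (TSV) and BED; `landscape` prints the
summary table and a JSON report; `plot` renders red/blue parental-origin
tracks per spore with green bars under non-Mendelian tracts. Real data
enter either as the same genotype TSV dialect (`ascus`, `chrom`, `pos`,
one column per spore; blank = missing) or as a joint multi-sample VCF via
`meiomap convert`, which keeps biallelic SNPs with distinct homozygous
parental calls and codes each spore by parental origin.

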