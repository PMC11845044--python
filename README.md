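# meiomap

Tetrad-based meiotic recombination mapping for budding yeast: crossover (CO)
and non-crossover gene-conversion (NCO) detection from parental-origin
genotypes, marker-density-corrected recombination landscapes, sequence
similarity tracks, and allele-shuffling statistics — plus a synthetic-meiosis
simulator with ground-truth events so every stage is testable without
sequencing data.

## Who this is for

Yeast tetrad-sequencing studies cross two homozygous strains, induce meiosis,
and sequence all four spores of each tetrad.  Every site where the parents
are homozygous for different alleles (a *fixed difference*) traces each
spore's chromosomes back to a parent.  In the absence of recombination the
four spores segregate 2:2 at every marker; a persistent 2:2 phase change in
which two spores exchange origin is a crossover, and a 3:1 run on a single
spore that reverts to the surrounding phase is a gene-conversion tract.  This
package implements that event calling and everything downstream, with
particular care for the marker-density artefacts that arise when one cross
carries heterozygous introgression from a sister species (locally ~6%
diverged, hence several-fold denser markers).

## What it computes

- **Origin encoding** (`meiomap.genotype_io`) — joint VCF → fixed-difference
  marker map → per-tetrad 4×M parent-of-origin ("seg") matrices.
- **Event calling** (`meiomap.events`) — segmentation of the 4-spore origin
  patterns into COs and NCOs, with CO-associated conversions decomposed,
  breakpoints at inter-marker midpoints, and the standard
  ≥ 3-supporting-marker NCO filter.
- **Landscapes** (`meiomap.landscape`) — 20 kb windows with CO counts
  smoothed across marker-free window runs (totals conserved exactly) and NCO
  counts divided by a Monte-Carlo detection probability: a 550 bp reference
  tract is placed uniformly in each window 10,000 times and the fraction of
  placements covering ≥ 3 markers is the probability of seeing a conversion
  there at all.  Plus marker-downsampling experiments, Wilcoxon and Spearman
  comparisons, and gaussian GLMs of window counts on cross, introgression and
  GC content.
- **Sequence similarity** (`meiomap.similarity`) — per-site diploid
  similarity (1 invariant, 0.5 polymorphic, 0 fixed difference) in 101 bp
  sliding windows (50 bp step), NCO-depth tracks, Spearman/loess association,
  and Welch tests of CO-flank vs NCO-flank similarity.
- **Allele shuffling** (`meiomap.shuffling`) — per gamete and region the
  parent-A proportion *p* (origin changes placed at inter-marker midpoints)
  and r̄ = 2p(1−p), the probability that a random pair of loci in the region
  carries alleles from different parents; averaged over gametes and compared
  between crosses with Welch t-tests under Bonferroni correction.
- **Synthetic meiosis** (`meiomap.simulate`) — two parental haplotypes with
  background markers at 1.35/kb and introgression blocks at 3.225/kb,
  gamma-renewal crossovers (shape 1 = Poisson), geometric conversion tracts
  (mean 550 bp), a genotyping error/missingness observation model, and a
  ground-truth event table with geometry-derived observability annotations.

## Worked example

```python
from meiomap import study_config, simulate_cross
from meiomap.events import call_all
from meiomap.landscape import assemble_window_table
from meiomap.shuffling import chromosome_regions, shuffling_records, mean_rbar

config = study_config("fermentation", n_tetrads=8, seed=42)
cross = simulate_cross(config)
print(f"markers: {len(cross.parents.marker_map)}")

events = call_all(cross.tetrads, cross.parents.marker_map,
                  config.chrom_lengths, min_nco_markers=3)
counts = events.counts()
print(f"CO/meiosis: {counts['CO'].sum() / config.n_tetrads:.1f}")
print(f"NCO/meiosis (>=3 markers): {counts['NCO'].sum() / config.n_tetrads:.1f}")

windows = assemble_window_table(
    events, cross.parents.marker_map, config.chrom_lengths,
    introgressions=cross.parents.introgressions,
    cross="fermentation", n_reps=2000, seed=0,
)
intro = windows[windows["introgression"] == 1]
bg = windows[windows["introgression"] == 0]
print(f"mean CO per 20 kb window: introgressed {intro['co_smoothed'].mean():.2f}, "
      f"background {bg['co_smoothed'].mean():.2f}")

records = shuffling_records(cross.tetrads, cross.parents.marker_map,
                            chromosome_regions(config.chrom_lengths))
mean, se, n = mean_rbar(records, "chr04")
print(f"chr04 mean rbar: {mean:.3f} (SE {se:.3f}, n={n} gametes)")
```

Output:

```
markers: 18538
CO/meiosis: 44.2
NCO/meiosis (>=3 markers): 1.9
mean CO per 20 kb window: introgressed 0.56, background 0.58
chr04 mean rbar: 0.359 (SE 0.028, n=32 gametes)
```

`markers` is the fixed-difference count for the simulated fermentation-style
cross (nine introgressions at 3.225 markers/kb over a 1.35/kb background).
`CO/meiosis` counts *detected* origin transitions — fewer than the generative
crossover rate because two- and three-strand double crossovers are invisible
in origin-coded data (see `docs/methods.md`).  Detected NCOs outside
introgressions are rare at background marker density, which is exactly what
the detection-probability correction in the window table compensates.  The
chromosome-4 r̄ of ~0.36 means a random pair of chr04 loci is shuffled in
roughly a third of gametes.

A command-line interface mirrors the library (`meiomap simulate`,
`meiomap call-events`, `meiomap landscape`, `meiomap similarity`,
`meiomap shuffle`); run `meiomap --help`.

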