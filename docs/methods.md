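# Methods

## Data model and coordinates

All analysis runs on parent-of-origin codes at fixed-difference markers:
sites where the two parental strains are homozygous for different alleles.
VCF input is 1-based and converted to 0-based internally; BED-style
intervals and conversion tracts are 0-based half-open.  Each tetrad is a
4 × M matrix of codes in {A-origin, B-origin, missing}.  Heterozygous spore
calls — impossible for a true haploid — are coded missing and counted, and a
marker column with any missing spore is skipped as uninformative.  Markers
at which all four spores agree (4:0) cannot arise under 2:2 segregation
without error; they are flagged, counted, and treated as missing.

## Event calling

Within each tetrad and chromosome, informative marker columns are
partitioned by their segregation tally.  Balanced (2:2) columns define a
phase; the caller walks consecutive balanced markers:

- **Crossover.**  A phase change in which exactly two spores exchange origin
  is one CO.  Its point estimate is the floor-midpoint of the transition
  gap; its uncertainty interval spans the flanking *balanced* markers.  A
  four-spore phase change is emitted as two simultaneous COs (the chromatid
  pairing is not identifiable from origin data; spores gaining B-origin are
  paired with spores losing it, in index order).
- **Non-crossover.**  A maximal run of 3:1 columns deviating on a single
  spore is one conversion tract on that spore.  Its minimal extent runs from
  the first to the last converted marker; its maximal extent reaches the
  flanking unconverted markers.  Tract length for summary statistics is the
  midpoint-to-midpoint span of the uncertainty interval, consistent with the
  breakpoint convention — the measurement convention is otherwise
  under-determined, and the downsampling experiment shows its bias
  explicitly (sparser markers ⇒ longer apparent tracts).
- **CO-associated conversion.**  Unbalanced columns between two different
  phases are assigned to the nearer phase (ties to the left); each side's
  runs become NCOs and the CO is placed between the last left-assigned and
  first right-assigned marker.  Because the exchange point could lie
  anywhere across the conversion run, the CO's uncertainty interval keeps
  the balanced-marker flanks.
- **Terminal 3:1 runs** (bounded by a phase on one side and the chromosome
  end on the other) are called NCO against that phase: crossovers are
  reciprocal and can never produce a 3:1 tally, so a 3:1 run is a conversion
  wherever it sits.

NCOs supported by fewer than three converted markers are removed by the
support filter (configurable; default 3).

What calling cannot do: double COs between adjacent markers on the same
chromatid pair are unobservable and are not imputed, and a crossover between
two chromatids that locally share parental origin produces no phase change
at all.  The latter is the classical invisibility of two- and three-strand
double crossovers in origin-coded tetrad data: with a Poisson crossover
process at roughly five exchanges per chromosome, about 25–30% of generative
exchanges leave no origin transition.  Detected CO counts are therefore
systematically below the generative rate; this is a property of the data
type, not of the caller, and the simulator's truth annotations (below) make
it measurable.

## Landscapes and corrections

Windows are 20 kb, non-overlapping, half-open, with the terminal remainder
truncated and retained.  COs are assigned by point estimate, NCOs by
minimal-tract midpoint.

**CO smoothing.**  A crossover falling in a long marker desert is localised
only to the middle of the empty stretch, so within each maximal run of
consecutive marker-free windows the CO count is redistributed evenly.
Redistribution is quantised to a dyadic grid (units of 2⁻²⁰ ≈ 10⁻⁶ of a
count) so that every window value and every partial sum is exactly
representable in binary floating point: per-chromosome totals are conserved
bit-for-bit in any summation order.

**NCO detection probability.**  For each window, a tract of the reference
conversion length (550 bp, the mean tract length where markers are densest)
is placed uniformly at random 10,000 times with the tract constrained inside
the window; the fraction of placements covering at least `min_markers`
markers is the detection probability, and the observed count is divided by
it.  `min_markers` defaults to 3, matching the caller's support filter, and
is exposed because the appropriate criterion depends on the filter actually
applied.  Edge placements (tracts straddling window bounds) are excluded — a
convention choice; with 550 bp tracts in 20 kb windows it affects < 3% of
placement mass.  Windows whose probability is zero (no markers) get an
undefined corrected count and are excluded from downstream statistics with a
logged count.  Monte-Carlo error at 10,000 placements is below 0.005 in
probability; tests check the estimator against exhaustive enumeration.

**Statistics.**  Between-cross window correlations use Spearman's rho;
introgressed-vs-background comparisons use the Wilcoxon rank-sum test with
the tie-corrected normal approximation (`scipy.stats.mannwhitneyu`,
asymptotic).  Window-count models are gaussian identity-link GLMs
(equivalent to ordinary least squares) of count on cross, introgression
flag, GC fraction and the introgression×cross interaction; interactions
whose coefficients are all non-significant at α = 0.05 are dropped and the
model refit.  Rank-deficient designs raise an error naming the collinear
columns.

## Sequence similarity

Diploid sequence similarity scores each position 1 (invariant between the
strains), 0.5 (polymorphic in either or both), or 0 (fixed difference) — the
probability that one base sampled from each strain matches — and averages
over 101 bp windows stepped by 50 bp.  Site classes come from the joint
genotype table; positions absent from it are invariant, and sites with a
heterozygous or missing parent are scored polymorphic.  NCO depth is the
number of (uncorrected) minimal tracts intersecting each window under
half-open overlap.  Association per region uses Spearman's rho (reported
significant below 0.001) and a loess regression of depth on similarity.  The
loess is implemented here — degree-2 local polynomials, tricube weights over
the nearest `ceil(span·n)` points (span 0.75 default), pointwise SE from the
equivalent-kernel row norm with a global residual variance — because no
installed package provides R-style local quadratic regression with an SE
band.  Flank comparisons average per-site similarity over the 100 bp up- and
downstream of CO breakpoints (centred on the midpoint estimate) and of NCO
maximal tracts, clipped at region bounds, and contrast CO vs NCO events per
region with Welch's t-test; regions with fewer than two events in either
class are skipped with a reason.

## Allele shuffling (r̄)

For each gamete and region, loci between same-origin markers are assumed to
share that origin; a change of origin between successive markers is placed
at their floor-midpoint; spans from the region edge to the first/last
informative marker take the nearest marker's origin (the maximal-parsimony
extension of the between-marker assumption; base-pair weighting throughout).
The parent-A proportion *p* then gives the intra-region shuffling statistic
r̄ = 2p(1−p) ∈ [0, 0.5], symmetric in the parents; A-span plus B-span equals
the region length exactly.  Only intra-region structure enters: the
independent-assortment component of genome-wide shuffling is out of scope.
Cross comparisons are Welch t-tests on per-gamete r̄, Bonferroni-corrected
within each family of regions (α/16 = 0.00313 for the 16 chromosomes,
α/9 = 0.00556 for the nine introgressed regions at family α = 0.05);
thresholds are also reported at 3 significant figures.

## The simulator

The generator emulates the study design, not just abstract meiosis:

- **Genome**: 16 chromosomes totalling ~12.07 Mb with a budding-yeast-like
  length profile (the real karyotype's lengths are not part of the inputs,
  so a representative profile is used).
- **Markers**: homogeneous Poisson placement at 1.35/kb background; the
  fermentation-style cross carries nine heterozygous introgressions (the
  printed study intervals on chromosomes 4, 6, 7, 9, 10, 10, 13, 14, 15) at
  3.225/kb.  Parents are homozygous and differ at every marker; parental
  heterozygous sites (for the similarity module) are placed at 0.5/kb.
- **Crossovers**: a stationary gamma-renewal process on the rate-weighted
  axis; shape 1 (the default, since interference is not quantified in the
  emulated design) is exactly Poisson.  Generative rates default to 82.5
  (natural) and 63.7 (fermentation) exchanges per meiosis apportioned by
  chromosome length, with a within-introgression rate multiplier (default
  0.4 in the fermentation design) that reshapes placement without changing
  chromosome totals — heteroduplex rejection suppresses crossovers locally.
  Each CO exchanges the suffixes of one chromatid per homolog, chosen
  uniformly among the four pairings.
- **Conversions**: Poisson initiations (30 per meiosis by length, within the
  range reported for budding yeast; the emulated design does not print its
  count), geometric tract lengths with mean 550 bp (gamma selectable — only
  the mean is constrained by the design), recipient chromatid uniform,
  origin flipped over the tract (guaranteeing 3:1 at converted markers), and
  a 2× introgression multiplier in the fermentation design.
- **Observation model**: independent per-cell origin flips (error) and
  masking (missingness), both default 0 — the pipeline's entry point is a
  cleaned joint-genotype call set.

Every truth event carries observability annotations computed from truth plus
marker geometry only, independent of the caller: whether a CO changed origin
at all (visible), has markers on both sides, and is the sole visible
transition in its inter-marker gap; and for NCOs the converted-marker count
and whether the tract's marker span is free of interference from other
events of the same tetrad.  Recovery tests assert 100% recovery of these
clean events and zero false positives, and merely count the rest — an
event that leaves no trace in origin-coded data cannot be recovered by any
caller.

What the simulator does not emulate: chromatid interference, a shared
fine-scale rate landscape between crosses (no GC- or hotspot-coupled rate
variation, so between-cross window correlations are near zero by design),
mitotic recombination, aneuploidy, structural variation, and read-level
artefacts.  Passing tests therefore validate the machinery — encoding,
calling, correction, statistics — under a faithful observation model; they
do not certify biological conclusions about any particular dataset.

## Numerical and design choices

- Same seed ⇒ byte-identical outputs; all randomness flows through
  `numpy.random.Generator`.
- Renewal stationarity is approximated with a 10-mean-gap burn-in for
  non-Poisson shapes; shape 1 bypasses it exactly.
- Detected conversion statistics are length-biased (a ≥ 3-marker tract is
  systematically longer than average at low marker density); the
  downsampling experiment measures this directly, and detected mean tract
  lengths exceed the generative 550 bp mean accordingly.
- The genome-average map density summary is 100 × (mean COs per meiosis) /
  (genome length in kb).
- Acceptance-scale runs use 48 tetrads on the ~12 Mb genome; heavier
  Monte-Carlo settings (10,000 placements) are kept because they are cheap
  once vectorised.

## Known limitations

- The caller's decomposition of complex multi-event patterns (overlapping
  conversions, conversions containing a crossover) follows deterministic
  conventions; genuinely ambiguous configurations — where distinct event
  histories produce identical origin data — are resolved by convention, not
  inference.
- Detection-probability correction assumes a single genome-wide reference
  tract length; when true tract lengths vary, the correction is exact only
  on average at the reference length.
- Terminal windows shorter than 20 kb are retained and flagged; count-based
  comparisons treat them like full windows, with window length available
  for sensitivity checks.
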