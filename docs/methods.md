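# Methods

## Scope and data model

`runscan` operates on diploid autosomal SNP-array genotypes held as an
individuals × SNPs dosage matrix (0/1/2 counts of the B allele, −1 for
missing) with a genetic map of 1-based base-pair positions, strictly
increasing within each chromosome. PLINK-text PED/MAP is the interchange
format; the B allele at each SNP is the lexicographically later of the two
observed alleles. This orientation is arbitrary, and deliberately so: every
statistic computed downstream (homozygous/heterozygous state, run
detection, locus run frequencies, r²) is invariant to allele relabeling, so
no reference-allele bookkeeping is needed. Monomorphic SNPs code as dosage
0 everywhere.

Two QC stages exist and are intentionally separate. Panel-wide QC before
run detection removes, in order: non-autosomal markers, markers with
missing call rate > 0.05, and individuals with missing call rate > 0.05
computed on the surviving marker set (all comparisons strict). No MAF or LD
pruning is applied before run detection — fixed alleles carry exactly the
homozygosity signal the detector needs, and LD pruning perturbs detection
in a population-dependent way. A second, per-population filter (MAF < 0.05
or missingness > 0.1, strict) is applied only before LD estimation, where
rare alleles genuinely bias r².

The ordering choice that individual call rates use the post-marker-filter
SNP set is a documented convention; the alternative (pre-filter rates) is a
one-line change but alters no invariant.

## The sliding-window detector

Both run types share one algorithm; only the definition of an *opposite*
genotype differs (heterozygous opposes a ROH, homozygous opposes an HRR),
making the two modes exactly symmetric: mapping hom↔het in the dosage
matrix and swapping the mode yields coordinate-identical calls, a property
the test suite asserts.

1. **Window eligibility.** Every window of `window_snps` consecutive SNPs
   (windows start at each SNP index that fits; a chromosome shorter than
   the window is scanned as one truncated window rather than skipped) is
   eligible iff it contains ≤ `max_opposite_in_window` opposite and
   ≤ `max_missing_in_window` missing genotypes.
2. **SNP membership.** Each SNP's score is the proportion of eligible
   windows among the windows covering it — edge SNPs are covered by fewer
   windows and are scored against their own coverage. A SNP is flagged
   when its score strictly exceeds `window_threshold` (default 0.05). The
   strict comparison is isolated in one predicate; at the default
   threshold it means "more than one eligible window out of twenty".
3. **Assembly.** Maximal stretches of flagged SNPs are split wherever
   adjacent members lie more than `max_gap_bp` apart; each gap-split
   candidate is judged independently against the SNP-count, length
   (`end_bp − start_bp`, not +1, matching the last-minus-first convention
   used for chromosome spans), density (`length/n_snps ≤ d·1000` with
   boundary equality passing) and run-level opposite/missing limits.

Run-level opposite/missing limits are enforced *in addition to* the
window-level limits, since both scopes are part of the parameter set. This
has a consequence worth knowing: a clean homozygous segment whose flanking
SNPs are heterozygous can have those flank SNPs flagged (the window
starting exactly at the flank holds only that one heterozygote and is
eligible), and a candidate that absorbs one flagged heterozygous flank on
each side then holds two heterozygotes and is rejected under the
one-heterozygote ROH allowance. On heterozygous backgrounds this makes the
default ROH parameter set conservative (the worked example in the README
shows the effect); two adjacent heterozygous SNPs at a boundary suppress
it completely, because every boundary-straddling window then holds two
opposite genotypes and becomes ineligible. The synthetic recovery
benchmarks pin boundaries exactly this way.

The vectorized implementation (cumulative-sum rolling counts) is verified
against a naive reference that re-enumerates every window and candidate —
exact list equality over thousands of randomized chromosome × parameter
combinations, which also fixes the semantics of edge coverage and
truncated windows wherever prose is ambiguous.

### Parameter defaults

ROH: window 20 SNPs, min 20 SNPs and 1000 kb per run, density 1 SNP/70 kb,
max gap 250 kb, ≤ 1 heterozygous and ≤ 1 missing per window and per run,
threshold 0.05 — the standard configuration for ~50k-marker panels, where
1000 kb corresponds to roughly 20 SNPs. Min-SNP and min-length constraints
are enforced independently even though they are nearly redundant at this
density. HRR scenarios 1–9 vary minimum length (400/250/10 kb), the
homozygous allowance (3/2/1 per run and window), the missing allowance
(2/1) and the window size (10/5), with max gap 1000 kb and density 70
kb/SNP throughout; scenario 2 is the conventional choice for island
calling.

## Aggregation

Length classes are lower-inclusive half-open bins over 1–2, 2–4, 4–8,
8–16, > 16 Mb (runs below 1 Mb, possible under permissive HRR parameters,
are labeled "<1"); half-open binning guarantees per-class counts and
lengths sum exactly to the grand totals. Population means divide by N, the
number of genotyped individuals, so zero-run individuals count in the
denominator — the same N as in the coverage formula (L_RUNCHR/N)/L_CHR.
Chromosomes with fewer than two markers have undefined span and are
omitted from coverage and from the F_ROH denominator, which is the summed
last-minus-first marker span over autosomes of the post-QC map.

## Islands and common regions

The locus run frequency of a SNP in a population is the fraction of
individuals whose detected runs contain it, with closed-interval
containment (run endpoints are member SNPs). The island threshold is the
0.999 quantile of that per-population distribution, computed as the
smallest value in the top 0.1% tail of the sorted frequencies (1-based
rank ⌊q·n⌋+1). This "top tail" rank convention — rather than the
⌈q·n⌉ nearest-rank estimator — is what makes "the top 0.999 SNPs"
literal: with 1000 SNPs it selects exactly the best one (plus ties),
whereas ⌈q·n⌉ would select everything whenever q·n lands on an integer.
Selection is ≥ threshold, so ties at the cut are all included; an
all-equal distribution selects every SNP and logs a warning. Both the
estimator (rank vs interpolated) and the tie rule (≥ vs >) are exposed on
`IslandParams`.

Selected SNPs are grouped per chromosome, starting a new island whenever
the distance to the previous selected SNP exceeds 250 kb (held equal to
the ROH max-gap for both modes); island coordinates are min/max member
positions, so single-SNP islands are legal. HRR islands with ≤ 4 member
SNPs are removed — small islands are artifacts of the permissive HRR
parameters — while ROH islands carry no size filter.

Common regions are computed by a breakpoint sweep on the closed-interval
line: elementary pieces are every island endpoint and every open interval
between consecutive endpoints; pieces get covering-population sets, equal
adjacent sets merge, and merged pieces with ≥ 2 populations are emitted.
Working with point and interval pieces (rather than midpoints alone)
resolves single-base-pair contacts exactly, which matters because island
endpoints are SNP coordinates shared across populations. The sweep is
validated against a half-step coverage scan on randomized fixtures.

## Linkage disequilibrium

r² is estimated per population from two-locus haplotype frequencies
reconstructed by EM over unphased genotype counts. All genotype pairs
except the double heterozygote resolve to known haplotypes; the EM iterates
the expected coupling fraction among double heterozygotes from a
linkage-equilibrium start, to relative tolerance 1e-10 or 1000 iterations,
then r² = D²/(pA·pa·pB·pb). Pairs with a monomorphic locus (among
pairwise-complete observations) are undefined and skipped, not reported as
zero. On tables without double heterozygotes the EM reduces to direct
haplotype counting exactly, and on general tables it agrees with a
two-stage grid search (10⁻⁴ sweep over the coupling fraction, 10⁻⁶
refinement) maximizing the genotype likelihood — an independent oracle
used in the tests. A squared dosage-correlation estimator
(`composite_r2`) is kept as a cross-check; both handle missing data
pairwise-complete.

Pair evaluation is windowed (default 1000 kb distance cap, optional SNP
count cap) and reported above r² > 0.2, both configurable. The
island-overlay filter keeps pairs with distance ≥ a minimum and r² above a
threshold and intersects the pair interval [pos_a, pos_b] with island
intervals (closed coordinates); typical overlay settings are 250–1000 kb
with r² thresholds between 0.3 and 0.9.

## Annotation overlap

Internal coordinates are 1-based closed throughout (island endpoints are
SNP positions); BED input/output converts at the boundary (0-based
half-open). Intersection is closed-interval and single-base-pair contact
counts as an overlap — island endpoints are exact SNP coordinates, and no
minimum-overlap rule is imposed. A category filter (e.g. QTL classes) is
applied before intersection, and a configurable proximity window allows
"near" queries; it has no default distance, since proximity has no
canonical definition.

## Synthetic data: what it does and does not emulate

The generator produces multi-population panels shaped like medium-density
array data: configurable chromosome count and SNP spacing (uniform with
±jitter around a mean, default 50 kb — the scale of a ~50k ovine panel),
per-SNP allele frequencies from a uniform MAF band, Hardy–Weinberg
genotypes independent across SNPs, and uniform missingness. On top of
this, ground-truth homozygous or heterozygous segments can be planted
(the homozygous allele is drawn per SNP from its frequency, so planting
does not distort the site-frequency spectrum; overlapping segments of
conflicting kind are rejected) and haplotype-pool LD blocks can be
simulated (two random haplotypes per individual drawn from a small shared
pool per block — within-block pairs are tightly coupled, two-haplotype
pools give r² = 1 at polymorphic sites, cross-block pairs are
independent).

What it deliberately does not model: background LD outside the explicit
block generator, recombination maps, mutation, selection, pedigree or
coalescent structure, array-specific genotyping error modes, and
ascertainment bias of array SNP selection. Consequently, passing the
recovery and gradient benchmarks demonstrates algorithmic correctness
(the detector finds what is there, with exact boundaries under pinned
flanks, and nothing on clean backgrounds) — not that any particular
parameter set is optimal on real array data, where background LD inflates
chance homozygous stretches and real run-length distributions are heavier
tailed.

Reproducibility: every generator derives independent substreams from one
integer seed via `numpy` `SeedSequence`; identical configuration and seed
give identical panels byte-for-byte.

## Validation-study design choices

- **Detector equivalence** runs the vectorized detector against the naive
  reference on 200 random chromosomes (≤ 300 SNPs, mixed heterozygosity
  and missingness) × 20 random valid parameter sets, exact equality.
- **Recovery benchmark**: 50 individuals, one 50 Mb chromosome at 25 kb
  spacing, two planted ROH per individual (61–79 SNPs, ≥ 1.5 Mb) with
  heterozygous 2-SNP flank pairs; expected outcome is 1:1 recovery with
  boundaries within one inter-SNP interval and zero calls on a pure
  Hardy–Weinberg background with MAF ≥ 0.3.
- **Scenario-sweep panel**: the qualitative response of HRR counts to the
  detection parameters is measured on a panel of discrete heterozygous
  blocks — one per mini-chromosome (14 SNPs, ~310–470 kb spans under 20%
  spacing jitter), interrupted by 0–3 homozygous SNPs. Block spans
  straddle the 400/250 kb length cuts, interruption counts straddle the
  3/2/1 homozygous allowances, and the absence of flanking background
  keeps boundary absorption from confounding the comparison. On
  threshold-level backgrounds (het fraction near the window limit),
  tightening the homozygous allowance *fragments* marginal runs and can
  raise counts — a real property of the algorithm, not of segment-bearing
  genomes, and the reason the benchmark uses discrete blocks.
- **Inbreeding gradient**: five populations (40 individuals each, two
  45 Mb chromosomes) on a heterozygosity-rich background (MAF 0.45–0.5)
  with 0/10/18/26/34 planted ~1.77 Mb ROH per individual. Planted
  homozygosity consumes heterozygous genome, so mean total ROH length
  rises and mean HRR count falls monotonically across the burden gradient
  — the negative ROH/HRR association, reproduced mechanistically.
- Problem sizes throughout (panels of tens of individuals × a few
  thousand SNPs) are chosen so the full battery runs in well under a
  minute while leaving every comparison statistically unambiguous
  (monotonicity margins of several standard errors).

## Numerical and degenerate-input conventions

- Dosages are int8; all counting is exact integer arithmetic. The only
  floating-point comparisons are the membership threshold (strict >) and
  the density bound (≤, boundary passes).
- Empty chromosomes are skipped with a log entry; a QC stage that removes
  every SNP returns an empty panel and a warning, not an error.
- QC report arithmetic (n_out = n_in − removed) is enforced by
  construction and cannot drift.
- EM r² caps at 1.0 against floating-point overshoot; undefined pairs
  return `None` rather than 0 so downstream thresholds cannot confuse
  "no LD" with "not estimable".
- Tidy exports write `%.10g` floats with fixed column order and a
  `schema_version` column; identical inputs and configuration reproduce
  byte-identical files.

## Known limitations

- The detector implements the sliding-window method only; the alternative
  "consecutive runs" method is out of scope.
- Islands carry no statistical significance test; the quantile threshold
  is descriptive.
- LD is reported as raw pairwise r² records (the point of the overlay
  design); D′ and distance-binned decay summaries are not provided.
- GO/KEGG enrichment and live database annotation are out of scope; the
  annotation module consumes user-supplied interval files.
- `pairwise_ld` evaluates pairs in Python loops; for full-chromosome
  all-pairs scans at array scale, restrict the distance window (default
  1000 kb) or pre-filter SNPs.
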