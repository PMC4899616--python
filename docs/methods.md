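# Methods

## Scope

`methdmr` implements a whole-genome bisulfite differential-methylation
analysis for a two-genotype plant design (one pooled methylome per
genotype, no biological-replicate modelling): context-aware cytosine
classification, a 50-bp-bin Fisher-exact hyper-DMR caller with bin
merging, interval-set overlap and enrichment statistics, genomic
composition and gene-body metaprofiles, and clone-based amplicon
summaries.  A synthetic methylome generator with planted ground truth
closes the loop so every stage can be validated end to end.

## Cytosine contexts

A cytosine's context is the two bases 3′ of it on its own strand: CG,
CHG or CHH with H ∈ {A, C, T}.  Coordinates are 1-based at the cytosine
(cytosine-report convention); a minus-strand call at position *p* refers
to the G at *p* on the plus strand, and its downstream window is read in
reverse complement.  Every interval elsewhere in the package is 0-based
half-open; the conversion is owned entirely by the I/O layer.  Edge
rules the data format does not define are made explicit: CG needs one
downstream base, CHG/CHH need two, and an N anywhere in the needed
window (or running off the sequence) makes the call `ambiguous`.
Ambiguous sites are excluded from all downstream statistics so that
undefined contexts cannot contaminate bins.  Symmetric CG sites are
*not* collapsed across strands; both strands carry their own counts and
region pooling naturally sums them.

## Methylation levels

A site's methylation is `n_meth / n_total`; a site enters any statistic
only with coverage ≥ `min_cov` (default 3, exposed as a parameter).
Region and bin levels pool read counts (Σmeth / Σtotal) over passing
sites per context rather than averaging site levels; count pooling
matches the count basis of the per-bin exact test and keeps additivity
over region splits.  A site-averaged mode is provided for comparison
since published region percentages do not always state which convention
they use.  A context with no passing reads has an undefined (NaN)
level, never zero.

## DMR calling

Chromosomes are tiled from coordinate 0 into 50-bp bins (terminal bin
truncated).  Per bin, passing counts of both genotypes form the 2×2
table [[meth_wt, unmeth_wt], [meth_mut, unmeth_mut]] and receive a
two-sided Fisher exact p-value.  A bin with zero pooled passing reads in
either genotype is untestable (not treated as level 0).  A bin is
significant when p ≤ α (default 0.01), the pooled level difference
mutant − wild type is ≥ `min_delta` (default 0.1), and the direction
matches (`hyper` by default, since demethylation mutants gain
methylation).  Neither α nor `min_delta` has a canonical published
value for this bin-based design; the defaults are conventional for
plant bin-based DMR calling and both are exposed.  No multiple-testing
correction is applied by default; a Benjamini–Hochberg mode exists but
is off, matching the uncorrected per-bin design.  Contexts are pooled
within a bin for testing (one test per bin), with an optional
single-context mode.

Significant bins are merged left to right whenever the gap to the next
one (half-open: `next.start − current.end`) is ≤ 50 bp — with 50-bp
bins this admits at most one intervening non-significant bin.  Merging
is idempotent and independent of input order.  The DMR span is the
union of member bins; each DMR carries its bin count, minimum and
median p, and per-context pooled levels in both samples.

### Exact-test implementation

The two-sided p is the classical "sum of tables no more probable than
observed" tail.  For table totals ≤ 500 it is evaluated in exact
integer arithmetic: the hypergeometric pmf numerators over the common
denominator C(N, r₁) are built by an integer recurrence, compared as
integers (so probability ties are exact, with no floating-point
ambiguity), and divided once at the end.  Larger tables switch to a
vectorised floating pmf with a 10⁻⁹ relative tie tolerance, where tie
handling is numerically irrelevant.  The unit suite cross-checks both
paths against `scipy.stats.fisher_exact` and against brute-force
rational enumeration.

## Overlap and enrichment

Two DMR sets are compared with a pairwise rule: an interval of A
overlaps B when its intersection with some *single* interval of B is
≥ 50 bp.  Whether fragmented (summed) intersections should count is
ambiguous in the field's usage; the single-interval reading is the
default and a summed mode sits behind a flag.  The chance expectation
for the overlap count is (A·B)/N and enrichment is the hypergeometric
upper tail P[X ≥ k], X ~ Hypergeom(N, B, A), including the observed
value.  N — the bin population, e.g. the number of 50-bp bins in the
analysed genome or the number of testable bins — is always an explicit
argument and never inferred, because published expected counts are not
reconstructible from any single naive N.  Reported percentages follow
the convention of one decimal, or two decimals below 1% where one
decimal would destroy the value.

## Composition and metaprofiles

Each DMR is assigned exactly one of genic / TE / intergenic by priority
(genic > TE > intergenic) with a ≥ 1 bp overlap criterion; the priority
is configurable because the assignment rule for a DMR touching both a
gene and a TE is a genuine free choice.  "Genic" means the annotated
gene span (GFF3 `gene` features, UTRs and introns included).

Metaprofiles average per-context methylation over genes scaled to 20
body bins plus 1-kb flanks in 10 fixed-width bins per side (both
configurable; the exact published bin counts for such plots are rarely
stated).  Minus-strand genes are flipped so upstream/TSS is always
left.  A site's counts are split across body bins by fractional overlap
of its 1-bp footprint, so genes shorter than the bin count still
contribute with correct weight.  Bin values are pooled counts across
genes, mirroring region-level semantics.

## Clone-based amplicon analysis

Only top-strand amplicons are modelled (bisulfite PCR is strand
specific); bottom-strand loci are handled by reverse-complementing the
reference first.  At each reference cytosine a clone base C is a
methylated call, T unmethylated, anything else missing.  Per-context
levels are methylated/(methylated+unmethylated) with explicit
denominators, since clone counts per locus vary between experiments.
The per-clone CHH methylation fraction acts as an advisory
bisulfite-conversion proxy (threshold 0.9); no clone is dropped and
duplicates are only reported, not removed.

## Synthetic methylome generator

The generator emulates the study conditions rather than any particular
deposited dataset.  Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| GC content | 0.36 | Arabidopsis-like |
| TE / gene fraction | 0.15 / 0.45 | Arabidopsis-like genome composition |
| profile: TE CG/CHG/CHH | 0.80/0.60/0.15 | heterochromatic TE methylation |
| profile: gene | 0.05/0.01/0.01 | low-methylation genic background |
| profile: intergenic | 0.08/0.03/0.03 | mildly methylated filler |
| mean depth λ | 20 | Poisson per-site depth; fixed-depth mode for exact-test oracles |
| planted Δm CG/CHG/CHH | 0.5/0.5/0.3 | strong hyper-DMR effect, CHH weaker as in RdDM-driven gains |
| planted width | 200–1000 bp | typical hyper-DMR scale |
| planted density | 30 per Mb | between sparse and dense demethylation-mutant loads |

Planted regions avoid TEs by default and keep ≥ 300 bp separation:
demethylase-target hyper-DMRs concentrate in euchromatic, genic
territory, and the separation keeps distinct truth regions distinct
after gap-merging.  The mutant differs from the wild type only inside
planted regions (Δm added, clipped at 1); hypo mode exists but is off.
Depths are drawn per sample (optionally paired), counts are binomial.
One generator stream seeds everything in a documented draw order
(sequence, blocks, placement, wt depths, wt counts, mut depths, mut
counts); byte-identical reruns are promised within this implementation
only.

Two arrangements exist: `random` (random block lengths 500–3000 bp,
classes chosen greedily toward the target fractions) and `cassette`
(repeating intergenic–TE–gene–TE units) for analyses that need genes
deterministically flanked by TEs, e.g. flank-elevated metaprofile
checks.

What the generator does *not* emulate: read-level errors, incomplete
bisulfite conversion, mapping bias, copy-number variation, correlated
methylation between neighbouring sites, or replicate variability.
Passing the planted-recovery suite therefore demonstrates correctness
of the statistical machinery under the stated noise model, not
performance on real libraries.

## Validation problem sizes

The acceptance suite runs the caller on three 2-Mb genomes at λ = 20
(recovery ≥ 90% of planted regions at ≥ 50 bp overlap, ≤ 5% of called
bases off target), a 500-kb fixed-depth null for calibration, an
exhaustive Fisher oracle over all 2×2 tables with total ≤ 60 (agreement
< 10⁻¹² against exact rational enumeration), a hypergeometric oracle
over all populations ≤ 40, a 50-clone round trip, and cassette-genome
metaprofiles; these sizes give stable statistics at desk-scale runtime.
The numbered scripts under `analysis/` use a 400-kb demo genome for the
same reason.

## Known limitations

- One methylome per genotype: no replicate-aware inference, matching
  the pooled-comparison design the caller reproduces.
- The caller's α and min_delta defaults are conventions, not published
  values; absolute DMR counts are threshold-sensitive even though
  planted-truth recovery is robust.
- Bins partially covered by a true region are called on attenuated
  pooled deltas, so called DMR edges can overshoot truth boundaries by
  up to one bin per side; this is inherent to fixed binning.
- The GFF3 reader extracts only the feature types asked of it; it is
  not a general GFF3 validator.
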