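# Methods

## The genetic model

`bsamap` models the textbook single-locus dominant-trait setting.  Two
fully inbred parental lines (G, green peel; Y, yellow peel) are fixed
for opposite alleles at every informative marker and at one causal
locus.  Phenotype is fully penetrant dominance: a plant is yellow iff it
carries at least one Y-origin allele at the locus; an optional
misphenotyping rate flips labels at random.  The expected phenotype
ratios are therefore 3:1 (yellow:green) in an F2 and 1:1 in a backcross
of the F1 to the green parent (BC1).

Meiosis follows Haldane's no-interference model: the number of
crossovers per chromosome per gamete is Poisson with mean
`length_cM / 100`, crossover positions are uniform in genetic distance,
and genetic position maps linearly to physical position along each
chromosome.  No crossover interference, no sex differences, no mutation.

## Pooled sequencing

Bulks are disjoint random samples of plants of one phenotype (default 33
per bulk, matching the emulated study design).  The bulk's true
green-parent allele frequency at a marker is the exact mean over its
2 × 33 member haplotypes.  Sequencing is modelled per site and sample as

* total depth ~ Poisson(mean_depth), default 30× (the emulated study
  reports parent/bulk coverages of roughly 23–34×);
* green-allele read count ~ Binomial(depth, f·(1−e) + (1−f)·e), with
  symmetric base-error rate e = 0.005 by default.

The simulated reference genome carries the yellow-parent allele at every
informative site, so the ALT allele is the green-parent allele and the
green bulk's SNP-index is high in the linked region.  This is a
bookkeeping convention (it reproduces the orientation of the emulated
study's figures), not a claim about any real reference assembly.
Coordinates are 1-based inclusive (VCF) everywhere; only the BED export
converts to 0-based half-open.

## Index tracks and region calling

Per-site SNP-index = alt reads / total reads per bulk; sites with zero
depth in either bulk are dropped, never imputed.  Window means use
half-open membership [start, start + window) with defaults 1 Mb window,
100 kb step, ≥ 10 sites (the emulated study plots windowed means but
does not state its geometry; these are configurable).  A window
qualifies when mean green-bulk index > 0.875 AND mean Δ > 0.5 — strict
inequalities, since the thresholds are quoted as "> 0.875" and
"> 0.5" — and a candidate region is a maximal run of at least 3
consecutive qualifying windows.  Any non-qualifying window (including
windows with too few sites) breaks a run.

## Segregation tests

Pearson's χ² on the two phenotype classes with expectations from the
hypothesized ratio, df = 1, no Yates correction; P is the χ²(1) upper
tail (for df = 1, equal to 2·(1 − Φ(√x))).  "Fits" means P > 0.05,
equivalently χ² < 3.84.

## Fine mapping from recombinants

Individuals are genotyped at ordered co-dominant markers
(A = homozygous green-parent, B = homozygous yellow-parent,
H = heterozygous, `-` = missing).  Phenotype constrains the genotype at
the causal position: green ⇒ {A}; yellow F2 ⇒ {H, B}; yellow BC1 ⇒ {H}.

An individual's genotype is known at its scored markers and is taken as
constant across runs of concordant markers.  Between two *discordant*
adjacent markers, the crossover point is unobserved, so every position
there is treated as possibly compatible whenever either flanking call is
allowed.  We deliberately do not place a point breakpoint (e.g. at the
midpoint) between discordant markers: with many recombinants, two plants
recombining on opposite sides of the locus within the same marker
interval would then both be assigned the same breakpoint and error-free
data would look self-contradictory.  The uncertainty treatment keeps
every error-free table consistent and reproduces the field convention of
reporting intervals by their flanking markers.

The mapped interval is the intersection of possibly-compatible positions
across individuals.  An isolated excluded single position (the point
evidence of a double recombinant at one marker) does not split the
reported interval.  The reported coordinates are those of the innermost
flanking markers; the locus lies strictly between them.  Missing calls
are uninformative.  Non-recombinant individuals contribute no constraint
under this model, so the pipeline genotypes all plants but narrows on
the recombinants only.

An empty intersection means some individual's phenotype contradicts the
rest — a misphenotyped plant, or a tight double recombinant created by
the no-interference crossover model (real meiosis shows strong positive
interference, so such plants are rarer in practice; under Haldane they
occur at roughly 2 × 10⁻⁴ per plant for ~2 cM marker spacing).  This
surfaces as an error by default; `drop_most_conflicting=True` instead
drops the individual whose removal yields the widest consistent
intersection (up to `max_drops`, logged), which is how a bench scientist
treats a single conflicting plant before re-genotyping it.

Marker development helpers: co-dominant InDel selection keeps
parent-informative InDels inside a region whose allele-length difference
is ≥ 3 bp (resolvable on a PAGE gel); marker–phenotype concordance
predicts yellow iff the call is H or B and reports the concordant
fraction with missing calls excluded and counted.

## Pigments and colour

Chlorophyll a/b and carotenoid concentrations follow the standard
three-wavelength linear equations for 96% ethanol extracts (see README);
they are reported per litre of extract, with an optional ×0.015 L/g
factor for 1 g tissue in 15 mL.  Because the equations are linear,
averaging replicate absorbances equals averaging computed contents.
CCI = 1000·a\*/(L\*·b\*) is NaN when the denominator is zero.

## Synthetic-study design point and problem sizes

The default configuration emulates the study design the package was
built around: F2 of 623 plants, BC1 of 71, 33-plant bulks, 30× depth,
0.5% base error, one informative SNP per 10 kb.  The miniature genome
uses 5 Mb chromosomes at 25 cM each (5 cM/Mb — a representative plant
rate; genome-wide averages for small cucurbit genomes run higher, while
mapped locus regions often recombine less) with the causal locus
mid-chromosome and one unlinked control chromosome; the genome-wide null
checks use a 20-chromosome genome matching the species karyotype
(2n = 40).  These sizes keep a full run under a second while preserving
the statistical structure of the real design.

## Statistical behaviour worth knowing

* **Causal-window signal.**  At the design point the windowed green-bulk
  index is ≈ 0.98 and windowed Δ ≈ 0.64 at the causal window, clearing
  the 0.875 / 0.5 thresholds with wide margins; candidate regions
  contain the causal position in ~100% of replicates.
* **Bulk-composition noise.**  A 33-plant bulk's allele frequency is
  strongly correlated along a chromosome (many gametes carry zero or one
  crossover), so the mean SNP-index of a *single* unlinked chromosome
  fluctuates with sd ≈ 0.04 around 0.5 even at high depth.  The null
  "index ≈ 0.5, Δ ≈ 0" statements are genome-wide statements; the
  package's null summaries therefore average over many chromosomes or
  replicate simulations, and single-chromosome deviations of ±0.1 in
  mean Δ are expected behaviour, not bugs.
* **Determinism.**  One integer seed drives every stage through
  independently spawned substreams; identical seed + config yields
  byte-identical VCF, tracks and report.

## What the simulator does not model

Real read alignment and variant calling (the pipeline starts at a VCF
with allele depths), sequencing-depth heterogeneity beyond Poisson,
mapping bias between alleles, structural variation, crossover
interference, segregation distortion, and any biology of the candidate
genes inside a mapped interval.  Passing tests therefore demonstrate the
statistical machinery on idealized data, not performance on a specific
real dataset.
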