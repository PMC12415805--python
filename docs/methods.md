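# Methods

This note documents the models and procedures implemented in `radsexlink`,
the parameter choices that matter, and what the simulation-based tests do
and do not establish.

## The synthetic-data generator

The simulator (`radsexlink.simdata`) emulates a ddRAD study of a species
with homomorphic XY sex chromosomes and a very large, repeat-rich genome:
a known-sex adult cohort for association screening and one outbred full-sib
family for linkage mapping.

**Genome.** Twelve chromosomes with graded sizes (largest ≈ 1.9× the
smallest), female genetic lengths summing to 1688 cM and male lengths to
1300 cM — the female/male map-length asymmetry typical of such systems. One
chromosome (the fifth) is the sex chromosome and carries the
**sex-determining region (sdr)** at one telomeric end of its male map, 2 cM
wide by default. The sdr width is a free parameter: real homomorphic systems
give no direct estimate, only the expectation that it is tiny relative to
gigantic chromosomes.

**Meiosis.** Each gamete receives, per chromosome, a crossover count drawn
as a zero-truncated Poisson — the obligate-chiasma assumption, which
prevents whole-chromosome co-segregation from swamping the sdr signal. The
truncated mean exceeds the raw rate, so the rate is calibrated by solving
`λ/(1−e^(−λ)) = L/100`; without this, every realised map distance would be
inflated and simulated recombinant fractions would not match the Haldane
expectation `r = (1−e^(−2d/100))/2` anywhere. Chromosomes shorter than
100 cM cannot have a truncated mean below 1 and receive exactly one
crossover (the obligate floor). Female crossovers are uniform on the female
map; male crossovers follow a symmetric U-shaped mixture of Beta(1, 8)
densities at the chromosome ends — the telomere-biased male recombination
widely observed in vertebrates — and are resampled out of the sdr, where
X–Y recombination is suppressed. Consequences worth noting: recombinant
fractions match Haldane only for intervals far from the obligate-chiasma
floor (the test uses loci 100 cM apart on a 500 cM chromosome), and the
male "positions" of loci are nominal physical-proportional coordinates, so
true male genetic distance is expanded near telomeres and compressed in
chromosome centres — which is precisely what creates the co-segregating
paternal marker clusters that the density scan must contend with.

**Loci and depth.** 1,200 RAD loci by default, placed with chromosome choice
proportional to genetic length; 32 of them are Y-restricted and lie inside
the sdr (both counts configurable; acceptance setups use up to 200 Y loci).
A quarter of the Y loci found a paralog family: one autosomal copy whose
300 bp sequence diverges by 5% per base. Read depth is negative binomial
with mean 28 and dispersion 12 (CV ≈ 0.36 — moderate RADseq overdispersion;
much wider dispersion would make a mean-28 locus routinely fail a median-20
screen, which is not what depth-filtered RAD catalogues look like), with 2%
per-cell dropout applied before the draw. In the cohort, Y loci receive
reads only in males, except paralog-family members, which receive
quarter-depth residual reads in each female with probability 0.3
(cross-mapping from the diverged copy). In the family, parental SNP
genotypes are drawn per SNP as paternal-only 0.35 / maternal-only 0.35 /
both-informative 0.20 / uninformative 0.10 — in an outbred wild-caught
pair, single-parent heterozygosity dominates because double heterozygosity
requires intermediate population allele frequencies. Offspring calls are
corrupted at a 1% genotype-error rate and dropped out at 2%; parental calls
stay intact so that informativeness classes remain ground truth.

**What the generator does not model:** sequencing reads (FASTQ),
restriction-site polymorphism, linked-paralog assembly artefacts, population
structure, or genotype-likelihood uncertainty. Tests that pass on these
simulations therefore establish the correctness of the *computations* under
the stated statistical assumptions, not robustness to every real-data
pathology.

## The association screen

Presence means ≥ 1 read (configurable). The median male depth is computed
over **all** male samples, zero-read samples included — the stricter and
more reproducible reading. The internal paralog search seeds candidate
pairs on shared 15-mers and scores them by infix alignment (edlib),
identity = matched columns / alignment length, coverage = aligned query
fraction; it is validated against an exhaustive Smith–Waterman oracle on
small catalogues. It is full-length-oriented (RAD markers are fixed-length
tags); partial-overlap paralogy below ~80% identity over the whole tag is
not its target. Ranking is lexicographic: residual female reads ascending,
paralog count ascending, mean male depth (over males with reads)
descending, ties by locus id. Recall of planted Y loci is perfect in the
low-dropout regime (≤ ~1%); at 5% dropout the 90%-presence rule itself
excludes loci with ≥ 4 dropped-out males (expected 1.5 ± 1.2 of 30), so
perfect recall is not attainable there by arithmetic, not by
implementation.

## Two-point linkage in an outbred (CP) family

For one parent, the transmitted allele is deduced per offspring where
unambiguous; both-informative markers leave heterozygous offspring
unscored. Phase is unknown, so the recombinant count is
`k = min(d, n−d)` over the two phase assignments. `LOD = k·log₁₀(2r̂) +
(n−k)·log₁₀(2(1−r̂))` with the `r̂ = 0` limit `n·log₁₀2` and `0·log 0 = 0`.
A minError-style shrinkage `r̃ = max(0, (r̂−0.02)/(1−0.04))` absorbs ~2%
miscalls in map distances (LOD uses the raw `r̂`).

**Grouping is done once**, over all informative markers, on the summed
parental LODs; the paternal (father-heterozygous), maternal and
sex-averaged informative masks apply afterwards, at ordering — so the three
map variants share group numbering, as multipoint CP mappers do. Ordering
is greedy nearest-neighbour insertion polished by eight window-3 2-opt
sweeps; positions are cumulative Haldane distances of adjacent `r̃` (capped
at 0.49), so co-segregating markers share a position. Pairs with no shared
informative parent have undefined `r̃` and are completed by one min-plus
pass through an intermediate marker before ordering. Sex-averaged pair
`r̃` is the meiosis-count-weighted mean of the parental estimates. This is
a deliberate two-point simplification of multipoint likelihood mapping:
published maps are parsed, not regenerated bit-exactly.

**LOD limits and marker density.** With n meioses the two-point LOD is
hard-capped at `n·log₁₀2` (≈ 44 at n = 146) for same-parent pairs and at
about half that (≈ 21.97) for links through both-informative markers, where
only homozygous offspring are scorable. A grouping limit of 20 therefore
presumes marker densities at which exact co-segregating bridges are
abundant (tens of thousands of markers); at the simulator's default 1,200
loci a single recombinant or miscall severs such a bridge
(LOD(73, 1) ≈ 19.6), and grouping at LOD 20 shatters chromosomes into
fragments. The recovery analyses therefore cluster simulated maps at
**LOD 10** with a **10-marker group-size floor** (the `sizeLimit` idiom):
comfortably below the both-informative cap, far above the chance ceiling
(≈ 7 at 146 meioses; no cross-chromosome join was ever observed), recovering
exactly 12 groups with adjusted Rand index ≈ 1.0. The pipeline defaults
remain LOD 20 / join-LOD 15 — appropriate for dense real catalogues — and
the error-free Y-cluster acceptance run uses them unchanged.

Known-offspring-sex calling flags a marker as X/Y-linked when paternal
transmission is perfectly sex-concordant among scorable offspring and an
exact binomial test against sex-independent transmission gives p < 10⁻⁶.

## Region scans

Maps are tiled into 2 cM bins, `ceil(length/2)` per group with the last bin
top-closed. Smoothed density uses a Gaussian kernel with SD = half the 10 cM
smoothing range, truncated at ± the range and renormalised per marker, so
per-group smoothed mass equals the marker count exactly; boundary bins are
consequently lean and flatness checks apply to interior bins. Enrichment
uses raw upper tails — `P(X ≥ k)`, X ~ Binomial(m, p̂) for paternal-specific
markers and `P(Y ≥ s)`, Y ~ Poisson(m·λ̂) for paternal-specific SNPs, with
p̂ and λ̂ the genome-wide rates over mapped markers and SNP counts taken
from the pre-thinning records — no multiple-testing correction, because the
scan's use is rank comparison of bins. A marker is paternal-specific when
every SNP of its RAD locus is; a pseudo presence/absence marker counts as
one paternal-specific SNP of its own.

The density contrast reports paternal bins at or above the 95th density
percentile whose markers are effectively absent from the maternal map
(fewer than two placed, with at least one genuinely missing) or maternally
below-median dense. An earlier design that first intersected the two maps'
marker sets was discarded: the intersection retains only both-informative
markers and deletes the pseudo/paternal-only pile-up that constitutes the
signal, returning empty reports even for a 20 cM non-recombining region.

**Scale effects on the negative result.** On default simulations the Y
region's enrichment is overwhelming (its bin holds ~32 paternal-specific
pseudo-markers among ~1,100 mapped markers — a ~30-fold higher
concentration than 32 among 10,763), so its p-value is essentially always
the global minimum; the published observation that other bins out-rank the
Y region is a property of dense real maps. The ambiguity *does* reproduce
through the density channel at this scale: one to eleven other paternal
groups exceed the Y region's density peak in every measured seed, because
telomere-biased male recombination collapses every chromosome centre into a
co-segregating cluster. This is the result the scans are meant to
demonstrate: without known-sex information, linkage signatures alone do not
single out a tiny sdr.

## Synteny filtering

Unique-best-hit: a query survives if its best hit has E ≤ 1e-20 and either
is the only hit (a unique hit has no competing paralog) or is at least five
orders of magnitude more significant than the runner-up; E = 0 is floored
at 1e-300 for the ratio. Filtering is idempotent and order-invariant; ties
break by bit score, then subject id. Orthology is per-group majority vote,
ties toward the larger summed bit score, with a warning when two groups
claim one chromosome.

## Numerical conventions and degenerate inputs

Genotypes are coded −1/0/1/2 (missing/hom-ref/het/hom-alt). Variant filters
use strict inequalities (> 5% missing, < 10 mean depth, < 0.2 MAF) with MAF
over all samples, parents included; pseudo rows bypass the depth and MAF
filters. Thinning keeps the first passing SNP per locus. Empty bins get
p = 1; p-values are floored at 1e-300. A group of one marker has length 0;
ordering orientation is canonicalised by marker id. `cluster_lod` output is
independent of row order; group ids sort by descending size, then smallest
member id. Single-marker and empty inputs return empty/null results rather
than raising, except where an input is contractually required (no sex
labels, no Y loci, unknown locus ids, negative E-values).

## Problem sizes used in validation

Test and acceptance runs use 1,200-locus genomes (300 for the
three-chromosome case), 146-offspring families, 10 replicate families of
200 Y markers for the allele-frequency check, 10⁴ meioses for crossover
properties, and catalogues of 30–60 sequences for alignment oracles. The
published-scale binning check runs on a synthetic stand-in map — 12 groups
with odd-integer lengths summing to 1366 cM and 10,763 markers — labelled
as such in the code; it validates the binning convention at that scale, not
the deposited map itself.
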