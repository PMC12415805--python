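# radsexlink

Discovery of **homomorphic sex-chromosome markers from RADseq data**, for
researchers working on organisms — amphibians, fish, reptiles — whose X and Y
(or Z and W) chromosomes are cytologically indistinguishable and whose
sex-determining region may be tiny. The package implements, as a tested and
reusable library, two complementary strategies:

1. **Association screen on a known-sex cohort.** A Y-restricted (hemizygous)
   RAD locus yields reads in males and none in females. From a loci × samples
   read-depth matrix the screen keeps loci with reads in ≥ 90% of male
   samples (median male depth ≥ 20) and in < 10% of females, counts potential
   paralogs by catalogue self-similarity (> 80% identity, > 25% query
   coverage — in giant repeat-rich genomes paralogs cross-amplify in PCR and
   cause false female positives), and ranks candidates by residual female
   reads, paralog count and male depth.

2. **Linkage-map scan on a full-sib family.** Y presence/absence markers are
   invisible to linkage software (missing in females, homozygous in males),
   so they are encoded as artificial biallelic **pseudo-SNPs** — `AA` when a
   sample has no reads, `AT` when it has reads — making the X-chromosome
   "absence" allele visible. In an XY family the expected minor allele
   frequency of such a marker is 0.25. The family pipeline filters variants
   (no indels, ≤ 5% missing, mean depth ≥ 10, MAF ≥ 0.2, one SNP per RAD
   locus), estimates two-point recombination fractions with phase
   minimisation (`r̂ = min(d, n−d)/n`), scores linkage as
   `LOD = k·log₁₀(2r̂) + (n−k)·log₁₀(2(1−r̂))`, separates linkage groups by
   single-linkage closure, orders markers (greedy insertion + window-3
   2-opt) and assigns cumulative **Haldane** positions
   `d = −50·ln(1−2r̃)` cM. Paternal, maternal and sex-averaged map variants
   apply Lep-MAP-style informative masks at the ordering stage. Region scans
   then bin each map into 2 cM bins and test **paternal-specific**
   marker/SNP enrichment (binomial and Poisson upper tails against
   genome-wide rates) and paternal-vs-maternal smoothed marker density.

A third component, the **simulator**, generates cohorts and families with
the statistical structure these analyses assume — an XY system with a small
non-recombining sex-determining region (sdr), obligate-chiasma meiosis with
telomere-biased male crossovers, paralog families leaking reads into
females, negative-binomial read depth — together with ground-truth tables,
so every stage can be validated by parameter recovery.

There is also a `synteny` module implementing the unique-best-hit filter for
cross-species alignment tables (a query survives only if its best hit beats
the runner-up by ≥ 5 orders of magnitude in E-value) and majority-vote
orthology assignment for Oxford plots.

## Worked example

`examples/01_screen_known_sex_cohort.py` simulates a 30♂/30♀ cohort with 32
planted Y-restricted loci and runs the screen:

```
408 loci screened; 32 truly Y-linked
24 candidates pass the presence/absence screen
true positives among candidates: 24

Top 10 candidates (female residuals asc, paralogs asc, depth desc):
         male_presence  male_median_depth  female_residual_reads  paralog_count  rank
locus
Y000010       1.000000               29.5                      0              0     1
Y000027       0.966667               28.0                      0              0     2
...
```

All 24 candidates are true Y loci; the 8 missing Y loci are the planted
paralog-family members whose autosomal copies leak reads into females —
exactly the failure mode the screen is designed to reject before PCR.
The other examples build the family linkage map (12 linkage groups; the 32
pseudo-markers land in a single paternal group), scan it for the
sex-determining region, and filter synteny hits.

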