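"""Screen a known-sex RADseq cohort for Y-linked presence/absence markers.

Simulates a 30-male / 30-female cohort in which 32 loci exist only on the Y
haplotype (a quarter of them with a diverged autosomal paralog that leaks
reads into females), then applies the depth-matrix screen: reads in >= 90%
of males with a median male depth >= 20, and reads in < 10% of females.
Candidates are annotated with paralog counts from catalogue self-similarity
(> 80% identity, > 25% coverage) and ranked for PCR validation.
"""

from radsexlink import (
    SimParams,
    build_genome,
    count_paralogs,
    place_loci,
    rank_candidates,
    screen_candidates,
    select_top,
    simulate_known_sex_cohort,
)
from radsexlink.sexassoc import candidates_to_frame

genome = build_genome({"seed": 11})
params = SimParams(seed=11, n_loci=400, n_y_loci=32)
catalog, truth = place_loci(genome, params)
cohort = simulate_known_sex_cohort(genome, catalog, truth, params)

candidates = screen_candidates(cohort)
candidates = count_paralogs(catalog, candidates)
ranked = rank_candidates(candidates)
top = select_top(ranked, n=10)

n_y_true = len(truth.y_loci)
print(f"{len(truth.table)} loci screened; {n_y_true} truly Y-linked")
print(f"{len(candidates)} candidates pass the presence/absence screen")
print(f"true positives among candidates: "
      f"{sum(c.locus in set(truth.y_loci) for c in candidates)}")
cols = ["male_presence", "male_median_depth", "female_residual_reads",
        "paralog_count", "rank"]
print("\nTop 10 candidates (female residuals asc, paralogs asc, depth desc):")
print(candidates_to_frame(top)[cols].to_string())
print("\nA rank-1 candidate with zero female residuals and zero paralogs is "
      "the safest PCR target; paralogous Y loci leak reads into females and "
      "are pushed down or filtered out.")
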