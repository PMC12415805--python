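"""Shared fixtures: simulated families run through the full mapping pipeline.

Pipeline runs are session-scoped because a 1,200-locus family plus map build
takes a few seconds; tests share them read-only.
"""

from __future__ import annotations

import pytest

from radsexlink import (
    SimParams,
    build_genome,
    build_maps,
    classify_informativeness,
    encode_presence_absence,
    filter_variants,
    merge_calls,
    place_loci,
    simulate_family,
)
from radsexlink import io as rio

# Grouping parameters for desk-scale (1,200-locus) simulated maps: the LOD
# limit must sit below the both-informative two-point cap (~73*log10(2) ~ 22)
# but far above the chance ceiling (~7 at 146 meioses); small tip fragments
# are dropped rather than force-joined.
SIM_LOD_LIMIT = 10.0
SIM_JOIN_LOD = 10.0
SIM_MIN_GROUP = 10


def run_family_pipeline(
    tmpdir,
    seed: int,
    sdr_width: float = 2.0,
    lod_limit: float = SIM_LOD_LIMIT,
    join_lod: float = SIM_JOIN_LOD,
    min_group_size: int = SIM_MIN_GROUP,
    **param_overrides,
):
    """Simulate a family, write/read the VCF, encode pseudo-markers, map."""
    genome = build_genome({"seed": seed, "sdr_width_cM": sdr_width})
    params = SimParams(seed=seed, **param_overrides)
    catalog, truth = place_loci(genome, params)
    fam = simulate_family(genome, catalog, truth, params)
    vcf = str(tmpdir / f"family_{seed}.vcf")
    rio.write_family_vcf(fam.genotypes, vcf)
    table = filter_variants(vcf)
    block = encode_presence_absence(fam.y_depth, truth.y_loci)
    merged = classify_informativeness(merge_calls(table, block))
    maps = build_maps(
        merged, lod_limit=lod_limit, join_lod=join_lod, min_group_size=min_group_size
    )
    return {
        "genome": genome,
        "catalog": catalog,
        "truth": truth,
        "family": fam,
        "table": merged,
        "maps": maps,
    }


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Three replicate default-parameter pipeline runs (seeds 1-3)."""
    tmpdir = tmp_path_factory.mktemp("fam")
    return {seed: run_family_pipeline(tmpdir, seed) for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def default_run(pipeline_runs):
    return pipeline_runs[1]


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """Error-free family: no genotype errors, no dropout (Y presence exact)."""
    tmpdir = tmp_path_factory.mktemp("fam_clean")
    return run_family_pipeline(
        tmpdir, seed=7, genotype_error_rate=0.0, dropout_prob=0.0
    )


def true_chromosome_labels(run, lmap):
    """Ground-truth chromosome of every marker on a map."""
    meta = run["table"].meta
    truth = run["truth"].table
    return [truth.loc[meta.loc[m, "locus"], "chrom"] for m in lmap.table.index]
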