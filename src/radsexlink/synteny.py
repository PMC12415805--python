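"""Cross-species synteny: best-hit filtering and Oxford-plot tables.

Alignments of mapped RAD markers against a reference genome are filtered by
a unique-best-hit rule designed for highly paralogous genomes: a query is
kept only if its best hit is at least five orders of magnitude more
significant than the runner-up (single-hit queries are kept — they have no
competing paralog) and meets a minimum E-value. Each linkage group is then
assigned its majority reference chromosome, yielding an Oxford-plot table
and the overall fraction of markers on their orthologous chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkmap import LinkageMap

_EVALUE_FLOOR = 1e-300  # stands in for E = 0 in ratio comparisons


def filter_unique_best(
    hits: pd.DataFrame, margin_orders: float = 5.0, min_evalue: float = 1e-20
) -> pd.DataFrame:
    """Keep one hit per query passing the unique-best-hit rule.

    A query survives iff its best hit has E <= ``min_evalue`` and either it
    is the only hit or best E <= next-best E * 10^(-margin_orders). E = 0 is
    treated as 1e-300 for the ratio. Idempotent and order-invariant; ties in
    E break toward the higher bit score, then subject id.
    """
    if (hits["evalue"] < 0).any():
        raise ValueError("negative E-values in hit table")
    if len(hits) == 0:
        return hits.copy()
    work = hits.copy()
    work["_e"] = work["evalue"].clip(lower=_EVALUE_FLOOR)
    if "bitscore" not in work.columns:
        work["bitscore"] = 0.0
    work = work.sort_values(
        ["qseqid", "_e", "bitscore", "sseqid"], ascending=[True, True, False, True], kind="stable"
    )
    keep_rows = []
    for _, grp in work.groupby("qseqid", sort=True):
        best = grp.iloc[0]
        if best["_e"] > min_evalue:
            continue
        if len(grp) == 1 or best["_e"] <= grp.iloc[1]["_e"] * 10.0 ** (-margin_orders):
            keep_rows.append(best)
    out = pd.DataFrame(keep_rows, columns=work.columns).drop(columns=["_e"])
    return out.reset_index(drop=True)


@dataclass
class OrthologyResult:
    """Per-group chromosome assignment plus the Oxford table."""

    assignment: pd.DataFrame  # index group: chromosome, n_on, n_total, fraction_on
    oxford: pd.DataFrame  # marker, group, position_cM, chromosome, position_bp
    fraction_on_orthologous: float


def assign_orthology(lmap: LinkageMap, filtered_hits: pd.DataFrame) -> OrthologyResult | None:
    """Majority-vote chromosome assignment per linkage group.

    Only hits of mapped markers are used. Ties in the majority vote break
    toward the chromosome with the larger summed bit score. Two groups
    claiming the same chromosome (non-reciprocal assignment) raise a
    warning. Returns None when no mapped marker has a hit.
    """
    hits = filtered_hits[filtered_hits["qseqid"].isin(lmap.table.index)].copy()
    if len(hits) == 0:
        return None
    hits["group"] = lmap.table.loc[hits["qseqid"], "group"].to_numpy()
    hits["position_cM"] = lmap.table.loc[hits["qseqid"], "position_cM"].to_numpy()
    if "bitscore" not in hits.columns:
        hits["bitscore"] = 0.0

    rows = []
    for g, grp in hits.groupby("group", sort=True):
        votes = grp.groupby("sseqid").agg(n=("sseqid", "size"), score=("bitscore", "sum"))
        votes = votes.sort_values(["n", "score"], ascending=False, kind="stable")
        chrom = votes.index[0]
        rows.append(
            {
                "group": int(g),
                "chromosome": chrom,
                "n_on": int(votes.iloc[0]["n"]),
                "n_total": int(len(grp)),
            }
        )
    assignment = pd.DataFrame(rows).set_index("group")
    assignment["fraction_on"] = assignment["n_on"] / assignment["n_total"]
    dup = assignment["chromosome"].value_counts()
    if (dup > 1).any():
        claimed = dup[dup > 1].index.tolist()
        warnings.warn(
            f"non-reciprocal assignment: chromosome(s) {claimed} claimed by multiple groups",
            stacklevel=2,
        )
    oxford = pd.DataFrame(
        {
            "marker": hits["qseqid"].to_numpy(),
            "group": hits["group"].to_numpy(),
            "position_cM": hits["position_cM"].to_numpy(),
            "chromosome": hits["sseqid"].to_numpy(),
            "position_bp": hits["sstart"].to_numpy() if "sstart" in hits.columns else np.nan,
        }
    )
    on = hits["sseqid"].to_numpy() == assignment.loc[hits["group"], "chromosome"].to_numpy()
    return OrthologyResult(assignment, oxford, float(np.mean(on)))


def ortholog_separation(start_a_bp: float, start_b_bp: float, chromosome_length_bp: float):
    """Physical separation of two orthologs and its fraction of the
    chromosome: (|a - b|, |a - b| / length)."""
    if chromosome_length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    sep = abs(float(start_a_bp) - float(start_b_bp))
    return sep, sep / float(chromosome_length_bp)
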