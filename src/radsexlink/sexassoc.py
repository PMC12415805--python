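"""Candidate Y-marker screening from a known-sex read-depth matrix.

A Y-restricted (hemizygous) locus yields reads in males and none in females.
The screen keeps loci with reads in at least 90% of male samples (median
depth across all males >= 20) and in fewer than 10% of female samples; a
stricter "radsex-style" variant demands absolute absence in females. Passing
candidates are annotated with paralog counts (catalogue self-similarity at
>80% identity and >25% query coverage) and ranked for PCR validation by
residual female reads, paralogy and male depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DepthMatrix, MarkerCatalog  # re-exported surface


@dataclass(frozen=True)
class ScreenThresholds:
    male_presence_min: float = 0.90
    male_median_depth_min: float = 20.0
    female_presence_max: float = 0.10
    presence_min_reads: int = 1

    def __post_init__(self):
        if not (0 <= self.male_presence_min <= 1 and 0 <= self.female_presence_max <= 1):
            raise ValueError("presence fractions must be in [0, 1]")
        if self.male_median_depth_min < 0 or self.presence_min_reads < 0:
            raise ValueError("depth thresholds must be non-negative")


@dataclass
class CandidateMarker:
    locus: str
    male_presence: float
    male_median_depth: float
    female_presence: float
    female_residual_reads: int
    male_mean_depth: float
    paralog_count: int | None = None
    rank: int | None = None
    radsex_style: bool = False


def _screen_stats(depth: DepthMatrix, presence_min_reads: int):
    males, females = depth.males, depth.females
    if not males or not females:
        raise ValueError("screen needs at least one male and one female sample")
    mc = depth.counts[males].to_numpy()
    fc = depth.counts[females].to_numpy()
    present_m = mc >= presence_min_reads
    stats = pd.DataFrame(
        {
            "male_presence": present_m.mean(axis=1),
            # median over ALL male samples, zero-read samples included
            "male_median_depth": np.median(mc, axis=1),
            "female_presence": (fc >= presence_min_reads).mean(axis=1),
            "female_residual_reads": fc.sum(axis=1),
            "male_mean_depth": np.where(
                present_m.any(axis=1),
                mc.sum(axis=1) / np.maximum(present_m.sum(axis=1), 1),
                0.0,
            ),
        },
        index=depth.loci,
    )
    return stats


def _to_candidates(stats: pd.DataFrame, keep: np.ndarray, radsex_style=False):
    out = []
    for locus, row in stats[keep].iterrows():
        out.append(
            CandidateMarker(
                locus=locus,
                male_presence=float(row["male_presence"]),
                male_median_depth=float(row["male_median_depth"]),
                female_presence=float(row["female_presence"]),
                female_residual_reads=int(row["female_residual_reads"]),
                male_mean_depth=float(row["male_mean_depth"]),
                radsex_style=radsex_style,
            )
        )
    return out


def screen_candidates(
    depth: DepthMatrix, thresholds: ScreenThresholds | None = None
) -> list[CandidateMarker]:
    """Loci with presence in >= 90% of males (median male depth >= 20) and
    presence in < 10% of females; presence means >= ``presence_min_reads``.

    Returns candidates in locus-id order, carrying all screening statistics.
    An empty matrix yields an empty list.
    """
    th = thresholds or ScreenThresholds()
    if len(depth.loci) == 0:
        return []
    stats = _screen_stats(depth, th.presence_min_reads)
    keep = (
        (stats["male_presence"] >= th.male_presence_min)
        & (stats["male_median_depth"] >= th.male_median_depth_min)
        & (stats["female_presence"] < th.female_presence_max)
    ).to_numpy()
    return _to_candidates(stats, keep)


def screen_candidates_radsex_style(
    depth: DepthMatrix, min_male_median_depth: float = 20.0, presence_min_reads: int = 1
) -> list[CandidateMarker]:
    """Stricter absence-based screen: zero reads in every female, presence in
    at least one male, and median depth across all males >= the threshold."""
    if len(depth.loci) == 0:
        return []
    stats = _screen_stats(depth, presence_min_reads)
    females = depth.females
    strict_absent = (depth.counts[females].to_numpy() == 0).all(axis=1)
    keep = (
        strict_absent
        & (stats["male_presence"].to_numpy() > 0)
        & (stats["male_median_depth"].to_numpy() >= min_male_median_depth)
    )
    return _to_candidates(stats, keep, radsex_style=True)


# ---------------------------------------------------------------------------
# Paralog counting


def _kmers(seq: str, k: int):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _identity_coverage(query: str, subject: str) -> tuple[float, float]:
    """Percent identity and query coverage of the best infix alignment of
    ``query`` within ``subject`` (edlib, extended CIGAR)."""
    import edlib
    import re

    res = edlib.align(query, subject, mode="HW", task="path")
    cigar = res.get("cigar")
    if not cigar:
        return 0.0, 0.0
    ops = {"=": 0, "X": 0, "I": 0, "D": 0}
    for count, op in re.findall(r"(\d+)([=XID])", cigar):
        ops[op] += int(count)
    aln_len = sum(ops.values())
    if not aln_len:
        return 0.0, 0.0
    identity = 100.0 * ops["="] / aln_len
    # infix mode consumes the whole query; coverage is the aligned fraction
    coverage = 100.0 * (ops["="] + ops["X"] + ops["I"]) / len(query)
    return identity, min(coverage, 100.0)


def _internal_hits(catalog: MarkerCatalog, queries: list[str], k: int = 15):
    """K-mer-seeded all-vs-catalogue similarity hits for the query loci."""
    index: dict[str, set[str]] = {}
    for sid, seq in catalog.items():
        for km in _kmers(seq, k):
            index.setdefault(km, set()).add(sid)
    hits = []
    for q in queries:
        qseq = catalog[q]
        partners = set()
        for km in _kmers(qseq, k):
            partners |= index.get(km, set())
        partners.discard(q)
        for s in sorted(partners):
            ident, cov = _identity_coverage(qseq, catalog[s])
            hits.append({"qseqid": q, "sseqid": s, "pident": ident, "qcovs": cov})
    return pd.DataFrame(hits, columns=["qseqid", "sseqid", "pident", "qcovs"])


def count_paralogs(
    catalog: MarkerCatalog,
    candidates: list[CandidateMarker],
    min_identity: float = 80.0,
    min_coverage: float = 25.0,
    hits: pd.DataFrame | None = None,
) -> list[CandidateMarker]:
    """Attach paralog counts: non-self catalogue sequences hit at
    >= ``min_identity`` percent identity and > ``min_coverage`` percent
    query coverage.

    When an external hit table (BLAST outfmt-6 style, with a ``qcovs``
    column) is supplied it is used verbatim; otherwise an internal
    15-mer-seeded infix-alignment search over the catalogue is performed.
    """
    for c in candidates:
        if c.locus not in catalog:
            raise ValueError(f"candidate sequence missing from catalogue: {c.locus}")
    queries = [c.locus for c in candidates]
    table = hits if hits is not None else _internal_hits(catalog, queries)
    counted: dict[str, int] = {q: 0 for q in queries}
    if len(table):
        sub = table[
            (table["qseqid"].isin(queries))
            & (table["qseqid"] != table["sseqid"])
            & (table["pident"] >= min_identity)
            & (table["qcovs"] > min_coverage)
        ]
        vc = sub.drop_duplicates(["qseqid", "sseqid"]).groupby("qseqid").size()
        counted.update(vc.to_dict())
    out = []
    for c in candidates:
        out.append(
            CandidateMarker(
                **{**c.__dict__, "paralog_count": int(counted[c.locus])}
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ranking and shortlist handling


def rank_candidates(candidates: list[CandidateMarker]) -> list[CandidateMarker]:
    """Lexicographic ranking for validation: residual female reads ascending,
    paralog count ascending, mean male depth descending; ties by locus id."""
    if any(c.paralog_count is None for c in candidates):
        raise ValueError("paralog counts must be populated before ranking")
    ordered = sorted(
        candidates,
        key=lambda c: (c.female_residual_reads, c.paralog_count, -c.male_mean_depth, c.locus),
    )
    return [
        CandidateMarker(**{**c.__dict__, "rank": i + 1}) for i, c in enumerate(ordered)
    ]


def select_top(ranked: list[CandidateMarker], n: int = 10) -> list[CandidateMarker]:
    """First ``n`` entries of a ranked list (the whole list if shorter)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return list(ranked[:n])


def deduplicate_across_runs(
    shortlists: list[list[CandidateMarker]], catalogs: list[MarkerCatalog]
) -> list[CandidateMarker]:
    """Union of shortlists from multiple pipeline runs, deduplicated by exact
    sequence identity (first occurrence wins)."""
    if len(shortlists) != len(catalogs):
        raise ValueError("need one catalogue per shortlist")
    seen: set[str] = set()
    out = []
    for lst, cat in zip(shortlists, catalogs):
        for c in lst:
            seq = cat[c.locus]
            if seq not in seen:
                seen.add(seq)
                out.append(c)
    return out


def candidates_to_frame(candidates: list[CandidateMarker]) -> pd.DataFrame:
    """Tabular view of a candidate list (one row per locus)."""
    return pd.DataFrame([c.__dict__ for c in candidates]).set_index("locus")
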