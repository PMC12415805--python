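"""Sex-determining-region scans on a linkage map.

Two complementary scans, both operating on 2 cM bins of an ordered map:

* a marker-density contrast between the paternal and maternal maps
  (a non-recombining male region piles markers onto a single paternal
  position while staying spread out maternally), smoothed with a truncated
  Gaussian kernel; and
* an enrichment scan for paternal-specific markers and SNPs (heterozygous in
  the father, homozygous in the mother), testing each bin's counts against
  genome-wide rates with a binomial (markers) and Poisson (SNPs) upper tail.

P-values are reported raw (no multiple-testing correction); the scan's
purpose is rank comparison of bins, mirroring a Manhattan-style display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .linkmap import GenotypeTable, LinkageMap, PATERNAL_ONLY


@dataclass(frozen=True)
class GlobalRates:
    """Genome-wide paternal-specific rates: p_hat = markers fraction,
    lambda_hat = SNPs per mapped marker."""

    p_hat: float
    lambda_hat: float

    def __post_init__(self):
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError("p_hat must be in [0, 1]")
        if self.lambda_hat < 0:
            raise ValueError("lambda_hat must be >= 0")


def bin_map(lmap: LinkageMap, bin_cM: float = 2.0) -> pd.DataFrame:
    """Tile each linkage group with ``bin_cM`` bins and count markers.

    Bins are [0, b), [b, 2b), ...; the number of bins per group is
    ceil(length / b) with the final bin closed at the top so the last marker
    is always binned. Every marker lands in exactly one bin. Returns a frame
    with one row per bin: group, bin_index, start, end, m.
    """
    rows = []
    for g in lmap.groups:
        sub = lmap.group_markers(g)
        length = float(sub["position_cM"].max())
        n_bins = max(1, int(np.ceil(length / bin_cM))) if length > 0 else 1
        idx = np.minimum((sub["position_cM"].to_numpy() / bin_cM).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        for b in range(n_bins):
            rows.append(
                {
                    "group": g,
                    "bin_index": b,
                    "start": b * bin_cM,
                    "end": (b + 1) * bin_cM,
                    "m": int(counts[b]),
                }
            )
    return pd.DataFrame(rows, columns=["group", "bin_index", "start", "end", "m"])


def marker_bins(lmap: LinkageMap, bin_cM: float = 2.0) -> pd.DataFrame:
    """Per-marker (group, bin_index) assignment under :func:`bin_map`'s
    convention."""
    parts = []
    for g in lmap.groups:
        sub = lmap.group_markers(g)
        length = float(sub["position_cM"].max())
        n_bins = max(1, int(np.ceil(length / bin_cM))) if length > 0 else 1
        idx = np.minimum((sub["position_cM"].to_numpy() / bin_cM).astype(int), n_bins - 1)
        parts.append(pd.DataFrame({"group": g, "bin_index": idx}, index=sub.index))
    return pd.concat(parts) if parts else pd.DataFrame(columns=["group", "bin_index"])


def density_profile(
    lmap: LinkageMap, bin_cM: float = 2.0, smooth_range_cM: float = 10.0
) -> pd.DataFrame:
    """Gaussian-smoothed per-bin marker density.

    Kernel SD is ``smooth_range_cM / 2`` truncated at +/- ``smooth_range_cM``
    and renormalised per marker over the bins of its group, so the smoothed
    mass of each group equals its marker count (no mass lost at group edges).
    """
    sd = smooth_range_cM / 2.0
    bins = bin_map(lmap, bin_cM)
    out = []
    for g in lmap.groups:
        gb = bins[bins["group"] == g]
        centers = ((gb["start"] + gb["end"]) / 2.0).to_numpy()
        density = np.zeros(len(centers))
        pos = lmap.group_markers(g)["position_cM"].to_numpy()
        for p in pos:
            d = np.abs(centers - p)
            w = np.where(d <= smooth_range_cM, np.exp(-0.5 * (d / sd) ** 2), 0.0)
            total = w.sum()
            if total > 0:
                density += w / total
        gb = gb.copy()
        gb["density"] = density
        out.append(gb)
    return pd.concat(out, ignore_index=True) if out else bins.assign(density=[])


def contrast_density(
    paternal_map: LinkageMap,
    maternal_map: LinkageMap,
    bin_cM: float = 2.0,
    smooth_range_cM: float = 10.0,
    quantile: float = 0.95,
) -> pd.DataFrame:
    """Paternal-exclusive density peaks.

    Bins whose paternal density reaches the given quantile are reported as
    paternal-exclusive when the markers of the bin are effectively absent
    from the maternal map (fewer than two placed there) or, where placed,
    their maternal-bin densities stay below the maternal profile's median —
    a paternal pile-up with no maternal counterpart. The two maps are
    expected to share group numbering (they do when built together); an
    error is raised if they share no markers at all. Ranked by paternal
    density, descending; may be empty (identical maps exclude everything,
    since every candidate bin's markers are maternally as dense as
    themselves).
    """
    if len(paternal_map.table.index.intersection(maternal_map.table.index)) == 0:
        raise ValueError("paternal and maternal maps share no markers")
    pat_prof = density_profile(paternal_map, bin_cM, smooth_range_cM)
    mat_prof = density_profile(maternal_map, bin_cM, smooth_range_cM)
    pat_assign = marker_bins(paternal_map, bin_cM)
    mat_assign = marker_bins(maternal_map, bin_cM)
    mat_density = mat_prof.set_index(["group", "bin_index"])["density"]
    mat_median = float(mat_prof["density"].median())
    threshold = float(pat_prof["density"].quantile(quantile))

    rows = []
    for _, b in pat_prof[pat_prof["density"] >= threshold].iterrows():
        in_bin = pat_assign[
            (pat_assign["group"] == b["group"]) & (pat_assign["bin_index"] == b["bin_index"])
        ].index
        if len(in_bin) == 0:
            continue
        on_mat = [m for m in in_bin if m in mat_assign.index]
        if len(on_mat) < 2 and len(on_mat) < len(in_bin):
            # a paternal pile-up whose markers are (almost) absent maternally
            mdens = 0.0
            exclusive = True
        else:
            mkeys = mat_assign.loc[on_mat]
            mdens = float(
                np.median(
                    [float(mat_density.get((g, i), 0.0)) for g, i in zip(mkeys["group"], mkeys["bin_index"])]
                )
            )
            exclusive = mdens < mat_median
        if exclusive:
            rows.append(
                {
                    "group": int(b["group"]),
                    "bin_index": int(b["bin_index"]),
                    "start": float(b["start"]),
                    "end": float(b["end"]),
                    "paternal_density": float(b["density"]),
                    "maternal_density_median": mdens,
                    "n_markers": int(len(in_bin)),
                    "n_on_maternal": int(len(on_mat)),
                }
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "group", "bin_index", "start", "end",
            "paternal_density", "maternal_density_median", "n_markers", "n_on_maternal",
        ],
    )
    return report.sort_values("paternal_density", ascending=False, kind="stable").reset_index(drop=True)


def count_parent_specific(
    lmap: LinkageMap, table: GenotypeTable, bin_cM: float = 2.0
) -> tuple[pd.DataFrame, GlobalRates]:
    """Per-bin totals of paternal-specific markers (k) and SNPs (s).

    A SNP is paternal-specific when heterozygous in the father and homozygous
    in the mother; a marker is paternal-specific when *every* SNP of its RAD
    locus is. SNP counts use the pre-thinning records retained on the
    genotype table; a pseudo presence/absence marker counts as one
    paternal-specific SNP of its own. Global rates are totals over the mapped
    markers: p_hat = sum(k)/sum(m), lambda_hat = sum(s)/sum(m).
    """
    if "informativeness" not in table.meta.columns:
        raise ValueError("informativeness classes required; run classify_informativeness")
    assign = marker_bins(lmap, bin_cM)
    snp = table.snp_table

    k_flags, s_counts = {}, {}
    for marker in assign.index:
        if marker not in table.meta.index:
            raise ValueError(f"mapped marker missing from genotype table: {marker}")
        locus = table.meta.loc[marker, "locus"]
        if bool(table.meta.loc[marker, "pseudo"]) or snp is None:
            cls = [table.meta.loc[marker, "informativeness"]]
        else:
            sub = snp[snp["locus"] == locus]
            cls = list(sub["snp_class"]) if len(sub) else [table.meta.loc[marker, "informativeness"]]
        k_flags[marker] = all(c == PATERNAL_ONLY for c in cls)
        s_counts[marker] = sum(c == PATERNAL_ONLY for c in cls)

    bins = bin_map(lmap, bin_cM)
    per = assign.copy()
    per["k"] = [int(k_flags[m]) for m in per.index]
    per["s"] = [s_counts[m] for m in per.index]
    agg = per.groupby(["group", "bin_index"])[["k", "s"]].sum()
    bins = bins.join(agg, on=["group", "bin_index"]).fillna({"k": 0, "s": 0})
    bins["k"] = bins["k"].astype(int)
    bins["s"] = bins["s"].astype(int)
    total_m = int(bins["m"].sum())
    rates = GlobalRates(
        p_hat=bins["k"].sum() / total_m if total_m else 0.0,
        lambda_hat=bins["s"].sum() / total_m if total_m else 0.0,
    )
    return bins, rates


def enrichment_test(bins: pd.DataFrame, rates: GlobalRates) -> pd.DataFrame:
    """Upper-tail enrichment p-values per bin.

    Markers: P(X >= k), X ~ Binomial(m, p_hat). SNPs: P(Y >= s),
    Y ~ Poisson(m * lambda_hat). Empty bins get p = 1; p-values are raw.
    """
    out = bins.copy()
    m = out["m"].to_numpy()
    k = out["k"].to_numpy()
    s = out["s"].to_numpy()
    p_binom = np.ones(len(out))
    p_pois = np.ones(len(out))
    nz = m > 0
    p_binom[nz] = stats.binom.sf(k[nz] - 1, m[nz], rates.p_hat)
    p_pois[nz] = stats.poisson.sf(s[nz] - 1, m[nz] * rates.lambda_hat)
    out["p_binom"] = np.clip(p_binom, 1e-300, 1.0)
    out["p_pois"] = np.clip(p_pois, 1e-300, 1.0)
    return out


@dataclass
class SexRegionReport:
    """Location of the pseudo-marker (candidate Y) cluster on a map."""

    group: int | None
    span_cM: float | None
    n_pseudo: int
    bin_indices: list[int]
    p_binom: list[float]
    p_pois: list[float]
    split_across_groups: bool = False

    @property
    def identified(self) -> bool:
        return self.group is not None


def locate_sex_region(
    lmap: LinkageMap, bins_with_p: pd.DataFrame | None = None, bin_cM: float = 2.0
) -> SexRegionReport:
    """Report where the presence/absence pseudo-markers landed.

    Names the group holding the pseudo-markers, their cM span, their bins,
    and (when an enrichment table is supplied) those bins' p-values. If no
    pseudo-marker was placed, returns a null report rather than raising;
    pseudo-markers split across groups trigger a warning and the majority
    group is reported.
    """
    pseudo = lmap.table[lmap.table["pseudo"].astype(bool)]
    if len(pseudo) == 0:
        return SexRegionReport(None, None, 0, [], [], [])
    groups = pseudo["group"].value_counts()
    split = len(groups) > 1
    if split:
        warnings.warn(
            f"pseudo-markers split across {len(groups)} linkage groups", stacklevel=2
        )
    g = int(groups.idxmax())
    sub = pseudo[pseudo["group"] == g]
    span = float(sub["position_cM"].max() - sub["position_cM"].min())
    assign = marker_bins(lmap, bin_cM).loc[sub.index]
    bin_ids = sorted(assign["bin_index"].unique().tolist())
    p_b, p_p = [], []
    if bins_with_p is not None:
        lookup = bins_with_p.set_index(["group", "bin_index"])
        for b in bin_ids:
            if (g, b) in lookup.index:
                p_b.append(float(lookup.loc[(g, b), "p_binom"]))
                p_p.append(float(lookup.loc[(g, b), "p_pois"]))
    return SexRegionReport(g, span, int(len(pseudo)), bin_ids, p_b, p_p, split)
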