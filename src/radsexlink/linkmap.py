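"""Linkage-map construction for an outbred full-sib (CP) family.

Implements the map-building stage of the pipeline: variant filtering, parental
informativeness classification, two-point recombination estimation with
phase minimisation, single-linkage LOD clustering, a join-singles pass, and
greedy ordering with 2-opt polishing. Paternal, maternal and sex-averaged maps
are built from informative-marker masks: the paternal map uses markers
heterozygous in the father (paternal-only and both-informative), the maternal
map the symmetric set, and the sex-averaged map all informative markers with
recombination fractions averaged over the available parental meioses.

This is a defined two-point simplification of multipoint CP mapping: linkage
groups come from transitive closure over pairwise LOD >= a limit, and orders
from nearest-neighbour insertion plus window-3 2-opt, not from a multipoint
likelihood. Distances are Haldane.

Genotypes are coded integers: -1 missing, 0 hom-ref, 1 het, 2 hom-alt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

PATERNAL_ONLY = "paternal-only"
MATERNAL_ONLY = "maternal-only"
BOTH = "both"
UNINFORMATIVE = "uninformative"

PATERNAL = "paternal"
MATERNAL = "maternal"
SEX_AVERAGED = "sex-averaged"


# ---------------------------------------------------------------------------
# Mapping function


def haldane(r):
    """Haldane map distance in cM for recombination fraction ``r``."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * r)


def inverse_haldane(d):
    """Recombination fraction for a Haldane distance ``d`` in cM."""
    d = np.asarray(d, dtype=float)
    return 0.5 * -np.expm1(-d / 50.0)


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class FilterParams:
    """Variant-filter thresholds (strict inequalities, as applied)."""

    max_missing_fraction: float = 0.05
    min_mean_depth: float = 10.0
    min_maf: float = 0.2
    one_snp_per_marker: bool = True

    def __post_init__(self):
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class GenotypeTable:
    """Coded diploid calls for a full-sib family (markers x samples).

    ``calls`` rows are marker ids, columns sample ids (father and mother among
    them); ``meta`` is indexed like ``calls`` and carries at least ``locus``
    and ``pseudo`` columns, with ``informativeness`` added by
    :func:`classify_informativeness`. ``snp_table`` optionally retains the
    pre-thinning SNP records (one row per SNP) for parent-specific counting.
    """

    calls: pd.DataFrame
    father: str
    mother: str
    meta: pd.DataFrame
    depths: pd.DataFrame | None = None
    snp_table: pd.DataFrame | None = None

    def __post_init__(self):
        for parent in (self.father, self.mother):
            if parent not in self.calls.columns:
                raise ValueError(f"parent column {parent!r} missing from calls")
        if not self.calls.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.calls.index]

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def offspring(self) -> list[str]:
        return [s for s in self.calls.columns if s not in (self.father, self.mother)]

    @property
    def markers(self) -> pd.Index:
        return self.calls.index


@dataclass(frozen=True)
class TwoPointResult:
    marker_a: str
    marker_b: str
    parent: str
    n: int
    k: int
    rf: float
    rf_adjusted: float
    lod: float


@dataclass
class LinkageMap:
    """Ordered markers with per-group cM positions.

    ``table`` is indexed by marker id with columns ``group`` (1-based int,
    groups numbered by descending size), ``position_cM``, ``informativeness``
    and ``pseudo``.
    """

    table: pd.DataFrame
    variant: str = SEX_AVERAGED

    @property
    def groups(self) -> list[int]:
        return sorted(self.table["group"].unique())

    def group_markers(self, group: int) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.sort_values("position_cM", kind="stable")

    def group_length(self, group: int) -> float:
        return float(self.table.loc[self.table["group"] == group, "position_cM"].max())

    @property
    def total_length(self) -> float:
        return float(sum(self.group_length(g) for g in self.groups))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Filtering and classification


def _classify_codes(father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Vectorised informativeness classes from coded parental genotypes."""
    f_het = father == HET
    m_het = mother == HET
    f_hom = (father == HOM_REF) | (father == HOM_ALT)
    m_hom = (mother == HOM_REF) | (mother == HOM_ALT)
    out = np.full(father.shape, UNINFORMATIVE, dtype=object)
    out[f_het & m_hom] = PATERNAL_ONLY
    out[m_het & f_hom] = MATERNAL_ONLY
    out[f_het & m_het] = BOTH
    return out


def classify_informativeness(table: GenotypeTable) -> GenotypeTable:
    """Attach per-marker informativeness classes derived from the parents.

    Paternal-only: father heterozygous, mother homozygous; maternal-only the
    symmetric case; both: both parents heterozygous; anything else (including
    a missing parental call) is uninformative.
    """
    father = table.calls[table.father].to_numpy()
    mother = table.calls[table.mother].to_numpy()
    meta = table.meta.copy()
    meta["informativeness"] = _classify_codes(father, mother)
    return replace(table, meta=meta)


def filter_variants(
    vcf_path,
    params: FilterParams | None = None,
    father: str = "father",
    mother: str = "mother",
) -> GenotypeTable:
    """Read a family VCF and apply the linkage-map variant filters.

    Excludes indels and any SNP with missing-call fraction > 5%, mean depth
    < 10, or minor allele frequency < 0.2 (MAF over all samples, parents
    included), then thins to one SNP per RAD locus (the first passing SNP;
    the VCF CHROM field is taken as the locus id, as in Stacks catalogues).
    Rows flagged ``PSEUDO=1`` in INFO bypass the depth and MAF filters.

    The pre-thinning SNP records (locus, parental genotypes, class) are kept
    on the returned table as ``snp_table`` for parent-specific counting.
    """
    from cyvcf2 import VCF

    params = params or FilterParams()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for parent in (father, mother):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not found in VCF")
    fa_idx, mo_idx = samples.index(father), samples.index(mother)

    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code_map = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)

    rows, row_ids, metas, depth_rows, snp_records = [], [], [], [], []
    seen_locus: set[str] = set()
    for v in vcf:
        if v.is_indel or len(v.ALT) != 1 or not v.is_snp:
            continue
        codes = code_map[np.asarray(v.gt_types)]
        missing_frac = float(np.mean(codes == MISSING))
        pseudo = bool(v.INFO.get("PSEUDO"))
        if missing_frac > params.max_missing_fraction:
            continue
        dp = v.format("DP")
        mean_depth = float(np.mean(dp[dp >= 0])) if dp is not None and (dp >= 0).any() else 0.0
        called = codes[codes != MISSING]
        alt_freq = float(np.sum(called)) / (2.0 * len(called)) if len(called) else 0.0
        maf = min(alt_freq, 1.0 - alt_freq)
        if not pseudo:
            if mean_depth < params.min_mean_depth:
                continue
            if maf < params.min_maf:
                continue
        locus = v.CHROM
        marker_id = v.ID if v.ID not in (None, ".") else f"{locus}:{v.POS}"
        snp_records.append(
            {
                "marker_id": marker_id,
                "locus": locus,
                "father_code": int(codes[fa_idx]),
                "mother_code": int(codes[mo_idx]),
                "pseudo": pseudo,
            }
        )
        if params.one_snp_per_marker and locus in seen_locus:
            continue
        seen_locus.add(locus)
        rows.append(codes)
        row_ids.append(marker_id)
        metas.append({"locus": locus, "pseudo": pseudo, "mean_depth": mean_depth, "maf": maf})
        depth_rows.append(dp[:, 0] if dp is not None and dp.ndim == 2 else np.zeros(len(samples)))

    calls = pd.DataFrame(
        np.array(rows, dtype=np.int8).reshape(len(rows), len(samples)),
        index=pd.Index(row_ids, name="marker_id"),
        columns=samples,
    )
    meta = pd.DataFrame(metas, index=calls.index)
    snp_table = pd.DataFrame(snp_records).set_index("marker_id") if snp_records else None
    if snp_table is not None and len(snp_table):
        snp_table["snp_class"] = _classify_codes(
            snp_table["father_code"].to_numpy(), snp_table["mother_code"].to_numpy()
        )
    depths = pd.DataFrame(np.array(depth_rows), index=calls.index, columns=samples)
    return GenotypeTable(calls, father, mother, meta, depths=depths, snp_table=snp_table)


# ---------------------------------------------------------------------------
# Two-point estimation


def transmissions(table: GenotypeTable, parent: str) -> pd.DataFrame:
    """Transmitted-allele matrix for one parent: markers x offspring.

    Entries are 0 (ref transmitted), 1 (alt transmitted) or NaN where the
    transmission cannot be deduced (parent not heterozygous, offspring
    missing, or a both-informative marker with a heterozygous offspring,
    whose paternal/maternal origin is ambiguous). Mendelian-impossible
    offspring calls score NaN as well.
    """
    if parent == PATERNAL:
        focal, other = table.father, table.mother
    elif parent == MATERNAL:
        focal, other = table.mother, table.father
    else:
        raise ValueError("parent must be 'paternal' or 'maternal'")

    off = table.calls[table.offspring].to_numpy(dtype=np.int8)
    focal_g = table.calls[focal].to_numpy()
    other_g = table.calls[other].to_numpy()

    t = np.full(off.shape, np.nan)
    het = focal_g == HET

    m = het & (other_g == HOM_REF)
    t[m] = np.where(off[m] == HOM_REF, 0.0, np.where(off[m] == HET, 1.0, np.nan))
    m = het & (other_g == HOM_ALT)
    t[m] = np.where(off[m] == HET, 0.0, np.where(off[m] == HOM_ALT, 1.0, np.nan))
    m = het & (other_g == HET)
    t[m] = np.where(off[m] == HOM_REF, 0.0, np.where(off[m] == HOM_ALT, 1.0, np.nan))

    return pd.DataFrame(t, index=table.markers, columns=table.offspring)


def _lod_from_counts(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """LOD(r̂) = k log10(2r̂) + (n−k) log10(2(1−r̂)), with 0·log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        term1 = np.where(k > 0, k * np.log10(2.0 * rf), 0.0)
        term2 = np.where(n - k > 0, (n - k) * np.log10(2.0 * (1.0 - rf)), 0.0)
    lod = term1 + term2
    return np.where(n > 0, lod, 0.0)


def shrink_rf(rf, min_error: float = 0.02):
    """Genotyping-error adjustment: r̃ = max(0, (r̂ − e) / (1 − 2e))."""
    rf = np.asarray(rf, dtype=float)
    return np.maximum(0.0, (rf - min_error) / (1.0 - 2.0 * min_error))


def pairwise_two_point(t: pd.DataFrame):
    """All-pairs two-point statistics from a transmission matrix.

    Returns (n, k, rf, lod) square DataFrames over the marker index, where k
    is the phase-minimised recombinant count min(d, n−d).
    """
    a1 = (t.to_numpy() == 1.0).astype(np.float64)
    a0 = (t.to_numpy() == 0.0).astype(np.float64)
    scored = a1 + a0
    n = scored @ scored.T
    d = a1 @ a0.T + a0 @ a1.T
    k = np.minimum(d, n - d)
    with np.errstate(invalid="ignore"):
        rf = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    lod = _lod_from_counts(k, n)
    idx = t.index
    wrap = lambda m: pd.DataFrame(m, index=idx, columns=idx)
    return wrap(n), wrap(k), wrap(rf), wrap(lod)


def estimate_rf(
    table: GenotypeTable,
    marker_a: str,
    marker_b: str,
    parent: str = PATERNAL,
    min_error: float = 0.02,
) -> TwoPointResult:
    """Two-point recombination fraction and LOD for one marker pair.

    Phase is unknown in an outbred family, so the recombinant count is
    minimised over the two possible phase assignments. ``rf_adjusted``
    applies the min-error shrinkage used for map distances.
    """
    t = transmissions(table, parent).loc[[marker_a, marker_b]]
    n_m, k_m, rf_m, lod_m = pairwise_two_point(t)
    n = int(n_m.iloc[0, 1])
    if n == 0:
        return TwoPointResult(marker_a, marker_b, parent, 0, 0, np.nan, np.nan, np.nan)
    k = int(k_m.iloc[0, 1])
    rf = float(rf_m.iloc[0, 1])
    return TwoPointResult(
        marker_a, marker_b, parent, n, k, rf, float(shrink_rf(rf, min_error)), float(lod_m.iloc[0, 1])
    )


# ---------------------------------------------------------------------------
# Clustering


def cluster_lod(lod: pd.DataFrame, lod_limit: float = 20.0):
    """Single-linkage transitive closure over pairs with LOD >= lod_limit.

    Returns (groups, singles): groups is a list of marker-id lists (size >= 2)
    sorted by descending size then smallest member id; singles are the
    remaining markers. The result is invariant to input row order.
    """
    markers = list(lod.index)
    m = np.nan_to_num(lod.to_numpy(), nan=-np.inf)
    np.fill_diagonal(m, -np.inf)
    g = nx.Graph()
    g.add_nodes_from(markers)
    ii, jj = np.nonzero(m >= lod_limit)
    g.add_edges_from((markers[i], markers[j]) for i, j in zip(ii, jj) if i < j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    groups = sorted((c for c in comps if len(c) > 1), key=lambda c: (-len(c), c[0]))
    singles = sorted(c[0] for c in comps if len(c) == 1)
    return groups, singles


def join_singles(
    lod: pd.DataFrame,
    groups: list[list[str]],
    singles: list[str],
    lod_limit: float = 15.0,
):
    """One pass assigning unplaced markers to their best-LOD group.

    A single joins the group holding its maximum best-pair LOD when that LOD
    >= lod_limit; ties break toward the larger group, then the lower group
    index. Membership is evaluated against the initial groups (singles do not
    chain onto each other within the pass).
    """
    new_groups = [list(g) for g in groups]
    remaining = []
    arr = lod.to_numpy()
    pos = {m: i for i, m in enumerate(lod.index)}
    group_rows = [[pos[m] for m in g] for g in groups]
    for s in singles:
        srow = arr[pos[s]]
        best = (-np.inf, 0, 0)  # (lod, size, -gid) maximised
        best_gid = None
        for gid, rows in enumerate(group_rows):
            g_lod = np.nanmax(srow[rows]) if rows else -np.inf
            key = (g_lod, len(rows), -gid)
            if key > best:
                best, best_gid = key, gid
        if best_gid is not None and best[0] >= lod_limit:
            new_groups[best_gid].append(s)
        else:
            remaining.append(s)
    return new_groups, remaining


# ---------------------------------------------------------------------------
# Ordering


def _adjacent_sum(order: list[int], rf: np.ndarray) -> float:
    return float(sum(rf[order[i], order[i + 1]] for i in range(len(order) - 1)))


def order_markers(markers: list[str], rf: pd.DataFrame, polish_iterations: int = 8):
    """Order one linkage group and assign cumulative Haldane positions.

    Greedy nearest-neighbour insertion (seeded with the closest pair, each
    next marker chosen by smallest rf to the placed set and inserted where it
    least increases the sum of adjacent rf), followed by ``polish_iterations``
    sweeps of window-3 2-opt. Positions are cumulative Haldane distances of
    adjacent rf values capped at 0.49; co-segregating markers (rf 0) share a
    position. Orientation is canonicalised so the first marker id precedes the
    last. Missing pairwise rf values are treated as free recombination (0.5).

    Returns (ordered ids, positions in cM).
    """
    if len(markers) == 1:
        return list(markers), np.array([0.0])
    sub = rf.loc[markers, markers].to_numpy(dtype=float)
    missing = np.isnan(sub)
    if missing.any():
        # complete undefined pairs (no shared informative parent) through an
        # intermediate marker: one min-plus pass, capped at free recombination
        a = np.where(missing, np.inf, sub)
        np.fill_diagonal(a, 0.0)
        bridged = np.min(a[:, :, None] + a[None, :, :], axis=1)
        sub = np.where(missing, np.minimum(bridged, 0.5), sub)
    np.fill_diagonal(sub, np.inf)

    n = len(markers)
    i0, j0 = divmod(int(np.argmin(sub)), n)
    order = [i0, j0]
    placed = np.zeros(n, dtype=bool)
    placed[[i0, j0]] = True
    while not placed.all():
        d_to_placed = np.where(placed[None, :], sub, np.inf)[~placed][:, placed].min(axis=1)
        cand = np.flatnonzero(~placed)[int(np.argmin(d_to_placed))]
        best_cost, best_pos = np.inf, 0
        for pos_i in range(len(order) + 1):
            trial = order[:pos_i] + [cand] + order[pos_i:]
            cost = _adjacent_sum(trial, sub)
            if cost < best_cost - 1e-15:
                best_cost, best_pos = cost, pos_i
        order.insert(best_pos, cand)
        placed[cand] = True

    np.fill_diagonal(sub, 0.0)
    from itertools import permutations

    for _ in range(max(0, polish_iterations)):
        improved = False
        for i in range(len(order) - 2):
            window = order[i : i + 3]
            base = order[:i] + order[i + 3 :]
            best_perm, best_cost = tuple(window), _adjacent_sum(order, sub)
            for perm in permutations(window):
                trial = order[:i] + list(perm) + order[i + 3 :]
                cost = _adjacent_sum(trial, sub)
                if cost < best_cost - 1e-12:
                    best_cost, best_perm = cost, perm
            if list(best_perm) != window:
                order[i : i + 3] = list(best_perm)
                improved = True
        if not improved:
            break

    ids = [markers[i] for i in order]
    if ids[0] > ids[-1]:
        ids = ids[::-1]
        order = order[::-1]
    adj = np.array([min(sub[order[i], order[i + 1]], 0.49) for i in range(len(order) - 1)])
    positions = np.concatenate([[0.0], np.cumsum(haldane(adj))])
    return ids, positions


# ---------------------------------------------------------------------------
# Map assembly


_MASKS = {
    PATERNAL: {PATERNAL_ONLY, BOTH},  # Lep-MAP-style informative mask 23
    MATERNAL: {MATERNAL_ONLY, BOTH},  # mask 13
    SEX_AVERAGED: {PATERNAL_ONLY, MATERNAL_ONLY, BOTH},
}


def _variant_pairwise(table: GenotypeTable, variant: str, min_error: float):
    """(markers, rf_adjusted, lod) for one map variant.

    Sex-averaged statistics sum parental LODs and average parental rf values
    weighted by their informative meiosis counts.
    """
    mask = _MASKS[variant]
    cls = table.meta["informativeness"]
    markers = [m for m in table.markers if cls[m] in mask]
    sub = GenotypeTable(
        table.calls.loc[markers], table.father, table.mother, table.meta.loc[markers]
    )
    if variant in (PATERNAL, MATERNAL):
        n, _, rf, lod = pairwise_two_point(transmissions(sub, variant))
        rf_v, lod_v = rf.to_numpy(), lod.to_numpy()
    else:
        n_f, _, rf_f, lod_f = pairwise_two_point(transmissions(sub, PATERNAL))
        n_m, _, rf_m, lod_m = pairwise_two_point(transmissions(sub, MATERNAL))
        nf, nm = n_f.to_numpy(), n_m.to_numpy()
        rf_fv = np.nan_to_num(rf_f.to_numpy() * nf)
        rf_mv = np.nan_to_num(rf_m.to_numpy() * nm)
        tot = nf + nm
        with np.errstate(invalid="ignore"):
            rf_v = np.where(tot > 0, (rf_fv + rf_mv) / np.maximum(tot, 1), np.nan)
        lod_v = lod_f.to_numpy() + lod_m.to_numpy()
    idx = pd.Index(markers)
    return (
        markers,
        pd.DataFrame(shrink_rf(np.clip(rf_v, 0, 0.5), min_error), index=idx, columns=idx),
        pd.DataFrame(lod_v, index=idx, columns=idx),
    )


def separate_groups(
    table: GenotypeTable,
    lod_limit: float = 20.0,
    join_lod: float = 15.0,
    min_error: float = 0.02,
    min_group_size: int = 1,
) -> list[list[str]]:
    """Assign all informative markers to linkage groups.

    Grouping happens once, over every informative marker, on the combined
    two-point LOD (parental LODs summed) — the per-parent informative masks
    apply later, at ordering, so the three map variants share one group
    numbering. Groups come from single-linkage closure at ``lod_limit``
    followed by one join-singles pass at ``join_lod``, and are sorted by
    descending size (ties by smallest member id).

    ``min_group_size`` drops smaller fragments (their markers stay unplaced),
    the usual guard when marker density is low relative to the LOD limit:
    with n meioses the two-point LOD cannot exceed n*log10(2), and links
    through both-informative markers cap at about half that, so sparse maps
    shed small tip fragments rather than false joins.
    """
    _, _, lod = _variant_pairwise(table, SEX_AVERAGED, min_error)
    groups, singles = cluster_lod(lod, lod_limit)
    groups, _ = join_singles(lod, groups, singles, join_lod)
    groups = [g for g in groups if len(g) >= min_group_size]
    return sorted(groups, key=lambda g: (-len(g), sorted(g)[0]))


def build_maps(
    table: GenotypeTable,
    lod_limit: float = 20.0,
    join_lod: float = 15.0,
    polish_iterations: int = 8,
    min_error: float = 0.02,
    variants: tuple[str, ...] = (PATERNAL, MATERNAL, SEX_AVERAGED),
    groups: list[list[str]] | None = None,
    min_group_size: int = 1,
) -> dict[str, LinkageMap]:
    """Build paternal, maternal and sex-averaged linkage maps.

    Linkage groups are separated once over all informative markers
    (:func:`separate_groups`); each map variant then keeps its informative
    mask's markers — paternal: father-heterozygous (paternal-only + both);
    maternal symmetric; sex-averaged: all — and orders them within each group
    using that variant's recombination fractions (father meioses, mother
    meioses, or the meiosis-count-weighted average). Group ids are therefore
    comparable across variants. Pseudo-markers, informative only in the
    father, never appear on the maternal map.
    """
    if "informativeness" not in table.meta.columns:
        table = classify_informativeness(table)
    if groups is None:
        groups = separate_groups(table, lod_limit, join_lod, min_error, min_group_size)
    out: dict[str, LinkageMap] = {}
    for variant in variants:
        markers, rf, _ = _variant_pairwise(table, variant, min_error)
        member = set(markers)
        rows = []
        for gid, group in enumerate(groups, start=1):
            sub = sorted(m for m in group if m in member)
            if not sub:
                continue
            ids, positions = order_markers(sub, rf, polish_iterations)
            for mid, pos in zip(ids, positions):
                rows.append(
                    {
                        "marker_id": mid,
                        "group": gid,
                        "position_cM": float(pos),
                        "informativeness": table.meta.loc[mid, "informativeness"],
                        "pseudo": bool(table.meta.loc[mid, "pseudo"]),
                    }
                )
        tab = pd.DataFrame(rows).set_index("marker_id") if rows else pd.DataFrame(
            columns=["group", "position_cM", "informativeness", "pseudo"]
        )
        out[variant] = LinkageMap(tab, variant=variant)
    return out


# ---------------------------------------------------------------------------
# Known-offspring-sex marker calling


def call_sex_linked_from_known_sex(
    table: GenotypeTable,
    offspring_sexes: pd.Series,
    alpha: float = 1e-6,
) -> pd.DataFrame:
    """Flag markers whose paternal transmission is perfectly sex-concordant.

    For each father-heterozygous marker, the transmitted paternal allele is
    compared with the offspring sexes; a marker is flagged X/Y-linked when
    transmission is perfectly concordant with sex among scorable offspring and
    an exact binomial test of the concordant count against sex-independent
    transmission (p = 0.5) gives p < ``alpha``.
    """
    missing = [o for o in table.offspring if o not in offspring_sexes.index]
    if missing:
        raise ValueError(f"offspring without sex calls: {missing[:5]}")
    t = transmissions(table, PATERNAL)
    is_male = offspring_sexes.loc[t.columns].eq("male").to_numpy()
    rows = []
    for marker in t.index:
        v = t.loc[marker].to_numpy()
        scored = ~np.isnan(v)
        n = int(scored.sum())
        if n == 0:
            rows.append({"marker_id": marker, "n": 0, "concordant": 0, "p_value": 1.0, "flagged": False})
            continue
        conc = int(max(np.sum(v[scored] == is_male[scored]), np.sum(v[scored] == ~is_male[scored])))
        p = float(stats.binomtest(conc, n, 0.5).pvalue)
        rows.append(
            {
                "marker_id": marker,
                "n": n,
                "concordant": conc,
                "p_value": p,
                "flagged": bool(conc == n and p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("marker_id")
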