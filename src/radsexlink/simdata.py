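"""Synthetic RADseq cohorts and full-sib families with an XY system.

The generator emulates the data structures the marker-discovery pipeline
assumes: a genome of several chromosomes with sex-specific genetic lengths,
one sex chromosome carrying a small non-recombining sex-determining region
(sdr) on the male map, Y-restricted presence/absence loci (some with diverged
autosomal paralogs that leak reads into females), negative-binomial read
depth with dropout, a known-sex adult cohort, and a two-parent full-sib
family segregating SNPs of every parental-informativeness class.

Meiosis uses an obligate chiasma (zero-truncated Poisson crossover count per
chromosome), uniform crossover placement in female meiosis and a symmetric
telomere-biased U-shaped placement density in male meiosis, with crossovers
suppressed inside the sdr. Note the obligate chiasma makes short chromosomes
deviate from the Haldane no-interference expectation; the two agree when the
chromosome is much longer than the interval of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FEMALE, MALE, UNKNOWN, DepthMatrix, MarkerCatalog
from .linkmap import GenotypeTable, HET, HOM_ALT, HOM_REF, MISSING

_NUCS = np.array(list("ACGT"))
SEQ_LEN = 300
_FLANK5 = "TGCAGG"  # SbfI-style restriction-site flank
_FLANK3 = "AATTC"


# ---------------------------------------------------------------------------
# Genome and parameters


@dataclass(frozen=True)
class Chromosome:
    id: str
    female_cM: float
    male_cM: float
    length_bp: int


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome set with sex-specific genetic lengths and an sdr interval.

    ``sdr`` is a (start, end) interval in cM on the *male* map of the sex
    chromosome; male recombination between the X and Y haplotypes is
    suppressed inside it.
    """

    chromosomes: tuple[Chromosome, ...]
    sex_chromosome: str
    sdr: tuple[float, float]
    seed: int = 0

    def __post_init__(self):
        ids = [c.id for c in self.chromosomes]
        if self.sex_chromosome not in ids:
            raise ValueError("sex_chromosome not among chromosome ids")
        for c in self.chromosomes:
            if c.female_cM <= 0 or c.male_cM <= 0 or c.length_bp <= 0:
                raise ValueError(f"non-positive length on chromosome {c.id}")
        lo, hi = self.sdr
        sex_len = self.chromosome(self.sex_chromosome).male_cM
        if not (0 <= lo < hi <= sex_len):
            raise ValueError("sdr interval must lie within the sex chromosome's male map")

    def chromosome(self, cid: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def chromosome_ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]


def build_genome(config: dict | None = None) -> GenomeModel:
    """Build a genome model from a configuration dictionary.

    Defaults: 12 chromosomes with graded sizes, total female map 1688 cM and
    male map 1300 cM, the 5th chromosome as the sex chromosome with a 2 cM
    sdr at one telomeric end of its male map. Deterministic for a given
    config (the seed only labels downstream simulations).
    """
    cfg = {
        "n_chromosomes": 12,
        "female_total_cM": 1688.0,
        "male_total_cM": 1300.0,
        "chromosome_bp": 1_500_000_000,
        "sex_chromosome_index": 4,
        "sdr_width_cM": 2.0,
        "seed": 0,
    }
    cfg.update(config or {})
    n = int(cfg["n_chromosomes"])
    if n < 1:
        raise ValueError("need at least one chromosome")
    if cfg["female_total_cM"] <= 0 or cfg["male_total_cM"] <= 0 or cfg["chromosome_bp"] <= 0:
        raise ValueError("genome lengths must be positive")
    # graded relative sizes, largest first, mirroring a real karyotype
    weights = np.linspace(1.3, 0.7, n) if n > 1 else np.array([1.0])
    weights = weights / weights.sum()
    chroms = tuple(
        Chromosome(
            id=f"chr{i + 1:02d}",
            female_cM=float(cfg["female_total_cM"] * w),
            male_cM=float(cfg["male_total_cM"] * w),
            length_bp=int(cfg["chromosome_bp"]),
        )
        for i, w in enumerate(weights)
    )
    sex_id = chroms[min(int(cfg["sex_chromosome_index"]), n - 1)].id
    male_len = next(c.male_cM for c in chroms if c.id == sex_id)
    width = float(cfg["sdr_width_cM"])
    if not 0 < width <= male_len:
        raise ValueError("sdr width must be positive and fit on the sex chromosome")
    return GenomeModel(chroms, sex_id, (male_len - width, male_len), seed=int(cfg["seed"]))


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults mirror the study design being emulated
    (30+30 known-sex adults, 146 offspring, mean read depth 28)."""

    n_males: int = 30
    n_females: int = 30
    n_offspring: int = 146
    n_loci: int = 1200
    n_y_loci: int = 32
    paralog_fraction: float = 0.25
    paralog_divergence: float = 0.05
    depth_mean: float = 28.0
    depth_dispersion: float = 12.0
    dropout_prob: float = 0.02
    female_residual_prob: float = 0.3
    genotype_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in (
            "paralog_fraction",
            "paralog_divergence",
            "dropout_prob",
            "female_residual_prob",
            "genotype_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.n_offspring < 2:
            raise ValueError("n_offspring must be >= 2")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_y_loci > self.n_loci:
            raise ValueError("n_y_loci cannot exceed n_loci")


@dataclass
class TruthTable:
    """Simulator ground truth, one row per locus.

    Columns: chrom, pos_female_cM (NaN for Y-restricted loci), pos_male_cM,
    y_linked, paralog_family (NaN when none), seq_id.
    """

    table: pd.DataFrame

    @property
    def y_loci(self) -> list[str]:
        return list(self.table.index[self.table["y_linked"]])

    def loci_on(self, chrom: str) -> list[str]:
        return list(self.table.index[self.table["chrom"] == chrom])


# ---------------------------------------------------------------------------
# Locus placement


def _random_seq(rng: np.random.Generator, core_len: int) -> str:
    return _FLANK5 + "".join(rng.choice(_NUCS, size=core_len)) + _FLANK3


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = np.array(list(seq))
    hit = rng.random(len(out)) < rate
    for i in np.flatnonzero(hit):
        out[i] = rng.choice(_NUCS[_NUCS != out[i]])
    return "".join(out)


def place_loci(genome: GenomeModel, params: SimParams, rng=None):
    """Place loci uniformly on the genetic maps and draw their sequences.

    ``params.n_loci`` loci are placed with chromosome choice proportional to
    sex-averaged genetic length; ``params.n_y_loci`` of them are Y-restricted
    and placed inside the sdr on the male map. A ``paralog_fraction`` of the
    Y loci found a paralog family: each gains one additional autosomal copy
    locus whose sequence diverges by ``paralog_divergence`` per base.

    Returns (MarkerCatalog, TruthTable).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    core = SEQ_LEN - len(_FLANK5) - len(_FLANK3)
    n_auto = params.n_loci - params.n_y_loci
    weights = np.array([(c.female_cM + c.male_cM) / 2 for c in genome.chromosomes])
    weights = weights / weights.sum()
    records, seqs = [], {}

    chrom_pick = rng.choice(len(genome.chromosomes), size=n_auto, p=weights)
    u = rng.random(n_auto)
    for i in range(n_auto):
        c = genome.chromosomes[chrom_pick[i]]
        lid = f"L{i:06d}"
        pf = u[i] * c.female_cM
        records.append(
            {
                "locus": lid,
                "chrom": c.id,
                "pos_female_cM": pf,
                "pos_male_cM": pf * c.male_cM / c.female_cM,
                "y_linked": False,
                "paralog_family": np.nan,
                "seq_id": lid,
            }
        )
        seqs[lid] = _random_seq(rng, core)

    sdr_lo, sdr_hi = genome.sdr
    y_pos = sdr_lo + rng.random(params.n_y_loci) * (sdr_hi - sdr_lo)
    y_ids = []
    for j in range(params.n_y_loci):
        lid = f"Y{j:06d}"
        y_ids.append(lid)
        records.append(
            {
                "locus": lid,
                "chrom": genome.sex_chromosome,
                "pos_female_cM": np.nan,
                "pos_male_cM": float(y_pos[j]),
                "y_linked": True,
                "paralog_family": np.nan,
                "seq_id": lid,
            }
        )
        seqs[lid] = _random_seq(rng, core)

    truth = pd.DataFrame(records).set_index("locus")
    n_para = int(np.floor(params.paralog_fraction * params.n_y_loci))
    para_members = rng.choice(y_ids, size=n_para, replace=False) if n_para else []
    autosomes = [c for c in genome.chromosomes if c.id != genome.sex_chromosome] or list(
        genome.chromosomes
    )
    extra = []
    for fam, yid in enumerate(sorted(para_members)):
        truth.loc[yid, "paralog_family"] = fam
        c = autosomes[int(rng.integers(len(autosomes)))]
        pf = float(rng.random() * c.female_cM)
        cid = f"P{fam:06d}"
        extra.append(
            {
                "locus": cid,
                "chrom": c.id,
                "pos_female_cM": pf,
                "pos_male_cM": pf * c.male_cM / c.female_cM,
                "y_linked": False,
                "paralog_family": fam,
                "seq_id": cid,
            }
        )
        seqs[cid] = _mutate(seqs[yid], params.paralog_divergence, rng)
    if extra:
        truth = pd.concat([truth, pd.DataFrame(extra).set_index("locus")])
    return MarkerCatalog(seqs), TruthTable(truth)


# ---------------------------------------------------------------------------
# Meiosis


def _ztp_lambda(target_mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean.

    Solves lam / (1 - exp(-lam)) = target_mean so that the obligate-chiasma
    draw still realises the nominal genetic length (an uncalibrated truncated
    Poisson would inflate every map distance). The truncated mean cannot fall
    below 1; for targets <= 1 the limit lam -> 0 (exactly one crossover) is
    returned as 0.0.
    """
    if target_mean <= 1.0:
        return 0.0
    from scipy.optimize import brentq

    return float(brentq(lambda lam: lam / -np.expm1(-lam) - target_mean, 1e-9, 2 * target_mean))


def crossover_positions(
    chrom: Chromosome, parent_sex: str, genome: GenomeModel, rng: np.random.Generator
) -> np.ndarray:
    """Crossover positions (cM, on the parent-sex map) for one meiosis.

    Count is zero-truncated Poisson(length/100) (obligate chiasma). Female
    positions are uniform; male positions follow a symmetric U-shaped
    telomere-biased mixture of Beta(1, 8) densities at the two chromosome
    ends. In male meiosis on the sex chromosome, positions falling inside the
    sdr are redrawn (suppressed X-Y recombination).
    """
    length = chrom.male_cM if parent_sex == MALE else chrom.female_cM
    lam = _ztp_lambda(length / 100.0)
    if lam == 0.0:
        k = 1  # obligate-chiasma floor: one crossover, realised length 100 cM
    else:
        k = 0
        while k == 0:
            k = int(rng.poisson(lam))

    def draw(size: int) -> np.ndarray:
        if parent_sex == FEMALE:
            return rng.random(size) * length
        b = rng.beta(1.0, 8.0, size=size)
        flip = rng.random(size) < 0.5
        return np.where(flip, b, 1.0 - b) * length

    pos = draw(k)
    if parent_sex == MALE and chrom.id == genome.sex_chromosome:
        lo, hi = genome.sdr
        bad = (pos >= lo) & (pos < hi)
        while bad.any():
            pos[bad] = draw(int(bad.sum()))
            bad = (pos >= lo) & (pos < hi)
    return np.sort(pos)


def simulate_meiosis(
    parent_haplotypes: dict[str, np.ndarray],
    positions: dict[str, np.ndarray],
    parent_sex: str,
    genome: GenomeModel,
    rng: np.random.Generator,
):
    """One gamete from a phased parent.

    ``parent_haplotypes[chrom]`` is a (2, n_loci) allele array and
    ``positions[chrom]`` the locus positions (cM) on the parent-sex map of
    that chromosome. Returns (alleles, origins) dicts; ``origins[chrom]`` is
    the 0/1 haplotype of origin at each locus, always a legal mosaic of the
    two input haplotypes.
    """
    alleles: dict[str, np.ndarray] = {}
    origins: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        haps = parent_haplotypes.get(chrom.id)
        if haps is None:
            continue
        pos = positions[chrom.id]
        xo = crossover_positions(chrom, parent_sex, genome, rng)
        start = int(rng.integers(2))
        origin = (start + np.searchsorted(xo, pos, side="right")) % 2
        origins[chrom.id] = origin
        alleles[chrom.id] = haps[origin, np.arange(haps.shape[1])]
    return alleles, origins


# ---------------------------------------------------------------------------
# Depth helpers


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# Known-sex cohort


def simulate_known_sex_cohort(
    genome: GenomeModel, catalog: MarkerCatalog, truth: TruthTable, params: SimParams, rng=None
) -> DepthMatrix:
    """Read-depth matrix for a known-sex adult cohort.

    Autosomal/X loci receive negative-binomial reads in every sample subject
    to dropout. Y-restricted loci receive reads only in males, except members
    of paralog families, which also receive (quarter-depth) residual reads in
    each female with probability ``female_residual_prob`` — cross-mapping
    from the diverged autosomal copy.
    """
    if params.n_males + params.n_females == 0:
        raise ValueError("cohort needs at least one sample")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    males = [f"M{i + 1:02d}" for i in range(params.n_males)]
    females = [f"F{i + 1:02d}" for i in range(params.n_females)]
    samples = males + females
    loci = list(truth.table.index)
    n_l, n_s = len(loci), len(samples)

    counts = _nb_depth(rng, params.depth_mean, params.depth_dispersion, (n_l, n_s))
    counts[rng.random((n_l, n_s)) < params.dropout_prob] = 0

    y_mask = truth.table["y_linked"].to_numpy()
    female_cols = np.arange(params.n_males, n_s)
    counts[np.ix_(y_mask, female_cols)] = 0
    leaky = y_mask & truth.table["paralog_family"].notna().to_numpy()
    if leaky.any() and params.n_females:
        leak = rng.random((int(leaky.sum()), params.n_females)) < params.female_residual_prob
        residual = _nb_depth(
            rng, params.depth_mean / 4.0, params.depth_dispersion, leak.shape
        )
        block = counts[np.ix_(leaky, female_cols)]
        block[leak] = residual[leak]
        counts[np.ix_(leaky, female_cols)] = block

    sexes = pd.Series({**{m: MALE for m in males}, **{f: FEMALE for f in females}})
    return DepthMatrix(pd.DataFrame(counts, index=loci, columns=samples), sexes)


# ---------------------------------------------------------------------------
# Full-sib family


@dataclass
class FamilySim:
    """A simulated full-sib family: SNP genotypes, Y-locus depths, truth."""

    genotypes: GenotypeTable
    y_depth: DepthMatrix
    offspring_sex: pd.Series
    snp_truth: pd.DataFrame = field(repr=False, default=None)


# Outbred wild-caught parents: single-parent heterozygosity dominates (a SNP
# heterozygous in both parents needs intermediate population allele frequency)
_CLASS_PROBS = {"paternal-only": 0.35, "maternal-only": 0.35, "both": 0.2, "uninformative": 0.1}


def _draw_parent_genotypes(rng: np.random.Generator, n: int):
    """Phased parental genotypes for n SNPs with the stated class mix.

    Returns (father_hap (n,2), mother_hap (n,2), class labels). Alleles are
    0/1; heterozygous parents get a random phase.
    """
    labels = list(_CLASS_PROBS)
    cls = rng.choice(len(labels), size=n, p=list(_CLASS_PROBS.values()))
    fa = np.zeros((n, 2), dtype=np.int8)
    mo = np.zeros((n, 2), dtype=np.int8)
    for i, c in enumerate(cls):
        label = labels[c]
        f_het = label in ("paternal-only", "both")
        m_het = label in ("maternal-only", "both")
        if f_het:
            fa[i] = [0, 1] if rng.random() < 0.5 else [1, 0]
        else:
            fa[i] = rng.integers(2) * np.array([1, 1])
        if m_het:
            mo[i] = [0, 1] if rng.random() < 0.5 else [1, 0]
        else:
            mo[i] = rng.integers(2) * np.array([1, 1])
    return fa, mo, np.array([labels[c] for c in cls], dtype=object)


def simulate_family(
    genome: GenomeModel, catalog: MarkerCatalog, truth: TruthTable, params: SimParams, rng=None
) -> FamilySim:
    """Simulate an XY-father full-sib family.

    Each non-Y locus carries 1-3 SNPs (1 + Poisson(0.7), capped) whose phased
    parental genotypes are drawn so that paternal-only, maternal-only,
    both-informative and uninformative SNPs all occur. Offspring are produced
    by :func:`simulate_meiosis` from each parent; offspring sex is the
    presence of the father's Y haplotype at the sdr. Y-restricted loci are
    reported in a 148-sample depth matrix (reads iff the Y haplotype was
    inherited, plus the father; never the mother). Offspring SNP calls are
    corrupted at ``genotype_error_rate`` and dropped out at ``dropout_prob``;
    parental calls stay intact so informativeness classes remain exact.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    offspring = [f"offspring_{i + 1:03d}" for i in range(params.n_offspring)]
    samples = ["father", "mother"] + offspring

    tt = truth.table
    snp_loci = list(tt.index[~tt["y_linked"]])
    y_loci = list(tt.index[tt["y_linked"]])

    n_snps_per_locus = 1 + np.minimum(rng.poisson(0.7, size=len(snp_loci)), 2)
    marker_ids, locus_of, chrom_of = [], [], []
    pos_f, pos_m = [], []
    for lid, k in zip(snp_loci, n_snps_per_locus):
        for j in range(int(k)):
            marker_ids.append(f"{lid}:{j + 1}")
            locus_of.append(lid)
            chrom_of.append(tt.loc[lid, "chrom"])
            pos_f.append(tt.loc[lid, "pos_female_cM"])
            pos_m.append(tt.loc[lid, "pos_male_cM"])
    n_m = len(marker_ids)
    chrom_of = np.array(chrom_of)
    pos_f = np.array(pos_f, dtype=float)
    pos_m = np.array(pos_m, dtype=float)

    fa_hap, mo_hap, snp_class = _draw_parent_genotypes(rng, n_m)

    # assemble per-chromosome haplotype/position blocks, father carries the
    # Y loci on haplotype index 1 of the sex chromosome
    y_pos = tt.loc[y_loci, "pos_male_cM"].to_numpy(dtype=float)
    sdr_mid = (genome.sdr[0] + genome.sdr[1]) / 2.0
    father_haps, father_pos, mother_haps, mother_pos = {}, {}, {}, {}
    f_index: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        rows = np.flatnonzero(chrom_of == chrom.id)
        f_index[chrom.id] = rows
        fpos = pos_m[rows]
        mpos = pos_f[rows]
        if chrom.id == genome.sex_chromosome:
            # append Y presence loci and the sex-determining locus sentinel
            father_pos[chrom.id] = np.concatenate([fpos, y_pos, [sdr_mid]])
            hap = np.zeros((2, len(rows) + len(y_loci) + 1), dtype=np.int8)
            hap[:, : len(rows)] = fa_hap[rows].T
            hap[1, len(rows) :] = 1  # Y haplotype carries presence loci + SD locus
            father_haps[chrom.id] = hap
        else:
            father_pos[chrom.id] = fpos
            father_haps[chrom.id] = fa_hap[rows].T.copy()
        mother_pos[chrom.id] = mpos
        mother_haps[chrom.id] = mo_hap[rows].T.copy()

    calls = np.empty((n_m, len(samples)), dtype=np.int8)
    calls[:, 0] = fa_hap.sum(axis=1)
    calls[:, 1] = mo_hap.sum(axis=1)
    y_present = np.zeros((len(y_loci), len(samples)), dtype=bool)
    y_present[:, 0] = True  # father
    sex = {}
    sexchrom = genome.sex_chromosome
    for oi, name in enumerate(offspring):
        pat, pat_origin = simulate_meiosis(father_haps, father_pos, MALE, genome, rng)
        mat, _ = simulate_meiosis(mother_haps, mother_pos, FEMALE, genome, rng)
        geno = np.empty(n_m, dtype=np.int8)
        for chrom in genome.chromosomes:
            rows = f_index[chrom.id]
            if chrom.id == sexchrom:
                geno[rows] = pat[chrom.id][: len(rows)] + mat[chrom.id]
                y_present[:, 2 + oi] = pat[chrom.id][len(rows) : len(rows) + len(y_loci)] == 1
                sex[name] = MALE if pat[chrom.id][-1] == 1 else FEMALE
            else:
                geno[rows] = pat[chrom.id] + mat[chrom.id]
        calls[:, 2 + oi] = geno

    # genotype errors and dropout, offspring columns only
    if params.genotype_error_rate > 0:
        err = rng.random((n_m, len(offspring))) < params.genotype_error_rate
        shift = rng.integers(1, 3, size=err.shape)
        block = calls[:, 2:]
        block[err] = (block[err] + shift[err]) % 3
        calls[:, 2:] = block
    if params.dropout_prob > 0:
        drop = rng.random((n_m, len(offspring))) < params.dropout_prob
        block = calls[:, 2:]
        block[drop] = MISSING
        calls[:, 2:] = block

    depths = _nb_depth(rng, params.depth_mean, params.depth_dispersion, (n_m, len(samples)))
    depths[:, 2:][calls[:, 2:] == MISSING] = 0

    calls_df = pd.DataFrame(calls, index=pd.Index(marker_ids, name="marker_id"), columns=samples)
    meta = pd.DataFrame(
        {
            "locus": locus_of,
            "pseudo": False,
            "mean_depth": depths.mean(axis=1),
            "chrom": chrom_of,
        },
        index=calls_df.index,
    )
    snp_truth = pd.DataFrame(
        {"locus": locus_of, "snp_class": snp_class, "chrom": chrom_of},
        index=calls_df.index,
    )
    genotypes = GenotypeTable(
        calls_df,
        "father",
        "mother",
        meta,
        depths=pd.DataFrame(depths, index=calls_df.index, columns=samples),
    )

    y_counts = _nb_depth(rng, params.depth_mean, params.depth_dispersion, y_present.shape)
    y_counts[~y_present] = 0
    if params.dropout_prob > 0:
        y_counts[rng.random(y_present.shape) < params.dropout_prob] = 0
    sexes = pd.Series(
        {"father": MALE, "mother": FEMALE, **{o: UNKNOWN for o in offspring}}
    )
    y_depth = DepthMatrix(
        pd.DataFrame(y_counts, index=pd.Index(y_loci, name="locus"), columns=samples), sexes
    )
    return FamilySim(genotypes, y_depth, pd.Series(sex), snp_truth)


# ---------------------------------------------------------------------------
# Published-scale stand-in map


def synthetic_published_scale_map(n_markers: int = 10763, seed: int = 0):
    """Synthetic linkage map at the scale of the study's sex-averaged map.

    This is a *synthetic stand-in*, not the deposited map: 12 groups with
    odd-integer lengths summing to 1366 cM (so 2 cM ceiling-binning yields
    689 bins) and ``n_markers`` markers placed deterministically along the
    groups, proportional to length. It exists so binning and density
    conventions can be exercised at the published scale without the
    supplementary data file.
    """
    from .linkmap import LinkageMap, SEX_AVERAGED

    bins_per_group = [75, 70, 66, 63, 60, 58, 56, 55, 54, 50, 45, 37]
    lengths = [2 * b - 1 for b in bins_per_group]  # odd lengths: sum 1366, ceil-bins 689
    rng = np.random.default_rng(seed)
    share = np.array(lengths, dtype=float) / sum(lengths)
    counts = np.floor(share * n_markers).astype(int)
    counts[: n_markers - counts.sum()] += 1
    rows = []
    m = 0
    for gid, (length, cnt) in enumerate(zip(lengths, counts), start=1):
        pos = np.sort(rng.random(cnt)) * length
        pos[0], pos[-1] = 0.0, float(length)  # anchor the group ends
        for p in pos:
            rows.append(
                {
                    "marker_id": f"S{m:06d}",
                    "group": gid,
                    "position_cM": float(p),
                    "informativeness": "both",
                    "pseudo": False,
                }
            )
            m += 1
    return LinkageMap(pd.DataFrame(rows).set_index("marker_id"), variant=SEX_AVERAGED)
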