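"""Pseudo-SNP encoding of presence/absence markers and offspring sex calling.

A Y-restricted marker is invisible to linkage software: absent (missing) in
females, apparently homozygous in males. Encoding presence/absence as an
artificial biallelic genotype — AA when a sample has no reads, AT when it has
reads — makes the X-chromosome "absence" allele visible, so the marker can be
mapped like any other heterozygous-father SNP. In an XY family the expected
minor allele frequency of such pseudo-markers is 0.25 (the father plus about
half the offspring carry T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DepthMatrix
from .linkmap import GenotypeTable, HET, HOM_REF

ABSENT = "AA"
PRESENT = "AT"


@dataclass
class PseudoGenotypeBlock:
    """Per-sample AA/AT calls for a set of presence/absence loci."""

    calls: pd.DataFrame  # loci x samples, values 'AA' | 'AT'
    provenance: str = "pseudo"

    @property
    def loci(self) -> pd.Index:
        return self.calls.index

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def minor_allele_frequencies(self) -> pd.Series:
        """Per-locus minor allele frequency of the artificial T allele,
        computed over all samples (parents included)."""
        t_count = (self.calls == PRESENT).sum(axis=1)
        freq = t_count / (2.0 * self.calls.shape[1])
        return np.minimum(freq, 1.0 - freq)


def encode_presence_absence(
    depth: DepthMatrix, loci=None, presence_min_reads: int = 1
) -> PseudoGenotypeBlock:
    """AA/AT encoding of read presence for the given loci.

    A sample is AT iff its read count is >= ``presence_min_reads``, AA
    otherwise; no missing calls are emitted. Encoding is idempotent in the
    depth matrix and monotone: adding reads can only flip AA -> AT.
    """
    loci = list(depth.loci) if loci is None else list(loci)
    unknown = [l for l in loci if l not in depth.loci]
    if unknown:
        raise KeyError(f"loci absent from depth matrix: {unknown[:5]}")
    present = depth.counts.loc[loci].to_numpy() >= presence_min_reads
    calls = pd.DataFrame(
        np.where(present, PRESENT, ABSENT),
        index=pd.Index(loci, name="locus"),
        columns=depth.counts.columns,
    ).astype(object)
    return PseudoGenotypeBlock(calls)


def merge_calls(genotypes: GenotypeTable, pseudo: PseudoGenotypeBlock) -> GenotypeTable:
    """Append pseudo-marker rows to a family genotype table.

    Pseudo rows are flagged ``pseudo=True`` in the metadata and coded like
    ordinary biallelic calls (AA -> hom-ref, AT -> het); original rows are
    unchanged. Sample sets must match exactly.
    """
    missing = [s for s in genotypes.samples if s not in pseudo.calls.columns]
    extra = [s for s in pseudo.calls.columns if s not in genotypes.samples]
    if missing or extra:
        raise ValueError(
            f"sample mismatch between genotype table and pseudo block: "
            f"missing={missing[:5]} extra={extra[:5]}"
        )
    if len(pseudo.loci) == 0:
        return genotypes
    coded = pd.DataFrame(
        np.where(pseudo.calls[genotypes.samples].to_numpy() == PRESENT, HET, HOM_REF).astype(np.int8),
        index=pseudo.loci,
        columns=genotypes.samples,
    )
    calls = pd.concat([genotypes.calls, coded])
    meta_new = pd.DataFrame(
        {"locus": list(pseudo.loci), "pseudo": True}, index=pseudo.loci
    )
    meta = pd.concat([genotypes.meta, meta_new])
    return GenotypeTable(calls, genotypes.father, genotypes.mother, meta,
                         depths=genotypes.depths, snp_table=genotypes.snp_table)


def split_pseudo(table: GenotypeTable) -> tuple[GenotypeTable, PseudoGenotypeBlock]:
    """Inverse of :func:`merge_calls`: split a merged table back into the
    SNP-only table and the pseudo block."""
    is_pseudo = table.meta["pseudo"].astype(bool)
    snp = GenotypeTable(
        table.calls[~is_pseudo.to_numpy()],
        table.father,
        table.mother,
        table.meta[~is_pseudo.to_numpy()],
        depths=table.depths,
        snp_table=table.snp_table,
    )
    coded = table.calls[is_pseudo.to_numpy()]
    block = PseudoGenotypeBlock(
        pd.DataFrame(
            np.where(coded.to_numpy() == HET, PRESENT, ABSENT),
            index=coded.index,
            columns=coded.columns,
        ).astype(object)
    )
    return snp, block


def call_offspring_sex(
    depth: DepthMatrix,
    y_loci,
    male_fraction_min: float = 0.5,
    presence_min_reads: int = 1,
    uncertainty_band: tuple[float, float] | None = None,
    samples=None,
) -> pd.Series:
    """Call sex from the presence of Y-restricted markers.

    A sample is called male iff the fraction of Y loci with reads is
    >= ``male_fraction_min``. With ``uncertainty_band=(lo, hi)``, fractions
    inside [lo, hi) are called 'unknown' instead — a guard against dropout.
    """
    y_loci = list(y_loci)
    if not y_loci:
        raise ValueError("sex calling requires at least one Y locus")
    cols = list(samples) if samples is not None else list(depth.samples)
    frac = (depth.counts.loc[y_loci, cols] >= presence_min_reads).mean(axis=0)
    calls = pd.Series(np.where(frac >= male_fraction_min, "male", "female"), index=cols)
    if uncertainty_band is not None:
        lo, hi = uncertainty_band
        calls[(frac >= lo) & (frac < hi)] = "unknown"
    return calls
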