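"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: depth TSV (rows = locus, columns = ``sample:sex``), FASTA marker
catalogues (Biopython), VCF v4.2 family genotypes (written directly, read
back through cyvcf2 in :func:`radsexlink.linkmap.filter_variants`), linkage
map TSV (marker_id, group, position_cM, informativeness, pseudo — the layout
of published map tables, so deposited maps parse with the same reader),
BLAST tabular outfmt-6, and a JSON truth table for simulations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DepthMatrix, MarkerCatalog
from .linkmap import GenotypeTable, HET, HOM_ALT, HOM_REF, LinkageMap, MISSING
from .simdata import TruthTable

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# Depth matrix TSV


def write_depth_tsv(depth: DepthMatrix, path) -> None:
    df = depth.counts.copy()
    df.columns = [f"{s}:{depth.sexes[s]}" for s in df.columns]
    df.to_csv(path, sep="\t", index_label="locus")


def read_depth_tsv(path) -> DepthMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus")
    samples, sexes = [], {}
    for col in df.columns:
        name, _, sex = col.rpartition(":")
        samples.append(name)
        sexes[name] = sex
    df.columns = samples
    return DepthMatrix(df, pd.Series(sexes))


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(catalog: MarkerCatalog, path) -> None:
    records = [SeqRecord(Seq(seq), id=lid, description="") for lid, seq in catalog.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> MarkerCatalog:
    return MarkerCatalog({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


# ---------------------------------------------------------------------------
# VCF


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_family_vcf(table: GenotypeTable, path, ref: str = "A", alt: str = "C") -> None:
    """Write a family genotype table as VCF v4.2.

    One record per marker; CHROM is the RAD locus id and POS the SNP's index
    within its locus, the layout of Stacks-style catalogues. Pseudo-markers
    get REF=A ALT=T and the INFO flag ``PSEUDO=1``. FORMAT is GT:DP (DP 0
    when no per-cell depths are attached).
    """
    samples = table.samples
    depths = table.depths
    pos_counter: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for locus in dict.fromkeys(table.meta["locus"]):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write('##INFO=<ID=PSEUDO,Number=0,Type=Flag,Description="Presence/absence pseudo-SNP">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for marker in table.markers:
            locus = table.meta.loc[marker, "locus"]
            pseudo = bool(table.meta.loc[marker, "pseudo"])
            pos_counter[locus] = pos_counter.get(locus, 0) + 1
            r, a = ("A", "T") if pseudo else (ref, alt)
            info = "PSEUDO=1" if pseudo else "."
            codes = table.calls.loc[marker]
            if depths is not None and marker in depths.index:
                dp = depths.loc[marker]
                cells = [f"{_GT_STRINGS[int(codes[s])]}:{int(dp[s])}" for s in samples]
            else:
                cells = [f"{_GT_STRINGS[int(codes[s])]}:0" for s in samples]
            fh.write(
                f"{locus}\t{pos_counter[locus]}\t{marker}\t{r}\t{a}\t.\tPASS\t{info}\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Linkage map TSV


def write_map_tsv(lmap: LinkageMap, path) -> None:
    out = lmap.table.copy()
    out["pseudo"] = out["pseudo"].astype(int)
    out.to_csv(path, sep="\t", index_label="marker_id")


def read_map_tsv(path, variant: str = "sex-averaged") -> LinkageMap:
    df = pd.read_csv(path, sep="\t", index_col="marker_id")
    df["pseudo"] = df["pseudo"].astype(bool)
    return LinkageMap(df, variant=variant)


# ---------------------------------------------------------------------------
# BLAST outfmt-6


def read_blast_tab(path, query_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Read BLAST tabular output (``-outfmt 6`` default columns).

    When ``query_lengths`` is given, a ``qcovs`` percent query-coverage
    column is derived from qstart/qend and the query length.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS, comment="#")
    if query_lengths is not None:
        span = (df["qend"] - df["qstart"]).abs() + 1
        qlen = df["qseqid"].map(query_lengths)
        df["qcovs"] = 100.0 * span / qlen
    return df


def write_blast_tab(df: pd.DataFrame, path) -> None:
    df[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Truth table JSON


def write_truth_json(truth: TruthTable, path) -> None:
    payload = truth.table.reset_index().replace({np.nan: None}).to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> TruthTable:
    records = json.loads(Path(path).read_text())
    df = pd.DataFrame(records).set_index("locus")
    df["paralog_family"] = df["paralog_family"].astype(float)
    df["pos_female_cM"] = df["pos_female_cM"].astype(float)
    return TruthTable(df)
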