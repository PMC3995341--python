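"""Readers and writers for the pipeline's on-disk formats.

Tabular data is tab-separated with a header line throughout. Genomic SNP
lists travel as minimal VCF (CHROM/POS/REF/ALT; read and written through
pysam) and gene models as GFF3 exon features grouped by their ``Parent``
attribute (read through gffutils).
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
import pysam

from .diagnostics import BASES

__all__ = [
    "read_site_counts",
    "write_site_counts",
    "read_gene_counts",
    "write_gene_counts",
    "read_vcf_snps",
    "write_vcf_snps",
    "read_gff3_exons",
    "write_gff3_genes",
    "read_term_map",
]

_SITE_COLS = ["chrom", "pos", "ref", *BASES]


def read_site_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a pileup-summary table (chrom, pos, ref, A, C, G, T)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "pos": int, "ref": str, **{b: int for b in BASES}},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed site table {path}: {exc}") from exc
    missing = set(_SITE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns {sorted(missing)}")
    return df[_SITE_COLS]


def write_site_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[_SITE_COLS].to_csv(path, sep="\t", index=False)


def read_gene_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read the long per-gene allele count table (gene_id, sample, n_count, i_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample": str})
    missing = {"gene_id", "sample", "n_count", "i_count"} - set(df.columns)
    if missing:
        raise ValueError(f"gene count table {path} missing columns {sorted(missing)}")
    return df


def write_gene_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["gene_id", "sample", "n_count", "i_count"]].to_csv(path, sep="\t", index=False)


def write_vcf_snps(snps: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a (chrom, pos, ref, alt) table as a minimal uncompressed VCF."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(snps["chrom"]):
        header.contigs.add(str(chrom))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in snps.itertuples(index=False):
            rec = vf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,  # pysam is 0-based
                alleles=(str(row.ref), str(row.alt)),
            )
            vf.write(rec)


def read_vcf_snps(path: str | os.PathLike) -> pd.DataFrame:
    """Read a VCF into a (chrom, pos, ref, alt) table (pos 1-based).

    Multi-allelic records contribute one row per alternative allele; non-SNP
    alleles (indels) are skipped.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    rows.append((rec.contig, rec.pos, rec.ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_gff3_genes(gene_models: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write (gene_id, chrom, start, end) intervals as gene + exon GFF3 features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in gene_models.itertuples(index=False):
            base = f"{row.chrom}\thomeobias\t"
            tail = f"\t{row.start}\t{row.end}\t.\t+\t.\t"
            fh.write(f"{base}gene{tail}ID={row.gene_id}\n")
            fh.write(f"{base}exon{tail}ID={row.gene_id}.exon1;Parent={row.gene_id}\n")


def read_gff3_exons(path: str | os.PathLike) -> pd.DataFrame:
    """Read exon intervals grouped by gene from a GFF3 file.

    Exon features are attributed to their ``Parent`` (resolved through one
    level of nesting if the parent is an mRNA). Returns ``gene_id, chrom,
    start, end`` with 1-based inclusive coordinates.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            continue
        parent_id = parents[0]
        try:
            parent = db[parent_id]
            if parent.featuretype != "gene" and parent.attributes.get("Parent"):
                parent_id = parent.attributes["Parent"][0]
        except gffutils.FeatureNotFoundError:
            pass
        rows.append((parent_id, exon.seqid, exon.start, exon.end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def read_term_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a term -> genes annotation (TSV: term, gene_id; one pair per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"term", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns {sorted(missing)}")
    return {term: set(sub["gene_id"]) for term, sub in df.groupby("term")}
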