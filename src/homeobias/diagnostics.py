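"""Homoeolog-diagnostic SNP selection and per-gene allele counting.

The two parental genomes (Nipponbare, the reference, and 93-11) differ at
many transcribed sites. A site is *diagnostic* when reads carrying the
reference base can be attributed to the Nipponbare homoeolog and reads
carrying the alternative base to the 93-11 homoeolog. Selection combines
three evidence sources:

1. sites where the 93-11 RNA-seq pileup is nearly fixed for the alternative
   base (depth > 10 and alt fraction > 0.95);
2. a genomic DNA SNP list between the two parental genomes (the site must be
   a known genomic difference, not an RNA artifact);
3. an exclusion list of sites where the Nipponbare RNA-seq pileup itself
   shows the alternative base above background (depth > 10, alt fraction
   > 5%), which would make the base non-diagnostic (residual heterozygosity,
   paralogy, or mapping error).

The diagnostic set is ``(1 ∩ 2) \\ 3``, keyed by (chrom, pos, alt base).

Site tables are pileup summaries: one row per site with per-base read counts
(columns ``chrom, pos, ref, A, C, G, T``; ``pos`` 1-based). The alternative
base at a site is the most frequent non-reference base.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: closed set of sample labels used across the pipeline
SAMPLES = ("parent_N", "parent_9", "in_silico", "N9", "9N", "NN99", "99NN")

__all__ = [
    "BASES",
    "SAMPLES",
    "site_key_set",
    "select_indica_rna_snps",
    "select_nipponbare_exclusion_snps",
    "derive_diagnostic_snps",
    "assign_snps_to_genes",
    "count_gene_alleles",
    "build_in_silico_hybrid",
    "filter_testable_genes",
]


def _with_alt(sites: pd.DataFrame) -> pd.DataFrame:
    """Annotate a pileup-summary table with depth, alt base and alt count."""
    required = {"chrom", "pos", "ref"} | set(BASES)
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    df = sites.copy()
    counts = df[list(BASES)].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative base counts in site table")
    df["depth"] = counts.sum(axis=1)
    # mask out the reference base, then take the most frequent remaining base
    base_idx = {b: j for j, b in enumerate(BASES)}
    ref_idx = df["ref"].map(base_idx)
    if ref_idx.isna().any():
        bad = df.loc[ref_idx.isna(), "ref"].unique()
        raise ValueError(f"invalid reference base(s): {bad}")
    masked = counts.copy()
    masked[np.arange(len(df)), ref_idx.to_numpy(dtype=int)] = -1
    alt_j = masked.argmax(axis=1)
    df["alt"] = np.array(BASES)[alt_j]
    df["alt_count"] = counts[np.arange(len(df)), alt_j]
    return df


def site_key_set(sites: pd.DataFrame) -> set[tuple]:
    """(chrom, pos, alt) key set for a table carrying those columns."""
    return set(zip(sites["chrom"], sites["pos"], sites["alt"]))


def select_indica_rna_snps(sites_93: pd.DataFrame) -> pd.DataFrame:
    """Sites nearly fixed for the alternative base in the 93-11 RNA pileup.

    Keeps sites with depth > 10 and alt fraction > 0.95 (both strict).
    Returns the annotated rows (chrom, pos, ref, alt, depth, alt_count).
    """
    df = _with_alt(sites_93)
    keep = (df["depth"] > 10) & (df["alt_count"] > 0.95 * df["depth"])
    return df.loc[keep, ["chrom", "pos", "ref", "alt", "depth", "alt_count"]].reset_index(
        drop=True
    )


def select_nipponbare_exclusion_snps(sites_N: pd.DataFrame) -> pd.DataFrame:
    """Sites where the Nipponbare RNA pileup shows the alt base above background.

    Same depth requirement as the 93-11 selection (depth > 10) but the alt
    fraction threshold drops to > 5%: any such site is excluded from the
    diagnostic set because reference-line reads already carry the
    alternative base.
    """
    df = _with_alt(sites_N)
    keep = (df["depth"] > 10) & (df["alt_count"] > 0.05 * df["depth"])
    return df.loc[keep, ["chrom", "pos", "ref", "alt", "depth", "alt_count"]].reset_index(
        drop=True
    )


def derive_diagnostic_snps(
    indica_rna: pd.DataFrame,
    genomic: pd.DataFrame,
    exclusion: pd.DataFrame,
) -> pd.DataFrame:
    """Set logic producing the diagnostic SNP list.

    ``(indica_rna ∩ genomic) \\ exclusion`` on the (chrom, pos, alt) key.
    Sites where the two positive evidence sources disagree on the alt base at
    the same position fall out of the intersection and are logged. The
    Nipponbare allele is the reference base, the 93-11 allele the alternative.

    All three inputs are tables with at least ``chrom, pos, ref, alt``
    columns (``genomic`` typically parsed from a VCF).
    """
    ind_keys = site_key_set(indica_rna)
    gen_keys = site_key_set(genomic)
    excl_keys = site_key_set(exclusion)

    kept = (ind_keys & gen_keys) - excl_keys
    # positions shared by the two positive sources but with disagreeing alt
    # bases fall out of the keyed intersection; report them
    conflict = (
        {(c, p) for c, p, _ in ind_keys} & {(c, p) for c, p, _ in gen_keys}
    ) - {(c, p) for c, p, _ in ind_keys & gen_keys}
    if conflict:
        logger.info("dropping %d site(s) with conflicting alt bases", len(conflict))
    ref_of = dict(zip(zip(indica_rna["chrom"], indica_rna["pos"]), indica_rna["ref"]))
    rows = sorted(kept)
    out = pd.DataFrame(rows, columns=["chrom", "pos", "allele_9"])
    out["allele_N"] = [ref_of[(c, p)] for c, p, _ in rows]
    return out[["chrom", "pos", "allele_N", "allele_9"]]


def assign_snps_to_genes(snps: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Assign each diagnostic SNP to the single gene whose exons contain it.

    ``exons`` has columns ``gene_id, chrom, start, end`` with 1-based
    inclusive coordinates. SNPs inside no gene or inside exons of two or more
    distinct genes are left unassigned (``gene_id`` = NaN) and counted in the
    log: multiply-assigned sites would test the same reads twice.
    """
    if (exons["end"] < exons["start"]).any():
        raise ValueError("degenerate exon interval (end < start)")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in exons.groupby("chrom"):
        # IntervalTree is half-open; +1 makes the 1-based inclusive end interior
        trees[chrom] = IntervalTree.from_tuples(
            (s, e + 1, g) for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    assigned = []
    n_none = n_multi = 0
    for chrom, pos in zip(snps["chrom"], snps["pos"]):
        hits = {iv.data for iv in trees[chrom][pos]} if chrom in trees else set()
        if len(hits) == 1:
            assigned.append(next(iter(hits)))
        else:
            assigned.append(None)
            if len(hits) == 0:
                n_none += 1
            else:
                n_multi += 1
    if n_none or n_multi:
        logger.info(
            "unassigned SNPs: %d intergenic, %d in overlapping gene models", n_none, n_multi
        )
    out = snps.copy()
    out["gene_id"] = assigned
    return out


def count_gene_alleles(
    site_tables: Mapping[str, pd.DataFrame], snps: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate per-gene allele-supporting read counts for each sample.

    For every diagnostic SNP with a gene assignment, reads matching the
    Nipponbare allele add to ``n_count`` and reads matching the 93-11 allele
    to ``i_count``; reads carrying neither base are ignored. Counting is
    per-site summation over each gene's SNPs (pileup summaries carry no
    read identity, so a read spanning several SNPs contributes at each).

    Parameters
    ----------
    site_tables : mapping sample label -> pileup-summary table.
    snps : diagnostic SNP table with ``gene_id`` (unassigned rows ignored).

    Returns a long table ``gene_id, sample, n_count, i_count``; genes whose
    SNPs received zero reads in a sample keep an explicit (0, 0) row.
    """
    usable = snps.dropna(subset=["gene_id"])
    out_frames = []
    for sample, sites in site_tables.items():
        merged = usable.merge(sites, on=["chrom", "pos"], how="left")
        counts = merged[list(BASES)].fillna(0).to_numpy(dtype=np.int64)
        base_idx = {b: j for j, b in enumerate(BASES)}
        n_j = merged["allele_N"].map(base_idx).to_numpy(dtype=int)
        i_j = merged["allele_9"].map(base_idx).to_numpy(dtype=int)
        rows = np.arange(len(merged))
        merged["n_count"] = counts[rows, n_j]
        merged["i_count"] = counts[rows, i_j]
        per_gene = (
            merged.groupby("gene_id", sort=True)[["n_count", "i_count"]].sum().reset_index()
        )
        per_gene.insert(1, "sample", sample)
        out_frames.append(per_gene)
    return pd.concat(out_frames, ignore_index=True)


def build_in_silico_hybrid(
    parent_N: pd.DataFrame, parent_9: pd.DataFrame
) -> pd.DataFrame:
    """Mix the two parental samples 1:1 into an in-silico hybrid.

    Each parent's per-gene counts are scaled by ``common_depth / library``
    where the library size is that parent's total diagnostic-site read count
    and ``common_depth`` is the smaller of the two libraries, then rounded to
    the nearest integer (ties to even). The Nipponbare allele column comes
    from the Nipponbare parent, the 93-11 column from the 93-11 parent.

    Inputs are ``gene_id, n_count, i_count`` tables for one sample each.
    """
    if len(parent_N) == 0 or len(parent_9) == 0:
        raise ValueError("parent count tables must be non-empty")
    lib_N = float(parent_N["n_count"].sum() + parent_N["i_count"].sum())
    lib_9 = float(parent_9["n_count"].sum() + parent_9["i_count"].sum())
    if lib_N == 0 or lib_9 == 0:
        raise ValueError("parent library size is zero")
    common = min(lib_N, lib_9)
    merged = parent_N[["gene_id", "n_count"]].merge(
        parent_9[["gene_id", "i_count"]], on="gene_id", how="outer"
    )
    merged = merged.fillna(0)
    n = np.round(merged["n_count"].to_numpy(dtype=float) * (common / lib_N))
    i = np.round(merged["i_count"].to_numpy(dtype=float) * (common / lib_9))
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "sample": "in_silico",
            "n_count": n.astype(np.int64),
            "i_count": i.astype(np.int64),
        }
    )
    return out.sort_values("gene_id", ignore_index=True)


def filter_testable_genes(
    counts: pd.DataFrame, min_total: int, samples: Iterable[str] | None = None
) -> set[str]:
    """Genes whose allele total reaches ``min_total`` in every analysed sample.

    ``counts`` is the long ``gene_id, sample, n_count, i_count`` table;
    ``samples`` restricts the requirement to a subset of samples (default:
    all samples present). A gene absent from any required sample fails.
    """
    df = counts if samples is None else counts[counts["sample"].isin(set(samples))]
    wanted = set(df["sample"].unique()) if samples is None else set(samples)
    totals = (
        df.assign(total=df["n_count"] + df["i_count"])
        .pivot_table(index="gene_id", columns="sample", values="total", fill_value=0)
    )
    for s in wanted - set(totals.columns):
        totals[s] = 0
    ok = (totals[list(wanted)] >= min_total).all(axis=1)
    return set(totals.index[ok])
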