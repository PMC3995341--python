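"""Diagnostic SNP selection, gene assignment, counting and in-silico mixing."""

import numpy as np
import pandas as pd
import pytest

from homeobias import diagnostics, io
from homeobias.diagnostics import (
    assign_snps_to_genes,
    build_in_silico_hybrid,
    count_gene_alleles,
    derive_diagnostic_snps,
    filter_testable_genes,
    select_indica_rna_snps,
    select_nipponbare_exclusion_snps,
)
from homeobias.simulate import SimulationConfig, sample_truth, simulate_site_table


def site_row(chrom, pos, ref, alt, ref_n, alt_n, **extra):
    row = {"chrom": chrom, "pos": pos, "ref": ref, "A": 0, "C": 0, "G": 0, "T": 0}
    row[ref] = ref_n
    row[alt] = alt_n
    row.update(extra)
    return row


class TestSnpSelection:
    def test_indica_thresholds_are_strict(self):
        sites = pd.DataFrame(
            [
                site_row("c1", 10, "A", "G", 0, 12),  # depth 12, alt 100% -> in
                site_row("c1", 20, "A", "G", 0, 10),  # depth 10 not > 10 -> out
                site_row("c1", 30, "A", "G", 5, 95),  # 95% not > 95% -> out
                site_row("c1", 40, "A", "G", 4, 96),  # 96% -> in
            ]
        )
        got = select_indica_rna_snps(sites)
        assert set(got["pos"]) == {10, 40}

    def test_exclusion_thresholds(self):
        sites = pd.DataFrame(
            [
                site_row("c1", 10, "A", "G", 94, 6),  # 6% alt -> excluded site
                site_row("c1", 20, "A", "G", 95, 5),  # 5% not > 5% -> kept clean
                site_row("c1", 30, "A", "G", 0, 8),  # depth 8 -> below depth floor
            ]
        )
        got = select_nipponbare_exclusion_snps(sites)
        assert set(got["pos"]) == {10}

    def test_set_logic(self):
        ind = pd.DataFrame(
            [
                {"chrom": "c1", "pos": 10, "ref": "A", "alt": "G"},
                {"chrom": "c1", "pos": 20, "ref": "A", "alt": "G"},
                {"chrom": "c1", "pos": 30, "ref": "T", "alt": "C"},
                {"chrom": "c1", "pos": 40, "ref": "A", "alt": "G"},
            ]
        )
        genomic = pd.DataFrame(
            [
                {"chrom": "c1", "pos": 10, "ref": "A", "alt": "G"},
                {"chrom": "c1", "pos": 30, "ref": "T", "alt": "C"},
                {"chrom": "c1", "pos": 40, "ref": "A", "alt": "C"},  # conflicting alt
            ]
        )
        excl = pd.DataFrame([{"chrom": "c1", "pos": 30, "ref": "T", "alt": "C"}])
        got = derive_diagnostic_snps(ind, genomic, excl)
        # pos 10: all evidence agrees; pos 20: RNA only; pos 30: excluded;
        # pos 40: alt disagreement between RNA and genomic list
        assert list(got["pos"]) == [10]
        assert got.loc[0, "allele_N"] == "A" and got.loc[0, "allele_9"] == "G"

    def test_order_invariance_and_idempotence(self):
        ind = pd.DataFrame(
            [
                {"chrom": "c1", "pos": p, "ref": "A", "alt": "G"}
                for p in (50, 10, 30, 20)
            ]
        )
        genomic = ind.sample(frac=1.0, random_state=1)
        empty = ind.iloc[:0]
        a = derive_diagnostic_snps(ind, genomic, empty)
        b = derive_diagnostic_snps(ind.iloc[::-1], genomic.iloc[::-1], empty)
        pd.testing.assert_frame_equal(a, b)
        again = derive_diagnostic_snps(
            a.rename(columns={"allele_9": "alt"}).assign(ref=lambda d: d["allele_N"]),
            genomic,
            empty,
        )
        pd.testing.assert_frame_equal(a, again)


class TestGeneAssignment:
    def make_snps(self, positions):
        return pd.DataFrame(
            {
                "chrom": "c1",
                "pos": positions,
                "allele_N": "A",
                "allele_9": "G",
            }
        )

    def test_assignment_rules(self):
        exons = pd.DataFrame(
            [
                {"gene_id": "gA", "chrom": "c1", "start": 100, "end": 200},
                {"gene_id": "gB", "chrom": "c1", "start": 180, "end": 300},
                {"gene_id": "gC", "chrom": "c1", "start": 400, "end": 500},
            ]
        )
        # 150: inside gA only; 190 and 200: inside both gA and gB (overlap);
        # 350: intergenic; 450: gC; 100: inclusive start boundary of gA
        snps = self.make_snps([150, 190, 350, 450, 100, 200])
        got = assign_snps_to_genes(snps, exons)
        assert list(got["gene_id"]) == ["gA", None, None, "gC", "gA", None]

    def test_degenerate_interval_rejected(self):
        exons = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c1", "start": 10, "end": 5}]
        )
        with pytest.raises(ValueError):
            assign_snps_to_genes(self.make_snps([7]), exons)


class TestCounting:
    def test_per_gene_summation(self):
        snps = pd.DataFrame(
            {
                "chrom": "c1",
                "pos": [10, 20, 30],
                "allele_N": ["A", "A", "A"],
                "allele_9": ["G", "G", "G"],
                "gene_id": ["g1", "g1", "g2"],
            }
        )
        sites = pd.DataFrame(
            [
                site_row("c1", 10, "A", "G", 30, 10, T=7),  # T reads match neither
                site_row("c1", 20, "A", "G", 50, 10),
                site_row("c1", 30, "A", "G", 0, 0),
            ]
        )
        got = count_gene_alleles({"s": sites}, snps).set_index("gene_id")
        assert tuple(got.loc["g1", ["n_count", "i_count"]]) == (80, 20)
        assert tuple(got.loc["g2", ["n_count", "i_count"]]) == (0, 0)  # row retained

    def test_conservation_against_per_site_totals(self, rng):
        n_sites = 40
        snps = pd.DataFrame(
            {
                "chrom": "c1",
                "pos": np.arange(1, n_sites + 1) * 10,
                "allele_N": "A",
                "allele_9": "G",
                "gene_id": [f"g{j % 7}" for j in range(n_sites)],
            }
        )
        counts = rng.integers(0, 100, size=(n_sites, 2))
        sites = pd.DataFrame(
            [
                site_row("c1", (j + 1) * 10, "A", "G", counts[j, 0], counts[j, 1])
                for j in range(n_sites)
            ]
        )
        got = count_gene_alleles({"s": sites}, snps)
        assert got["n_count"].sum() == counts[:, 0].sum()
        assert got["i_count"].sum() == counts[:, 1].sum()


class TestInSilicoHybrid:
    def test_equal_libraries_is_identity(self):
        pn = pd.DataFrame({"gene_id": ["g1", "g2"], "n_count": [300, 100], "i_count": 0})
        p9 = pd.DataFrame({"gene_id": ["g1", "g2"], "n_count": 0, "i_count": [100, 300]})
        got = build_in_silico_hybrid(pn, p9).set_index("gene_id")
        assert tuple(got.loc["g1", ["n_count", "i_count"]]) == (300, 100)
        assert tuple(got.loc["g2", ["n_count", "i_count"]]) == (100, 300)

    def test_scaling_to_smaller_library(self):
        # parent_N library 1,000,000; parent_9 library 500,000
        pn = pd.DataFrame(
            {"gene_id": ["g1", "rest"], "n_count": [300, 999_700], "i_count": 0}
        )
        p9 = pd.DataFrame(
            {"gene_id": ["g1", "rest"], "n_count": 0, "i_count": [100, 499_900]}
        )
        got = build_in_silico_hybrid(pn, p9).set_index("gene_id")
        assert tuple(got.loc["g1", ["n_count", "i_count"]]) == (150, 100)

    def test_zero_gene_stays_zero_and_empty_rejected(self):
        pn = pd.DataFrame({"gene_id": ["g1", "g2"], "n_count": [0, 10], "i_count": 0})
        p9 = pd.DataFrame({"gene_id": ["g1", "g2"], "n_count": 0, "i_count": [0, 10]})
        got = build_in_silico_hybrid(pn, p9).set_index("gene_id")
        assert tuple(got.loc["g1", ["n_count", "i_count"]]) == (0, 0)
        with pytest.raises(ValueError):
            build_in_silico_hybrid(pn.iloc[:0], p9)


class TestFilterTestable:
    def make_counts(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g1", "g2"],
                "sample": ["a", "a", "b", "b"],
                "n_count": [6, 20, 50, 3],
                "i_count": [5, 20, 50, 2],
            }
        )

    def test_threshold_semantics(self):
        # totals: g1 = 11 (a), 100 (b); g2 = 40 (a), 5 (b)
        counts = self.make_counts()
        assert filter_testable_genes(counts, 0) == {"g1", "g2"}
        assert filter_testable_genes(counts, 11) == {"g1"}  # g2 total 5 in b
        assert filter_testable_genes(counts, 12, samples=["a"]) == {"g2"}

    def test_missing_sample_counts_as_zero(self):
        counts = self.make_counts()
        assert filter_testable_genes(counts, 1, samples=["a", "b", "c"]) == set()

    def test_deep_simulation_passes_default_threshold(self, reference_sim):
        _, cfg, counts = reference_sim
        # at mean depth 1000 and dispersion 0.05 the NB left tail below 10
        # reads is negligible: essentially every gene is testable
        testable = filter_testable_genes(counts, 10)
        assert len(testable) >= 0.99 * cfg.n_genes


class TestSiteStageRecovery:
    def test_simulated_snps_recovered_exactly(self, tmp_path):
        """Error-free simulation round-trips through VCF/GFF3 to exact recovery."""
        cfg = SimulationConfig(
            n_genes=50,
            error_rate=0.0,
            withheld_fraction=0.2,
            contaminated_fraction=0.2,
            seed=13,
        )
        sites = simulate_site_table(sample_truth(cfg), cfg)
        io.write_vcf_snps(sites.genomic, tmp_path / "g.vcf")
        io.write_gff3_genes(sites.gene_models, tmp_path / "g.gff3")

        ind = select_indica_rna_snps(sites.sites_9)
        excl = select_nipponbare_exclusion_snps(sites.sites_N)
        snps = derive_diagnostic_snps(ind, io.read_vcf_snps(tmp_path / "g.vcf"), excl)
        snps = assign_snps_to_genes(snps, io.read_gff3_exons(tmp_path / "g.gff3"))

        truth = sites.truth_snps
        expected = truth[~truth["withheld"] & ~truth["contaminated"]]
        assert set(zip(snps["chrom"], snps["pos"])) == set(
            zip(expected["chrom"], expected["pos"])
        )
        # every surviving SNP maps back to its source gene
        merged = snps.merge(truth, on=["chrom", "pos"], suffixes=("", "_truth"))
        assert (merged["gene_id"] == merged["gene_id_truth"]).all()
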