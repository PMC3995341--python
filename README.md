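# homeobias

Homoeolog-specific expression analysis for hybrids and allopolyploids:
diagnostic-SNP selection, per-gene allele counting, exact bias testing,
and cis/trans regulatory-divergence classification — with a synthetic-data
generator that provides ground truth for every stage.

## The problem

When two diverged genomes meet in one nucleus — in an F1 hybrid or, after
whole-genome duplication (WGD), in an allopolyploid — each gene is present
as two parental copies (*homoeologs*). RNA-seq reads covering
parent-diagnostic SNPs reveal how strongly each copy is expressed, and
comparing three sample types separates the regulatory causes:

* **in-silico hybrid (P)** — the two parents' reads mixed 1:1; its allelic
  ratio reflects the parents' accumulated regulatory divergence,
  *cis* + *trans*;
* **true hybrid (H)** — both alleles share one *trans* environment, so the
  allelic ratio reflects *cis* divergence only;
* **tetraploid (T4)** — the same merged genome after WGD; ratio changes
  relative to the hybrid isolate the effect of genome doubling.

For a gene with cis effect `c` and trans effect `t` (log2 units), the
expected Nipponbare-allele fraction is `r/(1+r)` with `r = 2^(c+t)` in P
and `r = 2^c` in H. The package tests each gene's ratio against 1:1 with
the exact binomial test (BH-FDR, q < 0.05), compares ratios between
samples with the Yates-corrected chi-square test on the 2x2 allele-count
table, and classifies each gene as cis-only, trans-only, cis+trans,
cis x trans, compensatory, conserved, or ambiguous; as convergently,
divergently, or conservedly regulated relative to P; and into one of nine
bias-inheritance categories (the 3x3 cross of bias states in P and H/T4).

## Worked example

```python
from homeobias import PipelineConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(
    out_dir="demo",
    simulation={"n_genes": 1200, "depth": 1000, "dispersion": 0.05},
    seed=3,
)
out = run_pipeline(cfg)
master = pd.read_csv(out / "master_table.tsv", sep="\t")
truth = pd.read_csv(out / "truth.tsv", sep="\t")
joined = master.merge(truth, on="gene_id")
print(pd.crosstab(joined["architecture"], joined["cis_trans_N9"]).loc[
    ["cis_only", "compensatory", "conserved"],
    ["CIS_ONLY", "COMPENSATORY", "CONSERVED"]])
```

prints

```
cis_trans_N9    CIS_ONLY  COMPENSATORY  CONSERVED
architecture
cis_only             190             0          0
compensatory           0           188          3
conserved              0             0        185
```

i.e. of 200 simulated genes per architecture at mean depth 1000, 95% of
cis-only genes, 94% of compensatory genes (cis and trans cancel in the
parents but the hybrid exposes the cis imbalance), and 92% of conserved
genes are recovered by the classifier; the residue falls mostly into
adjacent categories through test-power boundaries, not into opposite ones.

The same run writes per-sample bias tables, regulation groups, the
nine-category inheritance matrix, hybrid-vs-tetraploid comparison sets,
Venn-region overlap counts, and a KS comparison of log2 allelic-ratio
spectra (`ranges.tsv`) — see `docs/methods.md` for the model and every
threshold.

A command-line interface mirrors the library:

```bash
homeobias simulate --out sim --seed 4 --n-genes 500
homeobias snps --indica-sites sim/sites_parent_9.tsv \
               --nipponbare-sites sim/sites_parent_N.tsv \
               --genomic-vcf sim/genomic_snps.vcf \
               --gff sim/genes.gff3 --out snps.tsv
homeobias analyze --config pipeline.yaml
```

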