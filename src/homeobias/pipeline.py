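"""End-to-end orchestration of the homoeolog-bias analysis.

A run starts from one of three entry points — a simulation config, per-site
pileup tables, or ready-made per-gene allele counts — and produces the full
set of tab-separated result tables in an output directory:

``diagnostic_snps.tsv``  (sites mode) selected SNPs with gene assignment
``gene_counts.tsv``      per gene x sample allele counts incl. in_silico
``bias_<sample>.tsv``    per-gene binomial 1:1 test and bias call
``cis_trans_<hybrid>.tsv``  seven-type regulatory-divergence classification
``groups_<sample>.tsv``  convergent/divergent/conserved assignment
``inheritance_matrix.tsv``  nine-category count/percentage matrix
``wgd_affected_<pair>.tsv``  hybrid-vs-tetraploid ratio-changed genes
``overlaps.tsv``         Venn region counts + inherited/novel proportions
``ranges.tsv``           pairwise KS comparison of log2-ratio distributions
``boxplots.tsv``         per-sample boxplot geometry
``master_table.tsv``     one row per testable gene, all calls joined
``enrichment.tsv``       (optional) per-group term enrichment
``run_log.json``         config echo + hash, versions, per-stage gene counts

All stages are deterministic given the inputs and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, diagnostics, io, report, simulate
from .stats import log2_allelic_ratio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "ratio_vectors"]

#: hybrid -> derived tetraploid pairing used by default for simulated data
DEFAULT_TETRAPLOID_OF = {"N9": "NN99", "9N": "99NN"}


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``simulation``, ``sites`` or ``counts`` selects the entry
    point. Sample roles identify the two parents, the hybrids (at least
    one), and optionally which tetraploid derives from which hybrid.
    """

    out_dir: str | Path
    counts: str | None = None  # path to a gene_counts.tsv
    sites: Mapping[str, str] | None = None  # sample -> pileup-summary path
    genomic_vcf: str | None = None  # required with `sites`
    gff3: str | None = None  # required with `sites`
    simulation: Mapping | None = None  # SimulationConfig fields
    parent_N: str = "parent_N"
    parent_9: str = "parent_9"
    hybrids: tuple[str, ...] = ("N9", "9N")
    tetraploid_of: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TETRAPLOID_OF)
    )
    alpha: float = 0.05
    pseudocount: float = 0.5
    min_total: int = 10
    seed: int = 0
    annotation: str | None = None  # term -> gene TSV for enrichment

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "hybrids" in raw:
            raw["hybrids"] = tuple(raw["hybrids"])
        return cls(**raw)

    def validate(self) -> None:
        chosen = [x is not None for x in (self.simulation, self.sites, self.counts)]
        if sum(chosen) != 1:
            raise ValueError("exactly one of simulation/sites/counts must be set")
        if self.sites is not None and (self.genomic_vcf is None or self.gff3 is None):
            raise ValueError("sites mode requires genomic_vcf and gff3")
        if not self.hybrids:
            raise ValueError("at least one hybrid sample is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.tetraploid_of) - set(self.hybrids)
        if unknown:
            raise ValueError(f"tetraploid pairing names unknown hybrids: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _per_sample(counts: pd.DataFrame, sample: str) -> pd.DataFrame:
    sub = counts.loc[counts["sample"] == sample, ["gene_id", "n_count", "i_count"]]
    if sub.empty:
        raise ValueError(f"no counts for required sample {sample!r}")
    return sub.reset_index(drop=True)


def ratio_vectors(
    tables: Mapping[str, pd.DataFrame], pseudocount: float
) -> dict[str, np.ndarray]:
    """Per-sample log2 allelic-ratio vectors over each table's genes."""
    return {
        s: log2_allelic_ratio(df["n_count"], df["i_count"], pseudocount)
        for s, df in tables.items()
    }


def _acquire_counts(cfg: PipelineConfig, out: Path, log: dict) -> pd.DataFrame:
    """Entry stage: produce the long gene-count table for the run."""
    if cfg.simulation is not None:
        sim_cfg = simulate.SimulationConfig(**{"seed": cfg.seed, **dict(cfg.simulation)})
        truths = simulate.sample_truth(sim_cfg)
        simulate.truth_frame(truths).to_csv(out / "truth.tsv", sep="\t", index=False)
        counts = simulate.simulate_gene_counts(truths, sim_cfg)
        log["stage_counts"]["simulated_genes"] = sim_cfg.n_genes
        return counts
    if cfg.counts is not None:
        return io.read_gene_counts(cfg.counts)

    # sites mode: diagnostic SNP selection then counting
    site_tables = {s: io.read_site_counts(p) for s, p in cfg.sites.items()}
    for role in (cfg.parent_N, cfg.parent_9):
        if role not in site_tables:
            raise ValueError(f"sites mode requires a site table for {role!r}")
    indica = diagnostics.select_indica_rna_snps(site_tables[cfg.parent_9])
    exclusion = diagnostics.select_nipponbare_exclusion_snps(site_tables[cfg.parent_N])
    genomic = io.read_vcf_snps(cfg.genomic_vcf)
    snps = diagnostics.derive_diagnostic_snps(indica, genomic, exclusion)
    exons = io.read_gff3_exons(cfg.gff3)
    snps = diagnostics.assign_snps_to_genes(snps, exons)
    snps.to_csv(out / "diagnostic_snps.tsv", sep="\t", index=False)
    log["stage_counts"]["diagnostic_snps"] = int(snps["gene_id"].notna().sum())
    return diagnostics.count_gene_alleles(site_tables, snps)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the result tables; returns the output dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "alpha": config.alpha,
        "min_total": config.min_total,
        "pseudocount": config.pseudocount,
        "stage_counts": {},
        "dropped": {},
    }

    counts = _acquire_counts(config, out, log)

    # assemble per-sample tables; build the in-silico mix if absent
    have = set(counts["sample"].unique())
    tetraploids = tuple(config.tetraploid_of.get(h) for h in config.hybrids)
    tetraploids = tuple(t for t in tetraploids if t is not None and t in have)
    analyzed = ["in_silico", *config.hybrids, *tetraploids]
    if "in_silico" not in have:
        mix = diagnostics.build_in_silico_hybrid(
            _per_sample(counts, config.parent_N), _per_sample(counts, config.parent_9)
        )
        counts = pd.concat([counts, mix], ignore_index=True)
    io.write_gene_counts(counts, out / "gene_counts.tsv")

    universe = diagnostics.filter_testable_genes(
        counts, config.min_total, samples=analyzed
    )
    all_genes = set(counts["gene_id"].unique())
    log["stage_counts"]["input_genes"] = len(all_genes)
    log["stage_counts"]["testable_genes"] = len(universe)
    log["dropped"]["below_min_total"] = len(all_genes) - len(universe)
    if not universe:
        raise RuntimeError("stage filter_testable_genes: no gene passes min_total")

    tables = {
        s: _per_sample(counts, s).pipe(lambda d: d[d["gene_id"].isin(universe)])
        .sort_values("gene_id", ignore_index=True)
        for s in analyzed
    }

    # stage: bias calls
    biases: dict[str, pd.DataFrame] = {}
    for s, df in tables.items():
        b = classify.call_bias(df, config.alpha)
        b.to_csv(out / f"bias_{s}.tsv", sep="\t", index=False)
        biases[s] = b.set_index("gene_id")
        log["stage_counts"][f"biased_{s}"] = int((b["bias"] != "EQUAL").sum())

    # stage: cis/trans types per hybrid
    cis_trans: dict[str, pd.DataFrame] = {}
    for h in config.hybrids:
        ct = classify.classify_cis_trans(tables["in_silico"], tables[h], config.alpha)
        ct.to_csv(out / f"cis_trans_{h}.tsv", sep="\t", index=False)
        cis_trans[h] = ct.set_index("gene_id")

    # stage: regulation groups per hybrid and tetraploid
    groups: dict[str, pd.DataFrame] = {}
    for s in [*config.hybrids, *tetraploids]:
        g = classify.classify_group(tables["in_silico"], tables[s], config.alpha)
        g.to_csv(out / f"groups_{s}.tsv", sep="\t", index=False)
        groups[s] = g.set_index("gene_id")

    # stage: inheritance categories and matrix
    sample_biases = {
        s: biases[s]["bias"] for s in [*config.hybrids, *tetraploids]
    }
    matrix = report.inheritance_matrix(biases["in_silico"]["bias"], sample_biases)
    matrix.to_csv(out / "inheritance_matrix.tsv", sep="\t", index=False)
    inheritance = {
        s: classify.classify_inheritance(biases["in_silico"]["bias"], sb)
        for s, sb in sample_biases.items()
    }

    # stage: direct hybrid-vs-tetraploid comparison
    wgd_sets: dict[str, set] = {}
    for h in config.hybrids:
        t = config.tetraploid_of.get(h)
        if t in tables:
            affected = classify.wgd_affected(tables[h], tables[t], config.alpha)
            wgd_sets[f"{t}_vs_{h}"] = affected
            pd.DataFrame({"gene_id": sorted(affected)}).to_csv(
                out / f"wgd_affected_{t}_vs_{h}.tsv", sep="\t", index=False
            )
            log["stage_counts"][f"wgd_affected_{t}_vs_{h}"] = len(affected)

    # stage: overlap summaries (ratio-changed sets and per-group Venn)
    overlap_rows = []
    changed = {
        s: set(g.index[(g["q"] < config.alpha) & ~g["untestable"]])
        for s, g in groups.items()
    }
    if len(changed) >= 2:
        for region, n in classify.venn_counts(changed).items():
            overlap_rows.append({"comparison": "ratio_changed", "region": "&".join(region), "count": n})
    for grp in classify.REG_GROUPS:
        by_sample = {
            s: set(g.index[g["group"] == grp]) for s, g in groups.items()
        }
        if len(by_sample) >= 2:
            for region, n in classify.venn_counts(by_sample).items():
                overlap_rows.append({"comparison": grp, "region": "&".join(region), "count": n})
        for h in config.hybrids:
            t = config.tetraploid_of.get(h)
            if t in by_sample:
                overlap_rows.append(
                    {
                        "comparison": grp,
                        "region": f"inherited_{h}_to_{t}",
                        "count": round(
                            classify.inherited_proportion(by_sample[h], by_sample[t]), 6
                        ),
                    }
                )
                overlap_rows.append(
                    {
                        "comparison": grp,
                        "region": f"novel_{t}_vs_{h}",
                        "count": round(
                            classify.novel_proportion(by_sample[h], by_sample[t]), 6
                        ),
                    }
                )
    pd.DataFrame(overlap_rows).to_csv(out / "overlaps.tsv", sep="\t", index=False)

    # stage: range comparison (log2 ratio distributions)
    ratios = ratio_vectors(tables, config.pseudocount)
    report.compare_ranges(ratios).to_csv(out / "ranges.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample": s, **report.boxplot_stats(v)} for s, v in ratios.items()]
    ).to_csv(out / "boxplots.tsv", sep="\t", index=False)

    # stage: optional enrichment
    if config.annotation is not None:
        term_map = io.read_term_map(config.annotation)
        group_sets = {
            f"{s}:{grp}": set(g.index[g["group"] == grp])
            for s, g in groups.items()
            for grp in classify.REG_GROUPS
        }
        report.enrichment_report(group_sets, universe, term_map, config.alpha).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
    else:
        logger.info("no annotation supplied; enrichment stage skipped")

    # master table: one row per testable gene
    master = pd.DataFrame(index=sorted(universe))
    master.index.name = "gene_id"
    for s, df in tables.items():
        d = df.set_index("gene_id")
        master[f"n_{s}"] = d["n_count"]
        master[f"i_{s}"] = d["i_count"]
    for s, b in biases.items():
        master[f"bias_{s}"] = b["bias"]
        master[f"q_bias_{s}"] = b["q"]
    for h, ct in cis_trans.items():
        master[f"cis_trans_{h}"] = ct["category"]
    for s, g in groups.items():
        master[f"group_{s}"] = g["group"]
        master[f"group_untestable_{s}"] = g["untestable"]
    for s, inh in inheritance.items():
        master[f"inheritance_{s}"] = inh.set_index("gene_id")["category"]
    for pair, affected in wgd_sets.items():
        master[f"wgd_{pair}"] = master.index.isin(affected)
    master.reset_index().to_csv(out / "master_table.tsv", sep="\t", index=False)
    log["stage_counts"]["master_rows"] = len(master)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
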