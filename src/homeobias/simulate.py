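"""Synthetic allele-specific count data under explicit regulatory architectures.

The generative model mirrors how cis and trans regulatory divergence act on
homoeolog expression. Each gene carries a cis effect ``c`` and a trans effect
``t`` (log2 units). In the 1:1 parental mix the Nipponbare:93-11 expression
ratio reflects the full accumulated divergence, ``r = 2^(c+t)``; inside a
hybrid nucleus the shared trans environment acts on both alleles equally, so
the allelic ratio reflects the cis component only, ``r = 2^c``. Tetraploids
behave like the hybrid plus a per-gene whole-genome-duplication perturbation
``w`` drawn independently for each tetraploid line, ``r = 2^(c+w)``.

Six architectures cover the classifier's seven outcome types (the seventh,
"ambiguous", is a residual category with no generative counterpart):

========================  =============================
architecture              constraint on (c, t)
========================  =============================
conserved                 c = t = 0
cis_only                  c != 0, t = 0
trans_only                c = 0, t != 0
cis_plus_trans            c·t > 0 (reinforcing)
cis_by_trans              c·t < 0, c + t != 0 (opposing)
compensatory              c = -t != 0 (exactly cancel)
========================  =============================

Counts: per gene and sample the total diagnostic read count is negative
binomial with mean proportional to the gene's base expression ``mu``
(normalised so the across-gene mean equals the configured depth) and
variance ``m + dispersion * m^2``; the Nipponbare-allele count is binomial
given the total with the architecture's expected N fraction. The
overdispersion is realised as a per-gene expression factor shared across
samples (gamma-Poisson with a common gamma draw), so depth variability of a
gene never masquerades as an allele-ratio difference between samples. Parental
samples are single-genotype, so all their reads carry that parent's allele;
the parents' totals are tilted by ``2^(±(c+t)/2)`` so the 1:1 in-silico mix
recovers the parental ratio ``2^(c+t)``.

The site-level simulator emits pileup summaries for the two parental RNA
samples plus a genomic SNP list, for testing the diagnostic-SNP stage:
93-11 reads carry the alternative base (up to the per-base error rate),
Nipponbare reads the reference base. A configurable fraction of true SNPs is
withheld from the genomic list, and another fraction is made non-diagnostic
by contaminating the Nipponbare pileup with >5% alternative-base reads.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import BASES, build_in_silico_hybrid

ARCHITECTURES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
)

SAMPLE_KINDS = ("parent_mix", "hybrid", "tetraploid_NN99", "tetraploid_99NN")

__all__ = [
    "ARCHITECTURES",
    "SAMPLE_KINDS",
    "RegulatoryTruth",
    "SimulationConfig",
    "sample_truth",
    "expected_n_fraction",
    "simulate_gene_counts",
    "simulate_site_table",
    "SimulatedSites",
]


@dataclass(frozen=True)
class RegulatoryTruth:
    """Ground-truth regulatory parameters for one gene."""

    gene_id: str
    mu: float  # base expression (expected reads per gene at unit depth)
    c: float  # cis effect, log2 units
    t: float  # trans effect, log2 units
    w_NN99: float  # WGD perturbation in the NN99 tetraploid, log2 units
    w_99NN: float  # WGD perturbation in the 99NN tetraploid, log2 units
    architecture: str

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")


def _equal_proportions() -> dict[str, float]:
    return {a: 1.0 / len(ARCHITECTURES) for a in ARCHITECTURES}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    Defaults describe the reference simulation used throughout the test
    suite: deep diagnostic coverage (mean 1000 reads/gene), mild RNA-seq
    overdispersion (0.05), cis/trans effect magnitudes uniform on
    [0.5, 3] log2 units with random sign, equal numbers of genes per
    architecture, and no WGD perturbation unless ``w_sd`` is raised.
    """

    n_genes: int = 1000
    depth: float = 1000.0  # mean diagnostic reads per gene per sample
    dispersion: float = 0.05  # NB dispersion phi: var = m + phi*m^2; 0 = Poisson
    architecture_proportions: Mapping[str, float] = field(
        default_factory=_equal_proportions
    )
    effect_low: float = 0.5  # min |c|, |t| in log2 units
    effect_high: float = 3.0  # max |c|, |t|
    mu_sigma: float = 1.0  # sd of log base expression (lognormal mu spread)
    w_sd: float = 0.0  # sd of per-tetraploid WGD perturbation
    snps_per_gene: int = 3
    error_rate: float = 0.005  # per-base sequencing error at simulated sites
    site_depth: float = 100.0  # mean read depth per simulated site
    withheld_fraction: float = 0.0  # true SNPs absent from the genomic list
    contaminated_fraction: float = 0.0  # SNPs with >5% alt reads in Nipponbare RNA
    contamination_level: float = 0.2  # alt fraction at contaminated sites
    seed: int = 0

    def validate(self) -> None:
        props = dict(self.architecture_proportions)
        unknown = set(props) - set(ARCHITECTURES)
        if unknown:
            raise ValueError(f"unknown architectures: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ValueError("architecture proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("architecture proportions must sum to 1")
        for name in ("depth", "site_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "dispersion",
            "w_sd",
            "error_rate",
            "withheld_fraction",
            "contaminated_fraction",
            "mu_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_genes < 1 or self.snps_per_gene < 1:
            raise ValueError("n_genes and snps_per_gene must be >= 1")
        if not 0 < self.effect_low <= self.effect_high:
            raise ValueError("require 0 < effect_low <= effect_high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture_proportions"] = dict(self.architecture_proportions)
        return d


def _draw_effect(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi) * rng.choice((-1.0, 1.0)))


def sample_truth(config: SimulationConfig) -> list[RegulatoryTruth]:
    """Draw a ground-truth table of ``n_genes`` regulatory architectures.

    Architectures are assigned by rounding ``n_genes * proportion`` to an
    exact partition (largest-remainder), so recovery rates per architecture
    are computed on deterministic group sizes; gene order is shuffled.
    All randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    props = dict(config.architecture_proportions)

    # largest-remainder apportionment of n_genes among architectures
    raw = {a: config.n_genes * props.get(a, 0.0) for a in ARCHITECTURES}
    counts = {a: int(np.floor(v)) for a, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    for a in sorted(ARCHITECTURES, key=lambda a: raw[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1

    labels = [a for a in ARCHITECTURES for _ in range(counts[a])]
    rng.shuffle(labels)

    lo, hi = config.effect_low, config.effect_high
    width = len(str(config.n_genes - 1))
    truths = []
    for g, arch in enumerate(labels):
        mu = float(rng.lognormal(mean=0.0, sigma=config.mu_sigma))
        if arch == "conserved":
            c = t = 0.0
        elif arch == "cis_only":
            c, t = _draw_effect(rng, lo, hi), 0.0
        elif arch == "trans_only":
            c, t = 0.0, _draw_effect(rng, lo, hi)
        elif arch == "cis_plus_trans":
            c = _draw_effect(rng, lo, hi)
            t = float(np.copysign(rng.uniform(lo, hi), c))
        elif arch == "cis_by_trans":
            c = _draw_effect(rng, lo, hi)
            t = float(-np.copysign(rng.uniform(lo, hi), c))
            while c + t == 0.0:  # measure-zero guard
                t = float(-np.copysign(rng.uniform(lo, hi), c))
        else:  # compensatory
            c = _draw_effect(rng, lo, hi)
            t = -c
        if config.w_sd > 0:
            w1, w2 = rng.normal(0.0, config.w_sd, size=2)
        else:
            w1 = w2 = 0.0
        truths.append(
            RegulatoryTruth(
                gene_id=f"gene{g:0{width}d}",
                mu=mu,
                c=c,
                t=t,
                w_NN99=float(w1),
                w_99NN=float(w2),
                architecture=arch,
            )
        )
    return truths


def expected_n_fraction(truth: RegulatoryTruth, sample_kind: str) -> float:
    """Expected fraction of Nipponbare-allele reads for one gene and sample.

    ``r/(1+r)`` with r = 2^(c+t) in the parental mix, 2^c in a hybrid, and
    2^(c+w) in a tetraploid. The hybrid value is independent of t: a shared
    trans environment cannot generate allelic imbalance.
    """
    if sample_kind == "parent_mix":
        e = truth.c + truth.t
    elif sample_kind == "hybrid":
        e = truth.c
    elif sample_kind == "tetraploid_NN99":
        e = truth.c + truth.w_NN99
    elif sample_kind == "tetraploid_99NN":
        e = truth.c + truth.w_99NN
    else:
        raise ValueError(f"unknown sample_kind {sample_kind!r}")
    r = 2.0**e
    return r / (1.0 + r)


def _gene_factors(rng, n: int, dispersion: float) -> np.ndarray:
    """Per-gene expression multipliers lambda with E=1, Var=dispersion.

    Totals are Poisson(m * lambda) with lambda shared across samples, which
    makes each sample's marginal total negative binomial with variance
    ``m + dispersion * m^2`` while keeping allele fractions conditionally
    binomial: depth variability of a gene does not masquerade as
    regulatory divergence.
    """
    if dispersion == 0.0:
        return np.ones(n)
    return rng.gamma(1.0 / dispersion, dispersion, size=n)


def truth_frame(truths: Sequence[RegulatoryTruth]) -> pd.DataFrame:
    """Ground-truth table as a DataFrame (one row per gene)."""
    return pd.DataFrame([asdict(tr) for tr in truths])


def simulate_gene_counts(
    truths: Sequence[RegulatoryTruth], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate per-gene allele counts for all seven samples.

    Returns the long table ``gene_id, sample, n_count, i_count`` covering
    parent_N, parent_9, in_silico (the 1:1 parental mix, built by
    :func:`~homeobias.diagnostics.build_in_silico_hybrid`), the reciprocal
    hybrids N9 and 9N, and the tetraploids NN99 and 99NN. The reciprocal
    hybrids are independent draws from the same distribution (reciprocal
    cross direction has no modelled effect); the two tetraploids differ
    through their independent w perturbations.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 1))
    genes = np.array([tr.gene_id for tr in truths])
    mu = np.array([tr.mu for tr in truths])
    c = np.array([tr.c for tr in truths])
    t = np.array([tr.t for tr in truths])
    m = config.depth * mu / mu.mean()
    lam = _gene_factors(rng, len(m), config.dispersion)

    frames = []

    # parents: single genotype, tilted totals so the 1:1 mix shows 2^(c+t)
    tilt = 2.0 ** ((c + t) / 2.0)
    tot_N = rng.poisson(m * lam * tilt)
    tot_9 = rng.poisson(m * lam / tilt)
    parent_N = pd.DataFrame(
        {"gene_id": genes, "sample": "parent_N", "n_count": tot_N, "i_count": 0}
    )
    parent_9 = pd.DataFrame(
        {"gene_id": genes, "sample": "parent_9", "n_count": 0, "i_count": tot_9}
    )
    frames += [parent_N, parent_9]
    frames.append(build_in_silico_hybrid(parent_N, parent_9))

    kind_of = {
        "N9": "hybrid",
        "9N": "hybrid",
        "NN99": "tetraploid_NN99",
        "99NN": "tetraploid_99NN",
    }
    for sample, kind in kind_of.items():
        frac = np.array([expected_n_fraction(tr, kind) for tr in truths])
        total = rng.poisson(m * lam)
        n = rng.binomial(total, frac)
        frames.append(
            pd.DataFrame(
                {"gene_id": genes, "sample": sample, "n_count": n, "i_count": total - n}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out[["n_count", "i_count"]] = out[["n_count", "i_count"]].astype(np.int64)
    return out


@dataclass
class SimulatedSites:
    """Site-level simulation output for the diagnostics stage."""

    sites_N: pd.DataFrame  # Nipponbare RNA pileup summary (chrom,pos,ref,A,C,G,T)
    sites_9: pd.DataFrame  # 93-11 RNA pileup summary
    genomic: pd.DataFrame  # genomic SNP list (chrom, pos, ref, alt)
    truth_snps: pd.DataFrame  # all true SNPs with gene_id, withheld, contaminated
    gene_models: pd.DataFrame  # gene_id, chrom, start, end (1-based inclusive)


def simulate_site_table(
    truths: Sequence[RegulatoryTruth], config: SimulationConfig
) -> SimulatedSites:
    """Simulate site-level pileups for the two parental RNA samples.

    Genes are laid out on one synthetic chromosome, 2 kb apart with a
    1.5 kb exon each holding ``snps_per_gene`` evenly spaced SNPs. At each
    SNP the 93-11 pileup is alternative-base at frequency
    ``1 - error_rate`` and the Nipponbare pileup reference-base at the same
    fidelity, with all errors landing on the other diagnostic base (the
    worst case for the filters). ``withheld_fraction`` of SNPs are omitted
    from the genomic list and ``contaminated_fraction`` get
    ``contamination_level`` alternative-base reads in the Nipponbare pileup.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 2))
    gene_len, gene_gap = 1500, 2000
    chrom = "chr1"

    gene_rows, snp_rows = [], []
    sites_N_rows, sites_9_rows = [], []
    for g, tr in enumerate(truths):
        start = g * gene_gap + 1
        end = start + gene_len - 1
        gene_rows.append((tr.gene_id, chrom, start, end))
        offsets = np.linspace(100, gene_len - 100, config.snps_per_gene).astype(int)
        for pos in start + offsets:
            ref = rng.choice(BASES)
            alt = rng.choice([b for b in BASES if b != ref])
            withheld = bool(rng.random() < config.withheld_fraction)
            contaminated = bool(rng.random() < config.contaminated_fraction)
            snp_rows.append((chrom, int(pos), ref, alt, tr.gene_id, withheld, contaminated))

            d9 = max(int(rng.poisson(config.site_depth)), 1)
            alt9 = rng.binomial(d9, 1.0 - config.error_rate)
            row9 = {b: 0 for b in BASES}
            row9[alt], row9[ref] = alt9, d9 - alt9
            sites_9_rows.append({"chrom": chrom, "pos": int(pos), "ref": ref, **row9})

            dN = max(int(rng.poisson(config.site_depth)), 1)
            p_alt = config.contamination_level if contaminated else config.error_rate
            altN = rng.binomial(dN, p_alt)
            rowN = {b: 0 for b in BASES}
            rowN[alt], rowN[ref] = altN, dN - altN
            sites_N_rows.append({"chrom": chrom, "pos": int(pos), "ref": ref, **rowN})

    truth_snps = pd.DataFrame(
        snp_rows,
        columns=["chrom", "pos", "ref", "alt", "gene_id", "withheld", "contaminated"],
    )
    genomic = truth_snps.loc[~truth_snps["withheld"], ["chrom", "pos", "ref", "alt"]]
    cols = ["chrom", "pos", "ref", *BASES]
    return SimulatedSites(
        sites_N=pd.DataFrame(sites_N_rows)[cols],
        sites_9=pd.DataFrame(sites_9_rows)[cols],
        genomic=genomic.reset_index(drop=True),
        truth_snps=truth_snps,
        gene_models=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"]),
    )
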