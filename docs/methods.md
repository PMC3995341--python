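# Methods

## Model

Each gene's two parental copies (homoeologs) are distinguished by
diagnostic SNPs, and their relative expression is summarised by the
Nipponbare-allele read fraction. Regulatory divergence between the parents
decomposes into a *cis* component `c` (linked to the allele, so it travels
with it into any nucleus) and a *trans* component `t` (diffusible, so a
hybrid nucleus applies one shared trans environment to both alleles). In
log2 units the expected allelic ratio is:

| sample                    | ratio N:9    |
|---------------------------|--------------|
| in-silico parental mix P  | `2^(c+t)`    |
| F1 hybrid H               | `2^c`        |
| tetraploid T4             | `2^(c+w)`    |

`w` is a per-gene, per-tetraploid perturbation standing in for the
stoichiometric disruption that accompanies whole-genome duplication. No
quantitative model of that effect exists; `w ~ Normal(0, w_sd)` drawn
independently for the two reciprocal tetraploids is this package's own
minimal stand-in, and its independence across lines is what produces the
low tetraploid-tetraploid overlap the classifier reports. Default
`w_sd = 0` (tetraploids behave like hybrids unless the perturbation is
switched on).

## Statistical tests

* **Bias (1:1) test** — exact binomial, two-sided by the
  minimum-likelihood rule: p sums `pmf(j; n, 0.5)` over all j whose point
  probability is at most that of the observed count (relative tolerance
  1e-7 for floating ties). At p0 = 0.5 this equals doubling the tail. A
  brute-force integer-combinatorics oracle in the test suite confirms
  agreement to 1e-12 for every (k, n) with n <= 200.
* **Ratio-change test** — Yates continuity-corrected chi-square on the
  2x2 allele-count table, `N(|ad-bc| - N/2)^2 / (r1 r2 c1 c2)` with the
  continuity term floored at zero, p from chi-square(1). For 2x2 tables
  this statistic is algebraically identical to the two-proportion test
  with continuity correction, so one code path serves both the cis/trans
  "T test" and the group-assignment comparison. Tables with a zero margin
  are untestable: the gene is flagged, never silently classified.
* **FDR** — Benjamini-Hochberg, one family per (test kind x sample pair)
  across the full testable gene universe; q < alpha = 0.05 throughout
  (configurable). Untestable (NaN) genes are excluded from the family.
* **Range comparison** — two-sample KS with the asymptotic p
  (appropriate at gene-universe n); the report flags p-values below
  2.2e-16, the double-precision floor conventionally printed as an
  inequality, but never truncates the computed value.
* **Enrichment** — upper-tail hypergeometric per annotation term, BH per
  group. Being discrete and one-tailed its null p-values are sub-uniform;
  the Monte-Carlo test asserts the false-positive rate at 0.05 stays in
  [0.01, 0.055].

## Classification rules

With sigP/sigH (bias tests in P and H) and sigT (ratio-change P vs H):
cis-only = sigP & sigH & !sigT; trans-only = sigP & !sigH & sigT;
cis+trans / cis x trans = all three, with concordant / opposite imbalance
direction in P and H; compensatory = !sigP & sigH & sigT; conserved =
none; everything else ambiguous. Direction uses the sign of
`n_count - i_count`, so significant genes sitting near 0.5 are handled
deterministically. Regulation groups: a significant ratio change vs P is
convergent (Group I) when `|fracN - 0.5|` shrinks and divergent (Group II)
when it grows; an exactly tied distance under a significant change implies
a direction flip and is assigned divergent. Inheritance categories are the
3x3 cross of bias states in P and in H/T4 (parental condition, loss of
bias, novel bias, opposite bias).

Note one deliberate asymmetry between generator and classifier: a
simulated opposing-architecture gene (`c*t < 0`) whose residual parental
imbalance keeps the sign of `c` (|t| < |c|) is *correctly* classified
cis+trans by the rules, which are defined on observed directions. Recovery
is therefore asserted only for architectures whose generative definition
matches an observable rule outcome (cis-only, compensatory, conserved,
trans-only).

## Synthetic-data generator

Per gene: base expression `mu ~ lognormal(0, 1)`; effect magnitudes
`|c|, |t| ~ Uniform[0.5, 3]` log2 units with random sign (spanning
just-detectable to strong bias at the reference depth); architectures
apportioned exactly by largest remainder. Totals are gamma-Poisson: a
per-gene factor `lambda ~ Gamma(1/phi, phi)` (mean 1, variance phi) is
drawn once and shared by all samples, and each sample's total is
`Poisson(m * lambda)` with `m = depth * mu / mean(mu)`, giving marginal
negative-binomial totals with variance `m + phi m^2`. Sharing the factor
across samples is intentional: it models gene-level depth variability
without letting library-to-library expression noise masquerade as
regulatory divergence, which keeps the allele-fraction channel
conditionally binomial — the sampling model the exact tests assume — and
makes the ground-truth architecture labels exact. Real parental libraries
do carry independent biological noise; in real data that noise *is* part
of parental divergence and is measured as such, so passing recovery tests
on this generator demonstrates classifier correctness, not robustness to
extra-binomial allele-fraction noise (which the tests deliberately
exclude; a beta-binomial bias test is out of scope).

Parental totals are tilted by `2^(±(c+t)/2)` so the 1:1 in-silico mix
(each parent scaled to the smaller diagnostic-read library, rounded
half-to-even) recovers ratio `2^(c+t)`. Allele counts are
`Binomial(total, expected fraction)`; parental samples are pure
single-genotype reads.

The site-level simulator lays genes on one synthetic chromosome (1.5 kb
exon, 2 kb spacing, `snps_per_gene` evenly spaced SNPs) and emits pileup
summaries in which 93-11 RNA carries the alternative base and Nipponbare
RNA the reference base at fidelity `1 - error_rate`, with all errors
landing on the other diagnostic base (worst case for the filters).
Configurable fractions of SNPs are withheld from the genomic list or
contaminated above the 5% exclusion threshold, to exercise the
intersection and exclusion rules. It does not model alignment artifacts,
mapping bias, or read-level linkage across SNPs.

## Diagnostic-SNP selection and counting

A site is diagnostic when (i) the 93-11 RNA pileup has depth > 10 and alt
fraction > 0.95, (ii) the site appears in the genomic DNA SNP list with
the same alternative base, and (iii) the Nipponbare RNA pileup does *not*
show the alternative base at depth > 10 with fraction > 5%. The exclusion
filter deliberately reuses the same depth floor as the selection filter.
All thresholds are strict inequalities. SNPs inside exons of exactly one
gene are assigned to it; SNPs in overlapping gene models are dropped
(multiple assignment would test the same reads twice). Counting is
per-site summation of allele-matching reads over a gene's SNPs — pileup
summaries carry no read identity, so a read spanning several SNPs
contributes at each; reads matching neither diagnostic base are ignored.
The testable universe keeps genes whose allele total reaches `min_total`
(default 10, configurable) in every analysed sample; no particular
universe size is claimed.

## Defaults and numerics

| parameter | default | meaning |
|---|---|---|
| alpha | 0.05 | q-value threshold for every test family |
| min_total | 10 | per-sample allele-total floor for testability |
| pseudocount | 0.5 | added to both counts for log2 ratios only, never tests |
| depth | 1000 | mean diagnostic reads per gene per sample |
| dispersion | 0.05 | NB overdispersion phi (0 = Poisson) |
| effect range | [0.5, 3] | uniform |c|, |t| magnitudes, log2 |
| w_sd | 0 (1.5 in WGD scenarios) | sd of tetraploid perturbation |
| error_rate | 0.005 | per-base error in site simulation |

`w_sd = 1.5` for the WGD-enabled analyses was fixed analytically, before
measurement, so the three-way range ordering is a property of the
configuration rather than of a lucky seed: with the default effect
distribution, `Var(c+t) - Var(c) ≈ 1.20` (trans variance plus a negative
cis-trans covariance from the opposing/compensatory architectures), so
the tetraploid spread `Var(c) + w_sd^2` exceeds the parental-mix spread
whenever `w_sd > ~1.1`; 1.5 also makes WGD perturbations comparable in
magnitude to the cis/trans effects themselves (mean 1.75).

Rounding is banker's (half-to-even) in the in-silico mix and in the
percentage formatter, which reproduces published count/percentage tables
digit-for-digit. Ties in the group-distance comparison go to divergent
(see above). All generators run on `numpy.random.default_rng` substreams
derived deterministically from the configured seed; identical config and
seed give byte-identical outputs, end to end.

## Problem sizes in the checks

The recovery suite uses 1000 genes per architecture at depth 1000 and
dispersion 0.05 (the reference conditions) and asserts >= 85% cis-only
and compensatory recovery and >= 90% conserved specificity; the range
analyses use 10,000 genes. These sizes give sampling error well below the
asserted margins while keeping the whole suite interactive.

## Known limitations

* The bias test is binomial, not beta-binomial: extra-binomial
  allele-fraction variance in real replicates would inflate significance.
* Pileup-level counting can count one read at several SNPs; with
  read-level data a one-vote-per-read scheme would be preferable.
* The WGD perturbation `w` is phenomenological; nothing anchors its
  distribution to a mechanistic model of dosage disruption.
* KS p-values use the asymptotic distribution; they are not exact at
  small n (irrelevant at gene-universe scale).
* The in-silico mix normalises by diagnostic-site library size, not
  whole-library size, so the 1:1 ratio holds on the reads actually
  analysed.
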