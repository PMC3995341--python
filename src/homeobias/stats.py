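"""Statistical primitives for homoeolog expression-bias analysis.

The layer is purely computational: it consumes scalars/arrays and returns
p-values and statistics. All multiple-testing families are formed by the
callers (one family per test kind and sample pair, across the full gene
universe).

Conventions
-----------
* The 1:1 homoeolog bias test is the exact two-sided binomial test with the
  minimum-likelihood definition of "two-sided": the p-value sums the
  probabilities of all outcomes whose point probability does not exceed that
  of the observed outcome (with a small relative tolerance for floating-point
  ties). At the null probability 0.5 this coincides with doubling the tail.
* Ratio-change tests between two samples use the Yates continuity-corrected
  chi-square statistic on the 2x2 allele-count table; for 2x2 tables this is
  algebraically identical to the two-proportion test with continuity
  correction, so a single code path serves both uses.
* FDR control is Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "binom_exact_two_sided",
    "binom_exact_two_sided_many",
    "yates_chi2_2x2",
    "yates_chi2_2x2_many",
    "bh_adjust",
    "ks_two_sample",
    "hypergeom_enrichment",
    "log2_allelic_ratio",
]

# Relative tolerance when comparing point probabilities for the two-sided sum;
# guards against floating-point noise splitting exactly tied outcomes.
_REL_TOL = 1e-7


def binom_exact_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method).

    Parameters
    ----------
    k : observed successes, 0 <= k <= n.
    n : number of trials, n >= 1.
    p0 : null success probability (default 0.5, the 1:1 test).

    Returns
    -------
    p-value in (0, 1]: the sum of ``pmf(j; n, p0)`` over all ``j`` with
    ``pmf(j) <= pmf(k) * (1 + 1e-7)``, clipped at 1.
    """
    if n < 1:
        raise ValueError("binomial test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    p = pmf[pmf <= pmf[k] * (1.0 + _REL_TOL)].sum()
    return float(min(p, 1.0))


def binom_exact_two_sided_many(
    k: np.ndarray, n: np.ndarray, p0: float = 0.5
) -> np.ndarray:
    """Vectorised :func:`binom_exact_two_sided` over arrays of (k, n).

    Groups calls by unique ``n`` so the pmf for each trial count is computed,
    sorted and accumulated once; each observation is then a binary search.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if k.shape != n.shape:
        raise ValueError("k and n must have matching shapes")
    if np.any((k < 0) | (k > n)):
        raise ValueError("require 0 <= k <= n elementwise")
    out = np.full(k.shape, np.nan, dtype=float)
    for nv in np.unique(n):
        idx = np.nonzero(n == nv)[0]
        if nv < 1:
            raise ValueError("binomial test undefined for n = 0")
        pmf = sps.binom.pmf(np.arange(nv + 1), nv, p0)
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        csum = np.cumsum(sorted_pmf)
        thresh = pmf[k[idx]] * (1.0 + _REL_TOL)
        pos = np.searchsorted(sorted_pmf, thresh, side="right")
        out[idx] = np.where(pos > 0, csum[np.maximum(pos - 1, 0)], 0.0)
    return np.minimum(out, 1.0)


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates continuity-corrected chi-square test on the 2x2 table [[a,b],[c,d]].

    Returns ``(statistic, p)``; ``(nan, nan)`` when any row or column margin is
    zero (the table is untestable and the caller should flag the gene).
    The continuity term ``|ad - bc| - N/2`` is floored at zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return (math.nan, math.nan)
    n_tot = r1 + r2
    num = max(abs(a * d - b * c) - n_tot / 2.0, 0.0)
    stat = n_tot * num * num / (r1 * r2 * c1 * c2)
    return (float(stat), float(sps.chi2.sf(stat, df=1)))


def yates_chi2_2x2_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Yates 2x2 test; NaN where a margin is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n_tot = r1 + r2
    testable = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.maximum(np.abs(a * d - b * c) - n_tot / 2.0, 0.0)
        stat = np.where(testable, n_tot * num * num / (r1 * r2 * c1 * c2), np.nan)
    p = np.where(testable, sps.chi2.sf(stat, df=1), np.nan)
    return stat, p


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries (untestable genes) are excluded from the family and returned
    as NaN; the remaining q-values are mapped back to input order.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic Kolmogorov distribution with effective sample size
    ``n_x * n_y / (n_x + n_y)`` (appropriate at gene-universe scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def hypergeom_enrichment(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``study_genes`` per term.

    Parameters
    ----------
    study_genes : the gene set of interest (must be a subset of the population).
    population_genes : the tested universe.
    term_map : mapping term -> annotated genes; each term's genes are first
        intersected with the population.

    Returns
    -------
    DataFrame with columns ``term, k, K, n, N, p, q`` where k = study hits,
    K = population genes carrying the term, n = study size, N = population
    size; p = P(X >= k) and q is BH-adjusted across all terms with K >= 1.
    """
    population = set(population_genes)
    study = set(study_genes)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    n_study, n_pop = len(study), len(population)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & population
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & study)
        p = float(sps.hypergeom.sf(k - 1, n_pop, big_k, n_study))
        rows.append((term, k, big_k, n_study, n_pop, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df


def log2_allelic_ratio(n_count, i_count, pseudocount: float = 0.5):
    """log2 of the (N allele)/(9 allele) count ratio with a pseudocount.

    Accepts scalars or arrays. The pseudocount is added to both counts; it
    must be positive whenever a raw count is zero (NaN is returned for a
    0/0 cell with pseudocount 0).
    """
    n = np.asarray(n_count, dtype=float)
    i = np.asarray(i_count, dtype=float)
    if np.any(n < 0) or np.any(i < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2((n + pseudocount) / (i + pseudocount))
    r = np.where((n + pseudocount == 0) & (i + pseudocount == 0), np.nan, r)
    if np.ndim(n_count) == 0 and np.ndim(i_count) == 0:
        return float(r)
    return r
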