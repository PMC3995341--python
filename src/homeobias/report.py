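"""Summary reports: category matrices, range comparisons, ratio validation.

Everything here is data-only: boxplot geometry is exported as quantiles and
whiskers, Venn diagrams as region counts, so that every reported number is
testable without rendering a figure.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import INHERITANCE_CATEGORIES, inheritance_label
from .stats import hypergeom_enrichment, ks_two_sample, log2_allelic_ratio

#: double-precision floor below which R itself prints "P < 2.2e-16"
P_FLOOR = 2.2e-16

__all__ = [
    "format_percent",
    "inheritance_matrix",
    "boxplot_stats",
    "compare_ranges",
    "validate_ratios",
    "enrichment_report",
]


def format_percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``decimals`` places.

    This single helper backs every count-plus-percentage cell in the summary
    tables, so the arithmetic convention (round-half-even, like repr of
    printed tables) is uniform across reports.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def inheritance_matrix(
    p_bias: pd.Series, sample_biases: Mapping[str, pd.Series], decimals: int = 2
) -> pd.DataFrame:
    """Nine-category bias-inheritance matrix across samples.

    ``p_bias`` is the parental-mix bias state per gene; ``sample_biases``
    maps each hybrid/tetraploid sample name to its bias states over the same
    universe. Rows are the nine ordered categories; per sample the matrix
    holds the gene count and its percentage of the universe.
    """
    total = len(p_bias)
    rows = []
    for a, b, kind in INHERITANCE_CATEGORIES:
        row: dict = {"category": inheritance_label(a, b), "kind": kind}
        for sample, s_bias in sample_biases.items():
            s = s_bias.reindex(p_bias.index)
            n = int(((p_bias == a) & (s == b)).sum())
            row[f"{sample}_count"] = n
            row[f"{sample}_pct"] = format_percent(n, total, decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def boxplot_stats(x: Sequence[float]) -> dict:
    """Tukey boxplot geometry: quartiles, 1.5*IQR whiskers, outlier count."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "n": int(x.size),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(x.size - inside.size),
    }


def compare_ranges(ratios: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise KS comparison of per-sample log2 allelic-ratio distributions.

    For every unordered sample pair: KS D, asymptotic p, a flag marking
    p below the double-precision floor (printed as "< 2.2e-16" by
    convention), and each sample's variance — the quantities behind a
    range-of-divergence boxplot comparison.
    """
    names = list(ratios)
    if len(names) < 2:
        raise ValueError("need at least two samples to compare ranges")
    clean = {
        k: np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]
        for k, v in ratios.items()
    }
    rows = []
    for a, b in itertools.combinations(names, 2):
        d, p = ks_two_sample(clean[a], clean[b])
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "ks_D": d,
                "ks_p": p,
                "below_floor": p < P_FLOOR,
                "var_a": float(np.var(clean[a])),
                "var_b": float(np.var(clean[b])),
            }
        )
    return pd.DataFrame(rows)


def validate_ratios(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, float]:
    """Least-squares agreement between two per-gene ratio measurements.

    Fits b = slope*a + intercept by OLS over genes finite in both vectors
    and returns ``(slope, intercept, R^2)`` with R^2 the squared Pearson
    correlation — the cross-platform validation statistic for comparing
    e.g. sequencing-based against pyrosequencing-based allelic ratios.
    Returns NaNs when fewer than 3 shared finite points or zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ratio vectors must have matching length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or np.var(a) == 0 or np.var(b) == 0:
        return (float("nan"),) * 3
    fit = sps.linregress(a, b)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def enrichment_report(
    group_sets: Mapping[str, Iterable[str]],
    population: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment for each classified gene group.

    One BH family per group (across its terms); rows with q < alpha carry
    ``significant=True``. Empty groups yield no rows.
    """
    population = set(population)
    frames = []
    for name, genes in group_sets.items():
        study = set(genes)
        if not study:
            continue
        df = hypergeom_enrichment(study, population, term_map)
        df.insert(0, "group", name)
        df["significant"] = df["q"] < alpha
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["group", "term", "k", "K", "n", "N", "p", "q", "significant"]
        )
    return pd.concat(frames, ignore_index=True)
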