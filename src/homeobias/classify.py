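"""Gene-level regulatory classifications.

Four classifications, all driven by the allele-count tables and the exact
tests in :mod:`homeobias.stats`:

* **Bias call** per gene and sample: Nipponbare-biased, 93-11-biased, or
  equal, from the exact binomial 1:1 test with BH-FDR across the sample's
  full gene universe (q < alpha).
* **cis/trans divergence type** per gene, from the bias tests in the
  parental mix (P) and a hybrid (H) plus the Yates 2x2 ratio-change test
  between them (T): cis-only, trans-only, cis+trans (reinforcing),
  cis x trans (opposing), compensatory, conserved, or ambiguous.
* **Regulation group** per gene and (hybrid or tetraploid) sample:
  convergent (I), divergent (II) or conserved (III) regulation, from the
  ratio-change test against the parental mix and the absolute distance of
  the N-allele fraction from 0.5.
* **Inheritance category** per gene and sample pair: the 3x3 cross of the
  parental-mix bias state with the hybrid/tetraploid bias state.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import bh_adjust, binom_exact_two_sided_many, yates_chi2_2x2_many

N_BIASED, I_BIASED, EQUAL = "N_BIASED", "I_BIASED", "EQUAL"
BIAS_STATES = (N_BIASED, I_BIASED, EQUAL)

CIS_ONLY = "CIS_ONLY"
TRANS_ONLY = "TRANS_ONLY"
CIS_PLUS_TRANS = "CIS_PLUS_TRANS"
CIS_BY_TRANS = "CIS_BY_TRANS"
COMPENSATORY = "COMPENSATORY"
CONSERVED = "CONSERVED"
AMBIGUOUS = "AMBIGUOUS"
REG_DIV_TYPES = (
    CIS_ONLY,
    TRANS_ONLY,
    CIS_PLUS_TRANS,
    CIS_BY_TRANS,
    COMPENSATORY,
    CONSERVED,
    AMBIGUOUS,
)

GROUP_I = "GROUP_I_CONVERGENT"
GROUP_II = "GROUP_II_DIVERGENT"
GROUP_III = "GROUP_III_CONSERVED"
REG_GROUPS = (GROUP_I, GROUP_II, GROUP_III)

#: the nine inheritance categories, ordered as conventionally tabulated:
#: parental condition x3, loss of bias x2, novel bias x2, opposite bias x2.
INHERITANCE_CATEGORIES = (
    ("EQUAL", "EQUAL", "parental_condition"),
    ("N_BIASED", "N_BIASED", "parental_condition"),
    ("I_BIASED", "I_BIASED", "parental_condition"),
    ("N_BIASED", "EQUAL", "no_bias"),
    ("I_BIASED", "EQUAL", "no_bias"),
    ("EQUAL", "N_BIASED", "novel_bias"),
    ("EQUAL", "I_BIASED", "novel_bias"),
    ("N_BIASED", "I_BIASED", "opposite_bias"),
    ("I_BIASED", "N_BIASED", "opposite_bias"),
)

_SYMBOL = {"N_BIASED": "N>9", "I_BIASED": "N<9", "EQUAL": "N=9"}

__all__ = [
    "BIAS_STATES",
    "REG_DIV_TYPES",
    "REG_GROUPS",
    "INHERITANCE_CATEGORIES",
    "call_bias",
    "classify_cis_trans",
    "classify_group",
    "classify_inheritance",
    "inheritance_label",
    "wgd_affected",
    "venn_counts",
    "inherited_proportion",
    "novel_proportion",
]


def _as_counts(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene_id", "n_count", "i_count"):
        if col not in df.columns:
            raise ValueError(f"count table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ValueError("count table must have one row per gene (single sample)")
    return df


def call_bias(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene homoeolog bias call for one sample.

    ``counts`` has one row per gene (``gene_id, n_count, i_count``); the BH
    family is all genes in the table. Genes with zero total are untestable:
    they are returned EQUAL with p = q = 1 and ``low_coverage`` set.

    Returns ``gene_id, n_count, i_count, p, q, bias, low_coverage``.
    """
    df = _as_counts(counts).copy()
    n = df["n_count"].to_numpy(np.int64)
    i = df["i_count"].to_numpy(np.int64)
    total = n + i
    p = np.ones(len(df))
    ok = total > 0
    p[ok] = binom_exact_two_sided_many(n[ok], total[ok], 0.5)
    q = bh_adjust(p)
    bias = np.where(
        (q < alpha) & (n != i), np.where(n > i, N_BIASED, I_BIASED), EQUAL
    )
    df["p"], df["q"], df["bias"] = p, q, bias
    df["low_coverage"] = ~ok
    df.loc[~ok, ["p", "q"]] = 1.0
    return df


def _direction(n: np.ndarray, i: np.ndarray) -> np.ndarray:
    """Sign of the allelic imbalance (+1 toward N, -1 toward 9, 0 equal)."""
    return np.sign(n - i)


def classify_cis_trans(
    P: pd.DataFrame, H: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Assign each gene one of the seven cis/trans regulatory-divergence types.

    ``P`` is the parental-mix (in-silico hybrid) count table and ``H`` a true
    hybrid, both one row per gene over the same universe. Three tests feed
    the rules, each BH-adjusted over the full universe:

    * sigP — 1:1 binomial test in P (parental expression divergence),
    * sigH — 1:1 binomial test in H (cis divergence),
    * sigT — Yates 2x2 test of the P vs H allele ratio (trans divergence).

    Rules: cis only = sigP & sigH & !sigT; trans only = sigP & !sigH & sigT;
    cis+trans / cis x trans = all three significant with concordant /
    opposite imbalance directions in P and H; compensatory = !sigP & sigH &
    sigT; conserved = none significant; everything else ambiguous. Direction
    concordance uses the sign of (n_count - i_count), so significant genes
    sitting near 0.5 are handled deterministically. Genes whose 2x2 table
    has a zero margin are untestable in T and fall to ambiguous (flagged).
    """
    P = _as_counts(P)
    H = _as_counts(H)
    merged = P.merge(H, on="gene_id", suffixes=("_P", "_H"), how="inner")
    if len(merged) != len(P) or len(merged) != len(H):
        raise ValueError("P and H must cover the same gene universe")

    bias_P = call_bias(P, alpha).set_index("gene_id")
    bias_H = call_bias(H, alpha).set_index("gene_id")
    merged = merged.set_index("gene_id")
    q_P = bias_P.loc[merged.index, "q"].to_numpy()
    q_H = bias_H.loc[merged.index, "q"].to_numpy()

    nP = merged["n_count_P"].to_numpy(np.int64)
    iP = merged["i_count_P"].to_numpy(np.int64)
    nH = merged["n_count_H"].to_numpy(np.int64)
    iH = merged["i_count_H"].to_numpy(np.int64)
    stat_T, p_T = yates_chi2_2x2_many(nP, iP, nH, iH)
    q_T = bh_adjust(p_T)

    sigP = q_P < alpha
    sigH = q_H < alpha
    sigT = q_T < alpha
    untestable_T = np.isnan(p_T)
    same_dir = _direction(nP, iP) == _direction(nH, iH)

    cat = np.full(len(merged), AMBIGUOUS, dtype=object)
    cat[sigP & sigH & ~sigT & ~untestable_T] = CIS_ONLY
    cat[sigP & ~sigH & sigT] = TRANS_ONLY
    cat[sigP & sigH & sigT & same_dir] = CIS_PLUS_TRANS
    cat[sigP & sigH & sigT & ~same_dir] = CIS_BY_TRANS
    cat[~sigP & sigH & sigT] = COMPENSATORY
    cat[~sigP & ~sigH & ~sigT & ~untestable_T] = CONSERVED

    return pd.DataFrame(
        {
            "gene_id": merged.index,
            "q_P": q_P,
            "q_H": q_H,
            "stat_T": stat_T,
            "q_T": q_T,
            "sigP": sigP,
            "sigH": sigH,
            "sigT": sigT,
            "untestable_T": untestable_T,
            "category": cat,
        }
    ).reset_index(drop=True)


def classify_group(
    P: pd.DataFrame, S: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Convergent / divergent / conserved regulation per gene.

    ``S`` is a hybrid or tetraploid sample. The Yates 2x2 test compares the
    allele ratio of S against the parental mix P (BH over the universe).
    Non-significant genes are Group III (conserved regulation). Significant
    genes move to Group I (convergent) when the distance of the N fraction
    from 0.5 shrinks relative to P, and to Group II (divergent) when it
    grows; an exactly equal distance with a significant change implies a
    direction flip and counts as divergent. Genes with a zero total in
    either sample are reported Group III with ``untestable`` set.
    """
    P = _as_counts(P)
    S = _as_counts(S)
    merged = P.merge(S, on="gene_id", suffixes=("_P", "_S"), how="inner")
    if len(merged) != len(P) or len(merged) != len(S):
        raise ValueError("P and S must cover the same gene universe")
    nP = merged["n_count_P"].to_numpy(np.int64)
    iP = merged["i_count_P"].to_numpy(np.int64)
    nS = merged["n_count_S"].to_numpy(np.int64)
    iS = merged["i_count_S"].to_numpy(np.int64)
    stat, p = yates_chi2_2x2_many(nP, iP, nS, iS)
    q = bh_adjust(p)

    totP, totS = nP + iP, nS + iS
    untestable = (totP == 0) | (totS == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_P = np.abs(nP / totP - 0.5)
        d_S = np.abs(nS / totS - 0.5)

    sig = (q < alpha) & ~untestable
    group = np.full(len(merged), GROUP_III, dtype=object)
    group[sig & (d_S < d_P)] = GROUP_I
    group[sig & (d_S >= d_P)] = GROUP_II
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "stat": stat,
            "p": p,
            "q": q,
            "d_P": d_P,
            "d_S": d_S,
            "group": group,
            "untestable": untestable,
        }
    )


def classify_inheritance(p_bias: pd.Series, s_bias: pd.Series) -> pd.DataFrame:
    """Cross the parental-mix bias state with a sample's bias state.

    Both inputs are gene-indexed Series of bias states from
    :func:`call_bias` at the same alpha. Returns ``gene_id, p_bias, s_bias,
    category`` where category is e.g. ``"N>9 -> N=9 (no_bias)"``. The nine
    cells are exhaustive and mutually exclusive.
    """
    if not p_bias.index.equals(s_bias.index):
        s_bias = s_bias.reindex(p_bias.index)
        if s_bias.isna().any():
            raise ValueError("bias series must share a gene universe")
    cat = [inheritance_label(a, b) for a, b in zip(p_bias, s_bias)]
    return pd.DataFrame(
        {
            "gene_id": p_bias.index,
            "p_bias": p_bias.to_numpy(),
            "s_bias": s_bias.to_numpy(),
            "category": cat,
        }
    ).reset_index(drop=True)


def inheritance_label(p_state: str, s_state: str) -> str:
    """Human-readable label of one inheritance cell, e.g. ``"N=9 -> N>9 (novel_bias)"``."""
    for a, b, kind in INHERITANCE_CATEGORIES:
        if (a, b) == (p_state, s_state):
            return f"{_SYMBOL[a]} -> {_SYMBOL[b]} ({kind})"
    raise ValueError(f"unknown bias states ({p_state!r}, {s_state!r})")


def wgd_affected(
    H: pd.DataFrame, T4: pd.DataFrame, alpha: float = 0.05
) -> set[str]:
    """Genes whose homoeolog ratio differs between a hybrid and its tetraploid.

    Direct Yates 2x2 ratio-change test (BH over the shared universe),
    q < alpha. This isolates the effect of genome doubling on top of
    hybridization, since the tetraploid derives from the same hybrid plant.
    """
    res = classify_group(H, T4, alpha)
    sig = (res["q"] < alpha) & ~res["untestable"]
    return set(res.loc[sig, "gene_id"])


def venn_counts(sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Counts of every exclusive membership region among 2-4 named sets.

    Keys are tuples of the member set names for that region (e.g. ("A","B")
    counts elements in A and B but in no other set); regions with the full
    union partition the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts expects 2 to 4 sets")
    as_sets = {k: set(v) for k, v in sets.items()}
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            region = set.intersection(*(as_sets[k] for k in inside))
            for k in names:
                if k not in inside:
                    region -= as_sets[k]
            out[inside] = len(region)
    return out


def inherited_proportion(hybrid_set: Iterable, tetraploid_set: Iterable) -> float:
    """Fraction of a hybrid's group-g genes retained in the matching tetraploid."""
    h, t = set(hybrid_set), set(tetraploid_set)
    if not h:
        return float("nan")
    return len(h & t) / len(h)


def novel_proportion(hybrid_set: Iterable, tetraploid_set: Iterable) -> float:
    """Fraction of a tetraploid's group-g genes absent from the matching hybrid."""
    h, t = set(hybrid_set), set(tetraploid_set)
    if not t:
        return float("nan")
    return len(t - h) / len(t)
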