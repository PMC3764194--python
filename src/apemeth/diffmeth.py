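"""Rank-based differential-methylation statistics.

All between-group calls in the pipeline run through this module: a
Wilcoxon rank-sum test (exact by enumeration for small, tie-free
samples; tie- and continuity-corrected normal approximation otherwise),
Benjamini-Hochberg FDR, the intragenus variance filter, conserved-site
and genus-specific calling across the four great-ape genera, and the
two-species pairwise caller.

A site is called differentially methylated between two groups when the
FDR-adjusted p-value is below ``q_max`` (default 0.05) *and* the mean
beta-value difference is at least ``delta_min`` (default 0.1). The FDR
family is each pairwise comparison, across all probes in the analysis
set.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: the four genera compared in the cross-species analysis
GENERA = ("Human", "Pan", "Gorilla", "Pongo")

#: default significance gates
Q_MAX = 0.05
DELTA_MIN = 0.1
SD_MAX = 0.1

#: largest pooled sample size handled by exact enumeration
EXACT_LIMIT = 16


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _rank_sum_counts(n1: int, n: int) -> np.ndarray:
    """Counts of size-``n1`` subsets of ranks {1..n} by rank sum.

    ``counts[s]`` = number of subsets whose ranks sum to ``s``. Computed
    by dynamic programming; the total is C(n, n1).
    """
    max_s = n1 * (2 * n - n1 + 1) // 2
    dp = np.zeros((n1 + 1, max_s + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    return dp[n1]


@functools.lru_cache(maxsize=None)
def _exact_tail_tables(n1: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(P(W <= w), P(W >= w)) indexed by the rank sum w."""
    counts = _rank_sum_counts(n1, n)
    total = counts.sum()
    lo = np.cumsum(counts) / total
    hi = np.cumsum(counts[::-1])[::-1] / total
    return lo, hi


def _exact_p(w: float, n1: int, n: int) -> float:
    lo, hi = _exact_tail_tables(n1, n)
    w = int(round(w))
    return float(min(1.0, 2.0 * min(lo[w], hi[w])))


def _asymptotic_p(w: float, pooled_sorted: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    u = w - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, t = np.unique(pooled_sorted, return_counts=True)
    tie = float((t.astype(float) ** 3 - t).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 1.0
    d = u - mu
    z = (d - 0.5 * np.sign(d)) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null by full enumeration of rank assignments when the pooled
    sample size is at most 16 and the data carry no ties; otherwise a
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values not allowed; drop them first")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_LIMIT and not has_ties:
        return _exact_p(w, n1, n)
    return _asymptotic_p(w, np.sort(pooled), n1, n2)


def wilcoxon_many(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for matrices ``X`` (m x n1)
    and ``Y`` (m x n2), same branch rules as :func:`wilcoxon_rank_sum`.

    Rows containing NaN yield NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    n = n1 + n2
    pooled = np.hstack([X, Y])
    valid = ~np.isnan(pooled).any(axis=1)
    p = np.full(pooled.shape[0], np.nan)
    if not valid.any():
        return p
    pv = pooled[valid]
    ranks = stats.rankdata(pv, axis=1)
    W = ranks[:, :n1].sum(axis=1)
    srt = np.sort(pv, axis=1)
    tied = (np.diff(srt, axis=1) == 0).any(axis=1)
    out = np.empty(pv.shape[0])
    if n <= EXACT_LIMIT:
        lo, hi = _exact_tail_tables(n1, n)
        idx = np.rint(W).astype(int)
        out = np.minimum(1.0, 2.0 * np.minimum(lo[idx], hi[idx]))
    else:
        tied[:] = True  # route every row through the normal branch
    for i in np.nonzero(tied)[0]:
        out[i] = _asymptotic_p(W[i], srt[i], n1, n2)
    p[valid] = out
    return p


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Comparison machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """Container for one pairwise group comparison (a table of probes)."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: p_value, q_value, delta_beta, significant


def compare_groups(
    betas: pd.DataFrame,
    samples_a,
    samples_b,
    name_a: str = "a",
    name_b: str = "b",
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
) -> ComparisonResult:
    """Per-probe Wilcoxon + BH-FDR comparison of two sample groups.

    ``betas`` is probes x samples. Significance is the conjunction
    q < q_max AND |mean_a - mean_b| >= delta_min. Probes with fewer
    than 2 non-missing values in either group get NaN statistics.
    """
    A = betas[list(samples_a)].to_numpy(dtype=float)
    B = betas[list(samples_b)].to_numpy(dtype=float)
    p = wilcoxon_many(A, B)
    # probes with missing values: test on available samples if >=2 per side
    bad = np.isnan(p)
    for i in np.nonzero(bad)[0]:
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if a.size >= 2 and b.size >= 2:
            p[i] = wilcoxon_rank_sum(a, b)
    q = bh_fdr(p)
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    significant = (q < q_max) & (np.abs(delta) >= delta_min)
    significant &= ~np.isnan(q)
    table = pd.DataFrame(
        {
            "p_value": p,
            "q_value": q,
            "delta_beta": delta,
            "significant": significant,
        },
        index=betas.index,
    )
    return ComparisonResult(name_a, name_b, table)


def _genus_samples(sheet: pd.DataFrame) -> dict[str, list]:
    if "genus" not in sheet.columns:
        raise ValueError("sample sheet needs a 'genus' column")
    return {g: list(sheet.index[sheet["genus"] == g]) for g in sheet["genus"].unique()}


def pairwise_genus_comparisons(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
) -> dict[tuple[str, str], ComparisonResult]:
    """All six pairwise comparisons among the four genera."""
    groups = _genus_samples(sheet)
    missing = [g for g in GENERA if g not in groups]
    if missing:
        raise ValueError(f"missing genera in sample sheet: {missing}")
    out = {}
    for a, b in itertools.combinations(GENERA, 2):
        out[(a, b)] = compare_groups(
            betas, groups[a], groups[b], a, b, q_max=q_max, delta_min=delta_min
        )
    return out


def intragenus_variance_filter(
    betas: pd.DataFrame, sheet: pd.DataFrame, sd_max: float = SD_MAX
) -> tuple[pd.Index, dict[str, int]]:
    """Retain probes with sample SD (ddof=1) strictly below ``sd_max``
    within every genus; report per-genus removal counts.

    A probe is counted as removed "in genus g" when its SD in g is
    >= sd_max (a probe can count toward several genera).
    """
    groups = _genus_samples(sheet)
    keep = np.ones(betas.shape[0], dtype=bool)
    removed: dict[str, int] = {}
    for g, samples in groups.items():
        sd = betas[samples].std(axis=1, ddof=1).to_numpy()
        high = sd >= sd_max
        removed[g] = int(high.sum())
        keep &= ~high
    return betas.index[keep], removed


def call_conserved(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    comparisons: dict | None = None,
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
) -> pd.Index:
    """Probes conserved across all genera: every pairwise comparison has
    q > q_max and |delta beta| < delta_min (both strict)."""
    comparisons = comparisons or pairwise_genus_comparisons(betas, sheet, q_max, delta_min)
    ok = np.ones(betas.shape[0], dtype=bool)
    for res in comparisons.values():
        t = res.table
        ok &= (t["q_value"] > q_max).to_numpy() & (
            t["delta_beta"].abs() < delta_min
        ).to_numpy()
    return betas.index[ok]


def call_genus_specific(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    comparisons: dict | None = None,
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
) -> pd.DataFrame:
    """Genus-specific differential-methylation calls.

    A probe is specific to genus g when all three comparisons of g
    against the other genera are significant. Probes matching no genus
    or more than one get call 'other'. Returns a DataFrame with a
    'call' column over the probes of ``betas``.
    """
    comparisons = comparisons or pairwise_genus_comparisons(betas, sheet, q_max, delta_min)
    sig = {
        pair: res.table["significant"].to_numpy() for pair, res in comparisons.items()
    }
    calls = np.full(betas.shape[0], "other", dtype=object)
    hits = np.zeros(betas.shape[0], dtype=int)
    for g in GENERA:
        mask = np.ones(betas.shape[0], dtype=bool)
        for pair, s in sig.items():
            if g in pair:
                mask &= s
        hits += mask
        calls[mask] = g.lower()
    calls[hits != 1] = "other"
    return pd.DataFrame({"call": calls}, index=betas.index)


def call_pairwise_dm(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = "species",
    sd_max: float = SD_MAX,
    q_max: float = Q_MAX,
    delta_min: float = DELTA_MIN,
) -> pd.DataFrame:
    """Two-species differential methylation (e.g. human vs chimpanzee).

    Probes with SD >= sd_max within either group are excluded before
    testing; the rest get the standard q/delta significance rule plus a
    direction ('hyper' when group_a is more methylated, else 'hypo').
    """
    samples_a = list(sheet.index[sheet[group_col] == group_a])
    samples_b = list(sheet.index[sheet[group_col] == group_b])
    sd_a = betas[samples_a].std(axis=1, ddof=1)
    sd_b = betas[samples_b].std(axis=1, ddof=1)
    kept = betas.index[(sd_a < sd_max) & (sd_b < sd_max)]
    res = compare_groups(
        betas.loc[kept], samples_a, samples_b, group_a, group_b, q_max, delta_min
    )
    table = res.table.copy()
    table["direction"] = np.where(table["delta_beta"] > 0, "hyper", "hypo")
    return table
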