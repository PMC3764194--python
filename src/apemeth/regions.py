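"""Spatial clustering of differentially methylated sites and the
permutation / distributional tests built on it.

A differentially methylated region is a maximal run of >= ``min_sites``
DM probes on one chromosome with consecutive probes at most
``max_gap`` (default 1000 bp, inclusive) apart. Clustering excess and
positional (gene-centric / CpG-island-centric) enrichment are assessed
against permutation nulls drawn without replacement from the analysis
universe; the beta-value distribution of DM sites is compared with the
genome-wide background by a two-sample KS test, and heterogeneity of
per-lineage change counts by a Poisson likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAX_GAP = 1000
MIN_SITES = 2


@dataclass(frozen=True)
class DMRegion:
    chrom: str
    start: int
    end: int
    probe_ids: tuple
    lineage: str = ""
    genes: tuple = ()


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed_fraction: float
    null_fraction: float
    ratio: float
    p_value: float


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_dm_sites(
    sites: pd.DataFrame,
    max_gap: int = MAX_GAP,
    min_sites: int = MIN_SITES,
    lineage: str = "",
) -> list[DMRegion]:
    """Chain DM probes into regions by single-linkage along each
    chromosome (gap <= max_gap, inclusive; runs with >= min_sites kept).

    ``sites`` has columns ``chrom`` and ``pos`` and is indexed by probe
    id; input order is irrelevant (sorted internally) and chaining
    never crosses chromosomes.
    """
    regions: list[DMRegion] = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                if i - start >= min_sites:
                    regions.append(
                        DMRegion(
                            chrom=str(chrom),
                            start=int(pos[start]),
                            end=int(pos[i - 1]),
                            probe_ids=tuple(ids[start:i]),
                            lineage=lineage,
                        )
                    )
                start = i
    return regions


def _count_clusters_sorted(pos: np.ndarray, max_gap: int, min_sites: int) -> int:
    """Cluster count for sorted positions (chromosomes pre-offset so
    cross-chromosome gaps always exceed max_gap)."""
    if pos.size < min_sites:
        return 0
    close = np.diff(pos) <= max_gap
    # count runs of >= (min_sites - 1) consecutive True values
    padded = np.concatenate([[False], close, [False]])
    starts = np.nonzero(~padded[:-1] & padded[1:])[0]
    ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
    return int(((ends - starts) >= (min_sites - 1)).sum())


def _encode_positions(sites: pd.DataFrame, max_gap: int) -> np.ndarray:
    """Map (chrom, pos) to a single coordinate line with inter-chromosome
    spacers wider than max_gap, preserving within-chromosome gaps."""
    out = np.empty(len(sites), dtype=np.int64)
    offset = 0
    k = 0
    for _, sub in sites.groupby("chrom", sort=True):
        p = np.sort(sub["pos"].to_numpy(np.int64))
        out[k : k + len(p)] = p - (p[0] if len(p) else 0) + offset
        k += len(p)
        if len(p):
            offset = out[k - 1] + 10 * max_gap + 1
    return out[:k]


def permutation_cluster_test(
    universe: pd.DataFrame,
    n_dm: int,
    observed_cluster_count: int,
    n_perm: int = 10000,
    seed: int | None = None,
    max_gap: int = MAX_GAP,
    min_sites: int = MIN_SITES,
):
    """Permutation p-value for the observed number of DM clusters.

    Draws ``n_dm`` sites without replacement from the universe,
    counts clusters, and reports p = (#{null >= observed} + 1) /
    (n_perm + 1) together with the null counts.
    """
    if n_dm > len(universe):
        raise ValueError("n_dm exceeds universe size")
    rng = np.random.default_rng(seed)
    line = np.sort(_encode_positions(universe, max_gap))
    null = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        sample = rng.choice(line, size=n_dm, replace=False)
        sample.sort()
        null[t] = _count_clusters_sorted(sample, max_gap, min_sites)
    p = (int((null >= observed_cluster_count).sum()) + 1) / (n_perm + 1)
    return p, null


# ---------------------------------------------------------------------------
# positional enrichment
# ---------------------------------------------------------------------------

def positional_enrichment(
    dm_ids,
    universe: pd.Series,
    n_perm: int = 10000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Category enrichment of DM sites against the tested universe.

    ``universe`` maps probe id -> category (one annotation scheme, e.g.
    gene-centric or island-centric classes); ``dm_ids`` is a subset of
    its index. For each category the observed DM fraction is compared
    with fractions from resampling |dm| probes without replacement,
    with a two-sided +1-corrected permutation p-value and the ratio
    observed / null mean.
    """
    dm_ids = pd.Index(dm_ids)
    if len(dm_ids) == 0:
        raise ValueError("no DM sites to test")
    if not dm_ids.isin(universe.index).all():
        raise ValueError("dm sites must belong to the universe")
    cats = pd.Categorical(universe)
    codes = cats.codes
    k = len(cats.categories)
    m = len(dm_ids)
    obs = np.bincount(codes[universe.index.get_indexer(dm_ids)], minlength=k) / m

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, k))
    n = len(universe)
    for t in range(n_perm):
        pick = rng.choice(n, size=m, replace=False)
        null[t] = np.bincount(codes[pick], minlength=k) / m

    out = []
    for j, cat in enumerate(cats.categories):
        lo = int((null[:, j] <= obs[j]).sum())
        hi = int((null[:, j] >= obs[j]).sum())
        p = min(1.0, 2.0 * (min(lo, hi) + 1) / (n_perm + 1))
        mean = float(null[:, j].mean())
        ratio = float(obs[j] / mean) if mean > 0 else np.inf
        out.append(EnrichmentResult(str(cat), float(obs[j]), mean, ratio, p))
    return out


# ---------------------------------------------------------------------------
# distribution and rate tests
# ---------------------------------------------------------------------------

def beta_distribution_ks(dm_betas, universe_betas):
    """Two-sample KS comparison of DM-site beta values against the
    background distribution. Returns (D, p)."""
    res = stats.ks_2samp(np.asarray(dm_betas), np.asarray(universe_betas))
    return float(res.statistic), float(res.pvalue)


def branch_rate_lrt(counts, branch_lengths=None):
    """Poisson likelihood-ratio test for rate homogeneity of lineage-
    specific methylation changes.

    H0: counts_i ~ Poisson(lambda * L_i); H1: per-lineage rates.
    The statistic is 2*(logL1 - logL0) = 2 * sum c_i log(c_i / e_i)
    with e_i = L_i * sum(c)/sum(L); df = k - 1; chi-square p-value.
    """
    c = np.asarray(counts, dtype=float)
    if branch_lengths is None:
        L = np.ones_like(c)
    else:
        L = np.asarray(branch_lengths, dtype=float)
    if (L <= 0).any():
        raise ValueError("branch lengths must be positive")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    df = len(c) - 1
    if total == 0:
        return 0.0, df, 1.0
    e = L * total / L.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, c * np.log(c / e), 0.0)
    g = 2.0 * float(terms.sum())
    return g, df, float(stats.chi2.sf(g, df))


# ---------------------------------------------------------------------------
# gene linkage
# ---------------------------------------------------------------------------

def gene_spans(gene_models: pd.DataFrame, upstream: int = 1500) -> pd.DataFrame:
    """Strand-aware extended gene spans: TSS - upstream through the
    3'UTR end (i.e. the transcript end on the coding strand)."""
    gm = gene_models.copy()
    plus = gm["strand"] == "+"
    gm["span_start"] = np.where(plus, gm["tx_start"] - upstream, gm["tx_start"])
    gm["span_end"] = np.where(plus, gm["tx_end"], gm["tx_end"] + upstream)
    gm["span_start"] = gm["span_start"].clip(lower=0)
    return gm


def link_regions_to_genes(
    regions: list[DMRegion],
    gene_models: pd.DataFrame,
    probe_positions: pd.DataFrame,
    upstream: int = 1500,
) -> list[DMRegion]:
    """Attach genes to regions: a gene is linked when its extended span
    overlaps at least one member probe. ``probe_positions`` has columns
    chrom, pos indexed by probe id; coordinates are 0-based half-open.
    """
    gm = gene_spans(gene_models, upstream)
    by_chrom = {c: sub for c, sub in gm.groupby("chrom")}
    linked = []
    for reg in regions:
        genes: list[str] = []
        sub = by_chrom.get(reg.chrom)
        if sub is not None:
            pos = probe_positions.loc[list(reg.probe_ids), "pos"].to_numpy()
            for g in sub.itertuples():
                if ((pos >= g.span_start) & (pos < g.span_end)).any():
                    genes.append(g.gene)
        linked.append(
            DMRegion(
                reg.chrom,
                reg.start,
                reg.end,
                reg.probe_ids,
                reg.lineage,
                tuple(sorted(set(genes))),
            )
        )
    return linked


def genes_with_regions(regions: list[DMRegion]) -> list[str]:
    """Deduplicated, sorted genes linked to any region."""
    out: set[str] = set()
    for r in regions:
        out.update(r.genes)
    return sorted(out)
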