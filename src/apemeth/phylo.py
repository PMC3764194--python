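"""Methylation phylogenetics and sequence divergence.

Pairwise sequence distances are substitution frequencies (per kb) over
gap-free alignment columns; methylation distances are Euclidean
distances between beta profiles (species means or individuals). Trees
are built by neighbor joining with nonparametric bootstrap over probes,
and methylation divergence is regressed on sequence divergence across
the six species pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

GAP_CHARS = set("-.Nn")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def sequence_pairwise_distances(blocks) -> DistanceMatrix:
    """Substitutions per kb between all taxon pairs, pooled over
    alignment blocks, ignoring every column that contains a gap or N.

    ``blocks`` is an iterable of mappings taxon -> aligned sequence
    (equal lengths within a block; all blocks must share taxa).
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no alignment blocks")
    taxa = sorted(blocks[0])
    n = len(taxa)
    diff = np.zeros((n, n))
    total = 0
    for block in blocks:
        if sorted(block) != taxa:
            missing = set(taxa) ^ set(block)
            raise ValueError(f"taxon set mismatch in block: {sorted(missing)}")
        seqs = [str(block[t]).upper() for t in taxa]
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("unequal sequence lengths within a block")
        arr = np.array([list(s) for s in seqs])
        ok = ~np.isin(arr, list(GAP_CHARS)).any(axis=0)
        arr = arr[:, ok]
        total += arr.shape[1]
        for i, j in itertools.combinations(range(n), 2):
            d = int((arr[i] != arr[j]).sum())
            diff[i, j] += d
            diff[j, i] += d
    if total == 0:
        raise ValueError("no gap-free columns")
    return DistanceMatrix(diff / total * 1000.0, ids=taxa)


def methylation_distances(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    level: str = "species",
    group_col: str = "species",
    normalized: bool = False,
) -> DistanceMatrix:
    """Euclidean distances between methylation profiles.

    ``species`` level averages beta per probe within each group first;
    ``individual`` level compares sample columns directly. Probes
    missing in either member of a pair are dropped pairwise and the
    distance rescaled by sqrt(total/used) to stay comparable; with
    ``normalized`` the distance is instead the per-probe RMS difference.
    """
    if level == "species":
        prof = betas.T.groupby(sheet[group_col]).mean().T
    elif level == "individual":
        prof = betas
    else:
        raise ValueError("level must be 'species' or 'individual'")
    labels = list(prof.columns)
    X = prof.to_numpy(dtype=float)
    n_total = X.shape[0]
    m = len(labels)
    D = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        diff = X[:, i] - X[:, j]
        used = ~np.isnan(diff)
        n_used = int(used.sum())
        if n_used == 0:
            raise ValueError(f"no shared probes between {labels[i]} and {labels[j]}")
        ss = float(np.sum(diff[used] ** 2))
        if normalized:
            d = np.sqrt(ss / n_used)
        else:
            d = np.sqrt(ss) * np.sqrt(n_total / n_used)
        D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids=labels)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Exact on additive matrices. Negative branch lengths are floored at
    0 with the deficit transferred to the sister edge. Ties in the
    Q-criterion break deterministically by (label-ordered) pair. The
    returned tree is unrooted, represented with a trifurcating root for
    >= 3 taxa.
    """
    if isinstance(dm, DistanceMatrix):
        labels = list(dm.ids)
        D = dm.data.astype(float).copy()
    else:
        raise TypeError("expected skbio DistanceMatrix")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    if (D < 0).any() or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric and non-negative")

    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            li, lj = 0.0, D[i, j]
        elif lj < 0:
            lj, li = 0.0, D[i, j]
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent = TreeNode(children=[ni, nj])
        newd = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final star of three
    (a, b, c) = range(3)
    la = max(0.0, (D[a, b] + D[a, c] - D[b, c]) / 2)
    lb = max(0.0, (D[a, b] + D[b, c] - D[a, c]) / 2)
    lc = max(0.0, (D[a, c] + D[b, c] - D[a, b]) / 2)
    for node, l in zip(nodes, (la, lb, lc)):
        node.length = float(l)
    return TreeNode(children=list(nodes))


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized
    as the side *not* containing the alphabetically first taxon."""
    taxa = frozenset(t.name for t in tree.tips())
    first = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if first in side:
            side = taxa - side
        parts.add(side)
    return parts


def bootstrap_supports(
    betas: pd.DataFrame,
    sheet: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    level: str = "species",
    group_col: str = "species",
) -> TreeNode:
    """Neighbor-joining tree with probe-bootstrap supports.

    Probes (characters) are resampled with replacement ``n_boot``
    times; each reference bipartition's support is the percentage of
    replicate trees containing it, stored as the internal node name.
    """
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(methylation_distances(betas, sheet, level, group_col))
    counts = {part: 0 for part in tree_bipartitions(tree)}
    n_probes = betas.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_probes, size=n_probes)
        bt = neighbor_joining(
            methylation_distances(betas.iloc[idx], sheet, level, group_col)
        )
        for part in tree_bipartitions(bt):
            if part in counts:
                counts[part] += 1
    taxa = frozenset(t.name for t in tree.tips())
    first = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        key = side if first not in side else taxa - side
        node.name = str(int(round(100.0 * counts[key] / n_boot)))
    return tree


def regress_divergences(meth_dm: DistanceMatrix, seq_dm: DistanceMatrix):
    """OLS of methylation distance on sequence distance over the
    unordered species pairs. Returns (slope, intercept, r_squared, p).
    """
    ids = sorted(set(meth_dm.ids) & set(seq_dm.ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 shared taxa")
    xs, ys = [], []
    for a, b in itertools.combinations(ids, 2):
        xs.append(seq_dm[a, b])
        ys.append(meth_dm[a, b])
    fit = stats.linregress(xs, ys)
    return fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue
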