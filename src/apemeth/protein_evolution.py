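"""Promoter methylation change versus protein-coding evolution.

For two species (the human-chimpanzee contrast), each 1:1 ortholog is
flagged as promoter-differentially-methylated when the mean |delta
beta| of its two most affected promoter probes (within 1,500 bp
upstream of the TSS, the 5'UTR or the first exon) is at least 0.1.
Genes shorter than 150 or longer than 1,500 amino acids are excluded.
Amino-acid change counts and the KA/KI ratio (amino-acid-changing
substitution rate relative to the local intergenic/intronic rate) are
then compared between DM and non-DM genes with a label-permutation
test. Genes with zero amino-acid changes but a DM promoter form the
"conserved protein, divergent promoter" set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AA_MIN = 150
AA_MAX = 1500
PROMOTER_DELTA = 0.1
MIN_PROMOTER_PROBES = 2


def length_filter(records: pd.DataFrame, aa_min: int = AA_MIN, aa_max: int = AA_MAX) -> pd.DataFrame:
    """Keep orthologs with aa_min <= aa_length <= aa_max (inclusive)."""
    keep = (records["aa_length"] >= aa_min) & (records["aa_length"] <= aa_max)
    return records[keep]


def promoter_dm_genes(
    dm_table: pd.DataFrame,
    promoter_probes: pd.DataFrame,
    delta_min: float = PROMOTER_DELTA,
    min_probes: int = MIN_PROMOTER_PROBES,
) -> pd.Series:
    """Promoter differential-methylation flag per gene.

    ``dm_table`` carries per-probe ``delta_beta`` (indexed by probe
    id); ``promoter_probes`` maps genes to their promoter probes
    (columns gene, probe_id). A gene is DM when the mean of its two
    largest |delta beta| values is >= ``delta_min``; genes with fewer
    than ``min_probes`` measured promoter probes are not evaluable and
    are excluded (neither DM nor non-DM). Ties in |delta| rank break by
    probe id.
    """
    merged = promoter_probes.merge(
        dm_table[["delta_beta"]], left_on="probe_id", right_index=True, how="inner"
    )
    merged["abs_delta"] = merged["delta_beta"].abs()
    merged = merged.sort_values(["abs_delta", "probe_id"], ascending=[False, True])
    flags = {}
    for gene, sub in merged.groupby("gene"):
        if len(sub) < min_probes:
            continue
        flags[gene] = bool(sub["abs_delta"].iloc[:2].mean() >= delta_min)
    return pd.Series(flags, dtype=bool, name="promoter_dm")


def permutation_group_diff(
    values,
    dm_labels,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided label-permutation test for a difference in group means.

    Returns (observed mean difference DM minus non-DM, p) with the +1
    permutation correction.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(dm_labels, dtype=bool)
    if v.shape != lab.shape:
        raise ValueError("values and labels must align")
    n_dm = int(lab.sum())
    if n_dm == 0 or n_dm == v.size:
        raise ValueError("both groups must be non-empty")
    obs = float(v[lab].mean() - v[~lab].mean())
    rng = np.random.default_rng(seed)
    total = v.sum()
    n = v.size
    hits = 0
    for _ in range(n_perm):
        pick = rng.choice(n, size=n_dm, replace=False)
        s = v[pick].sum()
        d = s / n_dm - (total - s) / (n - n_dm)
        if abs(d) >= abs(obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return obs, p


def conserved_protein_dm_genes(records: pd.DataFrame, dm_flags: pd.Series) -> list[str]:
    """Genes with zero amino-acid changes yet a DM promoter."""
    zero = records.loc[records["aa_changes"] == 0, "gene"]
    dm = set(dm_flags.index[dm_flags])
    return sorted(g for g in zero if g in dm)


def association_report(
    records: pd.DataFrame,
    dm_flags: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Run the full association analysis on length-filtered orthologs.

    Restricts to evaluable genes, tests aa_changes and ka_ki for a DM
    vs non-DM group difference, and lists conserved-protein/DM-promoter
    genes.
    """
    recs = records[records["gene"].isin(dm_flags.index)].copy()
    dropped = len(records) - len(recs)
    lab = dm_flags.reindex(recs["gene"]).to_numpy(dtype=bool)
    d_aa, p_aa = permutation_group_diff(recs["aa_changes"], lab, n_perm, seed)
    d_ka, p_ka = permutation_group_diff(
        recs["ka_ki"], lab, n_perm, None if seed is None else seed + 1
    )
    return {
        "n_genes": int(len(recs)),
        "n_dm": int(lab.sum()),
        "n_not_dm": int((~lab).sum()),
        "n_dropped_unmeasured": int(dropped),
        "aa_changes_diff": d_aa,
        "aa_changes_p": p_aa,
        "ka_ki_diff": d_ka,
        "ka_ki_p": p_ka,
        "conserved_protein_dm_genes": conserved_protein_dm_genes(recs, dm_flags),
    }
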