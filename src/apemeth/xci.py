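"""X-chromosome inactivation analysis.

On the X chromosome, the inactive X of females inflates methylation at
CpGs subject to inactivation, so female-male beta contrasts are
positive at most X-linked sites. Lineage-specific shifts in
inactivation status (escape candidates) are sites where exactly one
lineage shows no sex difference (|delta| < 0.1) while every other
species shows a clear one (delta > 0.1). Input betas must come from
the sex-stratified normalization path (no BMIQ).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import diffmeth

DELTA_THRESHOLD = 0.1


def _assert_x_only(chrom: pd.Series | None, index: pd.Index):
    if chrom is None:
        return
    c = chrom.reindex(index)
    bad = c[~c.isin(["chrX", "X"])]
    if len(bad):
        raise ValueError(f"autosomal probes passed to the X analysis: {list(bad.index[:5])}")


def sex_contrasts(
    betas_x: pd.DataFrame,
    sheet: pd.DataFrame,
    chrom: pd.Series | None = None,
    group_col: str = "species",
    test: bool = False,
) -> pd.DataFrame:
    """Per-species female-minus-male mean beta per probe.

    Returns a long table (probe_id, species, delta, n_female, n_male,
    evaluable); species with fewer than 2 individuals of either sex are
    flagged not evaluable (delta NaN). With ``test`` a Wilcoxon q-value
    per species is added.
    """
    _assert_x_only(chrom, betas_x.index)
    out = []
    for sp, sub in sheet.groupby(group_col):
        females = [s for s in sub.index if sub.loc[s, "sex"] == "F"]
        males = [s for s in sub.index if sub.loc[s, "sex"] == "M"]
        nf, nm = len(females), len(males)
        evaluable = nf >= 2 and nm >= 2
        if evaluable:
            delta = (
                betas_x[females].mean(axis=1) - betas_x[males].mean(axis=1)
            ).to_numpy()
        else:
            delta = np.full(betas_x.shape[0], np.nan)
        tbl = pd.DataFrame(
            {
                "probe_id": betas_x.index,
                "species": sp,
                "delta": delta,
                "n_female": nf,
                "n_male": nm,
                "evaluable": evaluable,
            }
        )
        if test and evaluable:
            p = diffmeth.wilcoxon_many(
                betas_x[females].to_numpy(), betas_x[males].to_numpy()
            )
            tbl["q_value"] = diffmeth.bh_fdr(p)
        out.append(tbl)
    return pd.concat(out, ignore_index=True)


def call_lineage_xci_shift(
    contrasts: pd.DataFrame,
    delta_threshold: float = DELTA_THRESHOLD,
    require_test: bool = False,
    q_max: float = 0.05,
) -> dict[str, pd.Index]:
    """Lineage-specific XCI-shift candidates.

    A probe is assigned to lineage g iff |delta_g| < threshold while
    delta_s > threshold for every other species (exactly one lineage
    may satisfy this). With ``require_test`` the other species must
    additionally pass the Wilcoxon q-gate (needs contrasts built with
    ``test=True``).
    """
    wide = contrasts.pivot(index="probe_id", columns="species", values="delta")
    species = list(wide.columns)
    if wide.isna().any().any():
        wide = wide.dropna()
    qwide = None
    if require_test:
        if "q_value" not in contrasts.columns:
            raise ValueError("contrasts lack q_value; rerun sex_contrasts(test=True)")
        qwide = contrasts.pivot(index="probe_id", columns="species", values="q_value")
        qwide = qwide.loc[wide.index]
    out: dict[str, pd.Index] = {}
    for g in species:
        others = [s for s in species if s != g]
        mask = (wide[g].abs() < delta_threshold) & (
            wide[others].gt(delta_threshold).all(axis=1)
        )
        if qwide is not None:
            mask &= qwide[others].lt(q_max).all(axis=1)
        out[g] = wide.index[mask]
    # exactly-one-lineage rule
    counts = pd.Series(0, index=wide.index)
    for ids in out.values():
        counts[ids] += 1
    multi = counts.index[counts > 1]
    return {g: ids.difference(multi) for g, ids in out.items()}


def female_hypermeth_fraction(
    contrasts: pd.DataFrame, species: str | None = None
) -> tuple[float, float]:
    """Fraction of evaluable probes more methylated in females, with an
    exact two-sided binomial test against 0.5.

    ``species=None`` pools the per-species contrasts of all evaluable
    species; probes with delta exactly 0 are excluded.
    """
    sub = contrasts[contrasts["evaluable"]]
    if species is not None:
        sub = sub[sub["species"] == species]
    delta = sub["delta"].dropna()
    delta = delta[delta != 0]
    n = len(delta)
    if n == 0:
        raise ValueError("no evaluable contrasts")
    k = int((delta > 0).sum())
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return k / n, float(res.pvalue)
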