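"""Cross-species probe retention rules for the 450K array.

The array's 50 bp probes were designed on the human reference, so in
each non-human species a probe is kept only when its binding site is
essentially intact: a perfect match, or 1-2 mismatches confined to the
first 45 bp with the 5 bp adjacent to the assayed CpG clean, and no
C>T loss of the assayed CpG itself. Population SNPs near the 3' end
(human MAF >= 0.05; species MAF >= 0.15), or more than two common
species SNPs anywhere in the first 45 bp, also disqualify a probe.
Probe positions are indexed 1-50 from the 5' end; position 50 is the
base adjacent to the assayed CpG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import diffmeth

PROBE_LEN = 50
THREE_PRIME = frozenset(range(46, 51))  # the 3' 5 bp closest to the CpG
MAX_MISMATCH = 2
HUMAN_MAF = 0.05
SPECIES_MAF = 0.15
MAX_SPECIES_SNPS_5PRIME = 2
DETECTION_P = 0.01


class Reason(str, Enum):
    perfect = "perfect"
    tolerated_mismatch = "tolerated_mismatch"
    drop_unmapped = "drop_unmapped"
    drop_3prime = "drop_3prime"
    drop_excess_mismatch = "drop_excess_mismatch"
    drop_cpg_ct = "drop_cpg_ct"
    drop_human_snp = "drop_human_snp"
    drop_species_snp_3prime = "drop_species_snp_3prime"
    drop_species_snp_count = "drop_species_snp_count"


@dataclass(frozen=True)
class MappingHit:
    """One probe's alignment against one species' genome.

    ``n_mismatch`` is -1 for unmapped probes (no hit within edit
    distance 3, or multiple equally good hits). ``cpg_ct_flag`` marks a
    C>T change of the assayed CpG site itself.
    """

    probe_id: str
    species: str
    n_mismatch: int
    mismatch_positions: frozenset = field(default_factory=frozenset)
    cpg_ct_flag: bool = False

    def __post_init__(self):
        pos = frozenset(self.mismatch_positions)
        object.__setattr__(self, "mismatch_positions", pos)
        if any(not (1 <= p <= PROBE_LEN) for p in pos):
            raise ValueError(f"mismatch positions outside 1..{PROBE_LEN}: {sorted(pos)}")
        if self.n_mismatch >= 0 and len(pos) != self.n_mismatch:
            raise ValueError(
                f"{self.probe_id}: n_mismatch={self.n_mismatch} but "
                f"{len(pos)} positions given"
            )


@dataclass(frozen=True)
class FilterDecision:
    probe_id: str
    species: str
    keep: bool
    reason: Reason
    perfect_match: bool = False


def classify_probe_mapping(hit: MappingHit) -> FilterDecision:
    """Apply the mapping-based retention rule to one probe/species hit.

    Keep iff mapped AND n_mismatch <= 2 AND no mismatch in positions
    46-50 AND the assayed CpG is intact. ``perfect_match`` marks the
    zero-mismatch subset used for the replicate analyses.
    """
    pid, sp = hit.probe_id, hit.species
    if hit.n_mismatch < 0:
        return FilterDecision(pid, sp, False, Reason.drop_unmapped)
    if hit.cpg_ct_flag:
        return FilterDecision(pid, sp, False, Reason.drop_cpg_ct)
    if hit.mismatch_positions & THREE_PRIME:
        return FilterDecision(pid, sp, False, Reason.drop_3prime)
    if hit.n_mismatch > MAX_MISMATCH:
        return FilterDecision(pid, sp, False, Reason.drop_excess_mismatch)
    if hit.n_mismatch == 0:
        return FilterDecision(pid, sp, True, Reason.perfect, perfect_match=True)
    return FilterDecision(pid, sp, True, Reason.tolerated_mismatch)


def apply_snp_filters(
    probe_id: str,
    human_snps: pd.DataFrame | None,
    species_snps: pd.DataFrame | None,
    species: str = "",
) -> FilterDecision:
    """SNP-based retention rule for one probe.

    ``human_snps`` / ``species_snps`` are tables with columns
    ``position`` (probe coordinates 1..50) and ``maf`` for this probe.
    Drop if any human SNP MAF >= 0.05 in positions 46-50, any species
    SNP MAF >= 0.15 there, or more than two species SNPs MAF >= 0.15 in
    positions 1-45.
    """
    def _check(df):
        if df is None or len(df) == 0:
            return np.empty(0, int), np.empty(0, float)
        pos = df["position"].to_numpy(int)
        maf = df["maf"].to_numpy(float)
        if ((maf < 0) | (maf > 0.5)).any():
            raise ValueError("MAF outside [0, 0.5]")
        if ((pos < 1) | (pos > PROBE_LEN)).any():
            raise ValueError("SNP position outside probe coordinates 1..50")
        return pos, maf

    hpos, hmaf = _check(human_snps)
    spos, smaf = _check(species_snps)
    if ((hmaf >= HUMAN_MAF) & (hpos >= 46)).any():
        return FilterDecision(probe_id, species, False, Reason.drop_human_snp)
    if ((smaf >= SPECIES_MAF) & (spos >= 46)).any():
        return FilterDecision(probe_id, species, False, Reason.drop_species_snp_3prime)
    if int(((smaf >= SPECIES_MAF) & (spos <= 45)).sum()) > MAX_SPECIES_SNPS_5PRIME:
        return FilterDecision(probe_id, species, False, Reason.drop_species_snp_count)
    return FilterDecision(probe_id, species, True, Reason.perfect, perfect_match=True)


def classify_mapping_table(mapping: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`classify_probe_mapping` over a mapping
    report with columns probe_id, species, n_mismatch, positions
    (comma-separated 1-based ints, empty for none), cpg_ct_flag."""
    rows = []
    for r in mapping.itertuples(index=False):
        pos = frozenset(
            int(p) for p in str(getattr(r, "positions", "") or "").split(",") if p
        )
        hit = MappingHit(r.probe_id, r.species, int(r.n_mismatch), pos, bool(r.cpg_ct_flag))
        d = classify_probe_mapping(hit)
        rows.append((d.probe_id, d.species, d.keep, d.reason.value, d.perfect_match))
    return pd.DataFrame(
        rows, columns=["probe_id", "species", "keep", "reason", "perfect_match"]
    )


def snp_filter_table(
    probe_ids,
    human_snps: pd.DataFrame,
    species_snps: pd.DataFrame,
    species: str,
) -> pd.DataFrame:
    """SNP decisions for every probe id; SNP tables carry columns
    probe_id, position, maf (and species for the species table)."""
    hgrp = dict(tuple(human_snps.groupby("probe_id"))) if len(human_snps) else {}
    ssub = species_snps[species_snps["species"] == species] if len(species_snps) else species_snps
    sgrp = dict(tuple(ssub.groupby("probe_id"))) if len(ssub) else {}
    rows = []
    for pid in probe_ids:
        d = apply_snp_filters(pid, hgrp.get(pid), sgrp.get(pid), species)
        rows.append((pid, species, d.keep, d.reason.value))
    return pd.DataFrame(rows, columns=["probe_id", "species", "keep", "reason"])


def detection_mask(detection_p: pd.DataFrame, p_max: float = DETECTION_P) -> pd.DataFrame:
    """Per-probe, per-sample missingness mask (True = masked/excluded).

    Masking is per individual: a probe failing detection in one sample
    remains usable in the others.
    """
    return detection_p > p_max


def fully_masked(mask: pd.DataFrame) -> pd.Index:
    """Probes masked in every sample (flagged for removal from shared sets)."""
    return mask.index[mask.all(axis=1)]


def celltype_filter(
    wb: pd.DataFrame,
    cd4: pd.DataFrame,
    cd16: pd.DataFrame,
    q_max: float = 0.05,
    delta_min: float = 0.1,
) -> pd.Index:
    """Probes differentially methylated between whole blood and either
    CD4+ T-cells or CD16+ neutrophils (q < 0.05 AND |delta beta| >= 0.1);
    the union is removed to guard against cell-composition confounding.
    """
    for name, df in (("cd4", cd4), ("cd16", cd16)):
        if not wb.index.equals(df.index):
            raise ValueError(f"{name} probes do not match whole blood")
        if wb.shape[1] < 2 or df.shape[1] < 2:
            raise ValueError("need >=2 samples per group")
    removed = pd.Index([])
    for other in (cd4, cd16):
        merged = pd.concat([wb, other], axis=1)
        res = diffmeth.compare_groups(
            merged, wb.columns, other.columns, q_max=q_max, delta_min=delta_min
        )
        removed = removed.union(res.table.index[res.table["significant"]])
    return removed


def shared_probe_sets(
    decisions: pd.DataFrame,
    snp_decisions: pd.DataFrame,
    scope: str = "all_species",
    celltype_removed=None,
    human_species: str = "Human",
    chimp_species: str = "Pan",
) -> pd.Index:
    """Build the cross-species comparable probe sets.

    ``decisions`` is the concatenated mapping-decision table over all
    non-human species; ``snp_decisions`` the SNP-decision analogue
    (human-SNP rule included for every species). Scopes:

    - ``all_species``: probes kept in every non-human species, minus
      SNP-dropped and cell-type-removed probes.
    - ``human_chimp``: same but requiring only the chimp lineage.
    - ``perfect_only``: the all-species set restricted to probes with a
      perfect match in every species.
    """
    if celltype_removed is None:
        celltype_removed = pd.Index([])
    species = [s for s in decisions["species"].unique() if s != human_species]
    if scope == "human_chimp":
        species = [chimp_species]
    elif scope not in ("all_species", "perfect_only"):
        raise ValueError(f"unknown scope {scope!r}")

    kept = None
    for sp in species:
        sub = decisions[decisions["species"] == sp]
        ids = sub.loc[sub["keep"].astype(bool), "probe_id"]
        if scope == "perfect_only":
            ids = sub.loc[
                sub["keep"].astype(bool) & sub["perfect_match"].astype(bool), "probe_id"
            ]
        ids = pd.Index(ids)
        kept = ids if kept is None else kept.intersection(ids)
    if kept is None:
        kept = pd.Index([])

    if len(snp_decisions):
        dropped = pd.Index(
            snp_decisions.loc[~snp_decisions["keep"].astype(bool), "probe_id"].unique()
        )
        kept = kept.difference(dropped)
    return kept.difference(pd.Index(celltype_removed)).sort_values()
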