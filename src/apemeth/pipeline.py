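"""End-to-end orchestration of the comparative-methylation pipeline.

``run_pipeline`` executes the stages in dependency order on a fully
synthetic cohort — simulate inputs, probe filtering, normalization,
genus-level differential methylation, region/enrichment statistics,
methylation phylogenetics, X-inactivation analysis, and the
promoter-methylation vs protein-evolution association — writing every
stage's outputs into a run directory with a checksummed manifest. A
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    diffmeth,
    io,
    normalization,
    phylo,
    probe_filter,
    protein_evolution,
    regions,
    synthetic_data,
    xci,
)

PROMOTER_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon")


@dataclass
class RunConfig:
    """Pipeline configuration. Thresholds default to the study values
    (SD filter 0.1, |delta beta| 0.1, q 0.05, 1 kb / 2-site clustering,
    10,000 cluster permutations, 1,000 association permutations and
    bootstraps); simulation sizes are deliberately desk-scale."""

    seed: int = 1
    # simulation
    n_probes: int = 3000
    n_per_taxon: int = 6
    n_dm: int = 240
    dm_delta: float = 0.3
    clustered_frac: float = 0.5
    n_xci_escape: int = 10
    noise_sd: float = 0.05
    drift_k: float = 0.3
    tree_scale: float = 1.0
    ortholog_coupling: float = 1.0
    # thresholds
    sd_max: float = 0.1
    delta_beta: float = 0.1
    q_max: float = 0.05
    max_gap: int = 1000
    min_sites: int = 2
    n_perm_cluster: int = 10000
    n_perm_enrich: int = 1000
    n_perm_assoc: int = 1000
    n_boot: int = 1000

    def validate(self):
        checks = [
            0 < self.sd_max <= 1,
            0 < self.delta_beta <= 1,
            0 < self.q_max < 1,
            self.max_gap > 0,
            self.min_sites >= 1,
            self.n_perm_cluster >= 1,
            self.n_perm_assoc >= 1,
            self.n_boot >= 1,
            self.n_probes >= 100,
            self.n_per_taxon >= 2,
            self.noise_sd > 0,
        ]
        if not all(checks):
            raise ValueError("invalid pipeline configuration")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data).validate()


def _stage_seed(config: RunConfig, idx: int) -> int:
    """Independent per-stage substream of the global seed."""
    h = hashlib.sha256(f"{config.seed}:{idx}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def export_gene_lists(foreground: dict[str, list], background: list, outdir: Path, meta):
    """Foreground/background gene-list text files for external
    enrichment tools; the background always contains the foreground."""
    outdir.mkdir(parents=True, exist_ok=True)
    bg = sorted(set(background) | {g for gl in foreground.values() for g in gl})
    io.write_probe_list(bg, outdir / "background_genes.txt", meta)
    for name, gl in sorted(foreground.items()):
        io.write_probe_list(sorted(set(gl)), outdir / f"{name}_genes.txt", meta)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; returns a summary dict (also written as
    summary.json). Fails fast with the stage name on any error."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": io.config_hash(asdict(config)), "seed": config.seed}
    summary: dict = {"config": asdict(config)}

    stage = "simulate"
    try:
        tree = synthetic_data.great_ape_tree(config.tree_scale)
        manifest, gene_models, islands = synthetic_data.simulate_manifest(
            config.n_probes, seed=_stage_seed(config, 0)
        )
        planted = synthetic_data.PlantedConfig(
            n_dm=config.n_dm,
            dm_delta=config.dm_delta,
            clustered_frac=config.clustered_frac,
            n_xci_escape=config.n_xci_escape,
        )
        betas_true, sheet, truth = synthetic_data.simulate_betas(
            tree,
            manifest,
            n_per_taxon=config.n_per_taxon,
            planted=planted,
            noise_sd=config.noise_sd,
            drift_k=config.drift_k,
            seed=_stage_seed(config, 1),
        )
        M, U = synthetic_data.simulate_signals(
            betas_true, manifest, seed=_stage_seed(config, 2)
        )
        det_p = synthetic_data.simulate_detection_p(
            betas_true, seed=_stage_seed(config, 3)
        )
        mapping, human_snps, species_snps = synthetic_data.simulate_mapping_and_snps(
            manifest, seed=_stage_seed(config, 4)
        )
        wb, cd4, cd16, ct_truth = synthetic_data.simulate_blood_reference(
            manifest, seed=_stage_seed(config, 5)
        )
        blocks, seq_truth = synthetic_data.simulate_alignment_blocks(
            tree, length=5000, rate=1.0, indel_rate=0.01, seed=_stage_seed(config, 6)
        )
        sim = outdir / "simulate"
        io.write_table(manifest, sim / "manifest.tsv", meta=meta)
        io.write_table(gene_models, sim / "gene_models.tsv", meta=meta, index=False)
        io.write_table(islands, sim / "islands.tsv", meta=meta, index=False)
        io.write_table(sheet, sim / "sample_sheet.csv", sep=",", meta=meta)
        io.write_table(betas_true, sim / "betas_true.tsv", meta=meta)
        io.write_table(M, sim / "signals_M.tsv", meta=meta)
        io.write_table(U, sim / "signals_U.tsv", meta=meta)
        io.write_table(det_p, sim / "detection_p.tsv", meta=meta)
        io.write_table(mapping, sim / "mapping.tsv", meta=meta, index=False)
        io.write_table(human_snps, sim / "human_snps.tsv", meta=meta, index=False)
        io.write_table(species_snps, sim / "species_snps.tsv", meta=meta, index=False)
        io.write_fasta_blocks(blocks, sim / "alignments.fasta")
        io.write_json(
            {
                "dm_sites": truth.dm_sites.to_dict("records"),
                "xci_escape": truth.xci_escape_sites.to_dict("records"),
                "celltype_dm": list(map(str, ct_truth)),
            },
            sim / "planted_truth.json",
            meta,
        )

        stage = "filter"
        decisions = probe_filter.classify_mapping_table(mapping)
        snp_parts = []
        for sp in decisions["species"].unique():
            snp_parts.append(
                probe_filter.snp_filter_table(manifest.index, human_snps, species_snps, sp)
            )
        snp_decisions = pd.concat(snp_parts, ignore_index=True)
        removed_ct = probe_filter.celltype_filter(wb, cd4, cd16, config.q_max, config.delta_beta)
        mask = probe_filter.detection_mask(det_p)
        dead = probe_filter.fully_masked(mask)
        shared = {}
        for scope in ("all_species", "human_chimp", "perfect_only"):
            s = probe_filter.shared_probe_sets(
                decisions, snp_decisions, scope, celltype_removed=removed_ct
            ).difference(dead)
            shared[scope] = s
        filt = outdir / "filter"
        io.write_table(decisions, filt / "mapping_decisions.tsv", meta=meta, index=False)
        io.write_table(snp_decisions, filt / "snp_decisions.tsv", meta=meta, index=False)
        for scope, ids in shared.items():
            io.write_probe_list(ids, filt / f"shared_{scope}.txt", meta)
        io.write_probe_list(removed_ct, filt / "celltype_removed.txt", meta)
        summary["n_shared"] = {k: int(len(v)) for k, v in shared.items()}
        summary["n_celltype_removed"] = int(len(removed_ct))

        stage = "normalize"
        is_x = manifest["chrom"] == "chrX"
        auto_ids = shared["all_species"].intersection(manifest.index[~is_x])
        x_ids = shared["all_species"].intersection(manifest.index[is_x])
        hc_ids = shared["human_chimp"].intersection(manifest.index[~is_x])
        betas_auto = normalization.normalize_cohort(
            M.loc[auto_ids], U.loc[auto_ids], manifest, sheet
        )
        betas_auto[mask.loc[auto_ids, betas_auto.columns]] = np.nan
        betas_x = normalization.normalize_cohort(
            M.loc[x_ids], U.loc[x_ids], manifest, sheet, stratify_by_sex=True
        )
        hc_samples = sheet.index[sheet["genus"].isin(["Human", "Pan"])]
        betas_hc = normalization.normalize_cohort(
            M.loc[hc_ids, hc_samples], U.loc[hc_ids, hc_samples], manifest,
            sheet.loc[hc_samples],
        )
        norm = outdir / "normalize"
        io.write_table(betas_auto, norm / "betas_autosomal.tsv", meta=meta)
        io.write_table(betas_x, norm / "betas_chrX.tsv", meta=meta)
        io.write_table(betas_hc, norm / "betas_human_chimp.tsv", meta=meta)

        stage = "diffmeth"
        retained, removal = diffmeth.intragenus_variance_filter(
            betas_auto, sheet, config.sd_max
        )
        bet = betas_auto.loc[retained]
        comparisons = diffmeth.pairwise_genus_comparisons(
            bet, sheet, config.q_max, config.delta_beta
        )
        calls = diffmeth.call_genus_specific(bet, sheet, comparisons)
        conserved = diffmeth.call_conserved(bet, sheet, comparisons)
        dm = outdir / "diffmeth"
        io.write_table(calls, dm / "genus_calls.tsv", meta=meta)
        io.write_probe_list(conserved, dm / "conserved_sites.txt", meta)
        for (a, b), res in comparisons.items():
            io.write_table(res.table, dm / f"comparison_{a}_{b}.tsv", meta=meta)
        counts = {
            g.lower(): int((calls["call"] == g.lower()).sum()) for g in diffmeth.GENERA
        }
        summary["variance_removed"] = removal
        summary["n_retained"] = int(len(retained))
        summary["genus_dm_counts"] = counts
        summary["n_conserved"] = int(len(conserved))

        stage = "regions"
        universe_sites = manifest.loc[retained, ["chrom", "pos"]]
        all_regions = []
        cluster_stats = {}
        for g in diffmeth.GENERA:
            ids = calls.index[calls["call"] == g.lower()]
            if not len(ids):
                cluster_stats[g] = {"n_sites": 0, "n_clusters": 0, "p": 1.0}
                continue
            regs = regions.cluster_dm_sites(
                manifest.loc[ids, ["chrom", "pos"]],
                config.max_gap,
                config.min_sites,
                lineage=g.lower(),
            )
            regs = regions.link_regions_to_genes(
                regs, gene_models, manifest[["chrom", "pos"]]
            )
            all_regions.extend(regs)
            p, _ = regions.permutation_cluster_test(
                universe_sites,
                len(ids),
                len(regs),
                config.n_perm_cluster,
                _stage_seed(config, 10),
                config.max_gap,
                config.min_sites,
            )
            cluster_stats[g] = {"n_sites": int(len(ids)), "n_clusters": len(regs), "p": p}
        dm_union = calls.index[calls["call"] != "other"]
        enrich = {}
        for scheme, col in (("gene_centric", "gene_class"), ("island_centric", "island_class")):
            if not len(dm_union):
                enrich[scheme] = []
                continue
            res = regions.positional_enrichment(
                dm_union,
                manifest.loc[retained, col],
                config.n_perm_enrich,
                _stage_seed(config, 11),
            )
            enrich[scheme] = [vars(e) for e in res]
        mean_beta = bet.mean(axis=1)
        ks_d, ks_p = regions.beta_distribution_ks(
            mean_beta.loc[dm_union], mean_beta
        ) if len(dm_union) else (0.0, 1.0)
        lrt_counts = [counts[g.lower()] for g in diffmeth.GENERA]
        lrt_stat, lrt_df, lrt_p = regions.branch_rate_lrt(lrt_counts)
        reg = outdir / "regions"
        io.write_table(
            pd.DataFrame(
                [
                    (
                        r.chrom,
                        r.start,
                        r.end,
                        r.lineage,
                        ",".join(r.probe_ids),
                        ",".join(r.genes),
                    )
                    for r in all_regions
                ],
                columns=["chrom", "start", "end", "lineage", "probes", "genes"],
            ),
            reg / "dm_regions.tsv",
            meta=meta,
            index=False,
        )
        io.write_json(cluster_stats, reg / "cluster_permutation.json", meta)
        io.write_json(enrich, reg / "enrichment.json", meta)
        io.write_json(
            {"ks_D": ks_d, "ks_p": ks_p, "lrt_stat": lrt_stat, "lrt_df": lrt_df, "lrt_p": lrt_p},
            reg / "distribution_tests.json",
            meta,
        )
        foreground = {
            g.lower(): [gene for r in all_regions if r.lineage == g.lower() for gene in r.genes]
            for g in diffmeth.GENERA
        }
        background = sorted(set(manifest.loc[retained, "gene"]) - {""})
        export_gene_lists(foreground, background, outdir / "gene_lists", meta)
        summary["cluster_stats"] = cluster_stats
        summary["ks"] = {"D": ks_d, "p": ks_p}
        summary["lrt"] = {"stat": lrt_stat, "df": lrt_df, "p": lrt_p}
        summary["n_regions"] = len(all_regions)
        summary["genes_with_regions"] = {
            k: len(set(v)) for k, v in foreground.items()
        }

        stage = "phylo"
        meth_dm = phylo.methylation_distances(betas_auto, sheet, "species")
        tree_boot = phylo.bootstrap_supports(
            betas_auto, sheet, config.n_boot, _stage_seed(config, 12)
        )
        seq_dm = phylo.sequence_pairwise_distances(blocks)
        slope, intercept, r2, pval = phylo.regress_divergences(meth_dm, seq_dm)
        ph = outdir / "phylo"
        io.write_table(
            pd.DataFrame(meth_dm.data, index=list(meth_dm.ids), columns=list(meth_dm.ids)),
            ph / "methylation_distances.tsv",
            meta=meta,
        )
        io.write_table(
            pd.DataFrame(seq_dm.data, index=list(seq_dm.ids), columns=list(seq_dm.ids)),
            ph / "sequence_distances.tsv",
            meta=meta,
        )
        io.write_newick(tree_boot, ph / "methylation_tree.nwk")
        io.write_json(
            {"slope": slope, "intercept": intercept, "r_squared": r2, "p": pval},
            ph / "divergence_regression.json",
            meta,
        )
        summary["phylo"] = {"r_squared": r2, "p": pval}

        stage = "xci"
        contrasts = xci.sex_contrasts(betas_x, sheet, chrom=manifest["chrom"])
        shifts = xci.call_lineage_xci_shift(contrasts, config.delta_beta)
        frac, bin_p = xci.female_hypermeth_fraction(contrasts)
        xd = outdir / "xci"
        io.write_table(contrasts, xd / "sex_contrasts.tsv", meta=meta, index=False)
        io.write_json(
            {k: list(map(str, v)) for k, v in shifts.items()}, xd / "xci_shifts.json", meta
        )
        io.write_json(
            {"female_hyper_fraction": frac, "binomial_p": bin_p},
            xd / "female_hypermethylation.json",
            meta,
        )
        summary["xci"] = {
            "female_hyper_fraction": frac,
            "binomial_p": bin_p,
            "shift_counts": {k: int(len(v)) for k, v in shifts.items()},
        }

        stage = "protein_evolution"
        hc_table = diffmeth.call_pairwise_dm(
            betas_hc, sheet.loc[hc_samples], "Human", "Pan", "genus",
            config.sd_max, config.q_max, config.delta_beta,
        )
        promoter = manifest[
            (manifest["gene"] != "") & manifest["gene_class"].isin(PROMOTER_CLASSES)
        ]
        promoter = promoter[promoter.index.isin(hc_table.index)]
        promoter_map = pd.DataFrame(
            {"gene": promoter["gene"].to_numpy(), "probe_id": promoter.index.to_numpy()}
        )
        dm_flags = protein_evolution.promoter_dm_genes(
            hc_table, promoter_map, config.delta_beta
        )
        planted_hc = set(
            truth.dm_sites.loc[
                truth.dm_sites["lineage"].isin(["Human", "Pan"]), "probe_id"
            ]
        )
        planted_genes = sorted(
            set(promoter.loc[promoter.index.isin(planted_hc), "gene"])
        )
        orthologs = synthetic_data.simulate_orthologs(
            list(gene_models["gene"]),
            coupling=config.ortholog_coupling,
            seed=_stage_seed(config, 13),
            dm_genes=planted_genes,
        )
        filtered = protein_evolution.length_filter(orthologs)
        report = protein_evolution.association_report(
            filtered, dm_flags, config.n_perm_assoc, _stage_seed(config, 14)
        )
        pe = outdir / "protein_evolution"
        io.write_table(hc_table, pe / "human_chimp_dm.tsv", meta=meta)
        io.write_table(orthologs, pe / "orthologs.csv", sep=",", meta=meta, index=False)
        io.write_table(dm_flags.to_frame(), pe / "promoter_dm_flags.tsv", meta=meta)
        io.write_json(report, pe / "association.json", meta)
        summary["protein_evolution"] = {
            k: report[k]
            for k in ("n_genes", "n_dm", "aa_changes_p", "ka_ki_p")
        }
        summary["n_hc_dm_sites"] = int(hc_table["significant"].sum())
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    io.write_json(summary, outdir / "summary.json", meta)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "run_manifest.json"
    )
    run_manifest = {
        str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in files
    }
    io.write_json(run_manifest, outdir / "run_manifest.json", meta)
    return summary
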