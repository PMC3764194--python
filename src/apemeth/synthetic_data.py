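"""Synthetic data generator with planted truth.

Emulates every input the comparative-methylation pipeline consumes:
a probe manifest with gene-centric and CpG-island-centric annotation,
phylogenetically structured beta values for the four great-ape genera
(Human, Pan, Gorilla, Pongo) with planted lineage-specific effects and
X-linked sex effects, raw signal intensities with a type II design
bias, per-species probe-mapping reports and SNP annotations, a blood
cell-type reference, an ortholog table whose protein-evolution rates
can be coupled to planted promoter effects, and multi-species
alignment blocks.

The evolutionary model for methylation is a bounded Gaussian drift:
per-probe ancestral means are drawn from an equal-weight
Beta(0.5, 5) / Beta(5, 0.5) mixture (reproducing the strongly bimodal
genome-wide beta density), and each branch adds N(0, k * sqrt(t))
truncated to [0, 1], with t the branch length in expected
substitutions per site and k = 0.3 by default. Branch lengths default
to the observed great-ape sequence divergences (human-chimp about
0.012 substitutions per site, human-orangutan about 0.031).

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

GENE_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "intergenic")
ISLAND_CLASSES = ("island", "shore", "shelf", "open_sea")
PROBE_LEN = 50
TYPE1_PROB = 0.28  # fraction of type I designs on the array


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class SimNode:
    name: str
    length: float = 0.0
    children: list = field(default_factory=list)

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("branch lengths must be >= 0")


@dataclass
class SimTree:
    """A rooted binary tree over the simulated taxa."""

    root: SimNode

    @property
    def taxa(self) -> list[str]:
        out: list[str] = []

        def walk(n):
            if not n.children:
                out.append(n.name)
            for c in n.children:
                walk(c)

        walk(self.root)
        if len(set(out)) != len(out):
            raise ValueError("taxon labels must be unique")
        return out

    def scaled(self, factor: float) -> "SimTree":
        def walk(n):
            return SimNode(n.name, n.length * factor, [walk(c) for c in n.children])

        return SimTree(walk(self.root))


def great_ape_tree(scale: float = 1.0) -> SimTree:
    """Default ((Human,Pan),Gorilla),Pongo topology with branch lengths
    in expected substitutions per site matching great-ape divergences."""
    root = SimNode(
        "root",
        0.0,
        [
            SimNode(
                "HPG",
                0.0075,
                [
                    SimNode(
                        "HP",
                        0.0035,
                        [SimNode("Human", 0.006), SimNode("Pan", 0.006)],
                    ),
                    SimNode("Gorilla", 0.0065),
                ],
            ),
            SimNode("Pongo", 0.014),
        ],
    )
    return SimTree(root).scaled(scale)


def null_tree() -> SimTree:
    """The same topology with zero-length branches: no evolution, i.e.
    a global null for between-genus differences."""
    return great_ape_tree(scale=0.0)


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedConfig:
    """What to plant. Defaults reflect the study conditions used across
    the test-bench: lineage effects of 0.3 beta, a 60% majority of
    X-linked sites carrying a 0.3 female-hypermethylation effect, and
    escape sites whose focal-lineage sex effect collapses to 0.02."""

    n_dm: int = 0
    dm_delta: float = 0.3
    dm_lineages: tuple | None = None  # cycle over taxa when None
    clustered_frac: float = 0.0
    n_xci_escape: int = 0
    escape_lineage: str = "Human"
    escape_residual: float = 0.02
    sex_effect_frac: float = 0.6
    sex_delta: float = 0.3


@dataclass
class PlantedTruth:
    dm_sites: pd.DataFrame  # probe_id, lineage, delta (signed)
    xci_escape_sites: pd.DataFrame  # probe_id, lineage
    sex_effect_sites: pd.Index
    clustered_dm_sites: pd.Index
    celltype_dm_sites: pd.Index = field(default_factory=lambda: pd.Index([]))
    defective_probes: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _make_genes(rng, chrom_sizes: dict, n_genes: int) -> pd.DataFrame:
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    rows = []
    for i in range(n_genes):
        c = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
        size = chrom_sizes[c]
        tx_len = int(rng.integers(3000, 30000))
        lo, hi = 2000, size - tx_len - 2000
        if hi <= lo:
            raise ValueError(f"chromosome {c} too small for gene models")
        tx_start = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = int(rng.integers(100, 400))
        exon1 = int(rng.integers(100, 500))
        utr3 = int(rng.integers(200, 800))
        rows.append((f"GENE{i:05d}", c, strand, tx_start, tx_start + tx_len, utr5, exon1, utr3))
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "strand", "tx_start", "tx_end", "utr5_len", "exon1_len", "utr3_len"],
    )


def _gene_features(g) -> dict:
    """Strand-aware feature intervals (0-based half-open) of one gene."""
    if g.strand == "+":
        tss = g.tx_start
        return {
            "TSS200": (tss - 200, tss),
            "TSS1500": (tss - 1500, tss - 200),
            "5UTR": (tss, tss + g.utr5_len),
            "1stExon": (tss + g.utr5_len, tss + g.utr5_len + g.exon1_len),
            "3UTR": (g.tx_end - g.utr3_len, g.tx_end),
            "Body": (g.tx_start, g.tx_end),
        }
    tss = g.tx_end
    return {
        "TSS200": (tss, tss + 200),
        "TSS1500": (tss + 200, tss + 1500),
        "5UTR": (tss - g.utr5_len, tss),
        "1stExon": (tss - g.utr5_len - g.exon1_len, tss - g.utr5_len),
        "3UTR": (g.tx_start, g.tx_start + g.utr3_len),
        "Body": (g.tx_start, g.tx_end),
    }


def simulate_manifest(
    n_probes: int,
    chrom_sizes: dict | None = None,
    gene_models: pd.DataFrame | None = None,
    island_spec: pd.DataFrame | None = None,
    seed: int = 0,
    n_genes: int | None = None,
):
    """Generate a probe manifest plus the gene models and CpG-island
    intervals it is annotated against.

    Coordinates are 0-based half-open; a probe's position is the C of
    the assayed CpG. Gene-centric classes follow the seven array
    categories with priority TSS200 > TSS1500 > 5UTR > 1stExon > 3UTR >
    Body; island-centric classes are island / shore (<= 2 kb) / shelf
    (2-4 kb) / open sea. Returns (manifest, gene_models, islands).
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        total = max(n_probes, 100) * 6000
        chrom_sizes = {
            "chr1": int(total * 0.45),
            "chr2": int(total * 0.30),
            "chrX": int(total * 0.25),
        }
    if any(s <= 0 for s in chrom_sizes.values()):
        raise ValueError("chromosome sizes must be positive")

    if gene_models is None:
        n_genes = n_genes if n_genes is not None else max(10, n_probes // 10)
        gene_models = _make_genes(rng, chrom_sizes, n_genes)
    else:
        for g in gene_models.itertuples():
            if g.tx_start < 0 or g.tx_end > chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.gene} exceeds chromosome bounds")

    if island_spec is None:
        rows = []
        for g in gene_models.itertuples():
            if rng.random() < 0.5:
                tss = g.tx_start if g.strand == "+" else g.tx_end
                half = int(rng.integers(250, 1000))
                rows.append((g.chrom, max(0, tss - half), tss + half))
        for c, size in chrom_sizes.items():
            for _ in range(max(1, len(gene_models) // (6 * len(chrom_sizes)))):
                s = int(rng.integers(0, max(1, size - 2000)))
                rows.append((c, s, s + int(rng.integers(300, 2000))))
        island_spec = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # place probes: most near genes (promoter-weighted), the rest uniform
    chroms, positions = [], []
    genes_arr = list(gene_models.itertuples())
    chrom_names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
    for _ in range(n_probes):
        if genes_arr and rng.random() < 0.7:
            g = genes_arr[rng.integers(0, len(genes_arr))]
            tss = g.tx_start if g.strand == "+" else g.tx_end
            off = int(rng.integers(-1700, 2500))  # upstream..into the gene
            pos = tss + (off if g.strand == "+" else -off)
            c = g.chrom
        else:
            c = chrom_names[rng.choice(len(chrom_names), p=sizes / sizes.sum())]
            pos = int(rng.integers(0, chrom_sizes[c]))
        pos = int(np.clip(pos, 0, chrom_sizes[c] - 1))
        chroms.append(c)
        positions.append(pos)

    df = pd.DataFrame({"chrom": chroms, "pos": positions})
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.index = pd.Index([f"cg{i:06d}" for i in range(len(df))], name="probe_id")

    # gene-centric annotation with class priority
    # 3UTR outranks Body (the body span covers the whole transcript)
    priority = {c: i for i, c in enumerate(["TSS200", "TSS1500", "5UTR", "1stExon", "3UTR", "Body"])}
    gene_class = np.full(len(df), "intergenic", dtype=object)
    gene_name = np.full(len(df), "", dtype=object)
    best = np.full(len(df), 99, dtype=int)
    pos_by_chrom = {c: df.index[df["chrom"] == c] for c in chrom_names}
    for g in gene_models.itertuples():
        ids = pos_by_chrom.get(g.chrom)
        if ids is None or not len(ids):
            continue
        p = df.loc[ids, "pos"].to_numpy()
        loc = df.index.get_indexer(ids)
        for cls, (s, e) in _gene_features(g).items():
            inside = (p >= s) & (p < e)
            if not inside.any():
                continue
            pr = priority[cls]
            upd = loc[inside][pr < best[loc[inside]]]
            gene_class[upd] = cls
            gene_name[upd] = g.gene
            best[upd] = pr
    df["gene"] = gene_name
    df["gene_class"] = gene_class

    # island-centric annotation by distance to the nearest island
    island_class = np.full(len(df), "open_sea", dtype=object)
    for c in chrom_names:
        ids = pos_by_chrom[c]
        if not len(ids):
            continue
        p = df.loc[ids, "pos"].to_numpy()
        loc = df.index.get_indexer(ids)
        isl = island_spec[island_spec["chrom"] == c]
        if not len(isl):
            continue
        dist = np.full(len(p), np.inf)
        for i in isl.itertuples():
            d = np.where(
                (p >= i.start) & (p < i.end),
                0,
                np.minimum(np.abs(p - i.start), np.abs(p - (i.end - 1))),
            )
            dist = np.minimum(dist, d)
        cls = np.where(
            dist == 0, "island", np.where(dist <= 2000, "shore", np.where(dist <= 4000, "shelf", "open_sea"))
        )
        island_class[loc] = cls
    df["island_class"] = island_class

    df["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    type1 = rng.random(len(df)) < TYPE1_PROB
    df["design_type"] = np.where(type1, "I", "II")
    chan = np.where(rng.random(len(df)) < 0.5, "red", "green")
    df["channel"] = np.where(type1, chan, "green")
    return df, gene_models, island_spec


# ---------------------------------------------------------------------------
# beta values
# ---------------------------------------------------------------------------

def _reflect01(x: np.ndarray) -> np.ndarray:
    """Fold values back into [0, 1] at the boundaries (reflection
    rather than truncation: measured betas never sit exactly at 0 or
    1, and truncation atoms would create rank ties the assay does not
    produce)."""
    x = np.abs(x)
    x = 1.0 - np.abs(1.0 - x)
    return np.clip(x, 0.0, 1.0)


def _bimodal_means(rng, n: int) -> np.ndarray:
    """Ancestral per-probe means: equal-weight unmethylated/methylated
    modes plus a minor (10%) intermediate fraction, as in genome-wide
    blood beta densities (the intermediate mass also keeps the
    three-state mixture fits identifiable)."""
    u = rng.random(n)
    low = rng.beta(0.5, 5.0, size=n)
    high = rng.beta(5.0, 0.5, size=n)
    mid = rng.beta(5.0, 5.0, size=n)
    return np.where(u < 0.45, low, np.where(u < 0.9, high, mid))


def _evolve_means(rng, tree: SimTree, anc: np.ndarray, drift_k: float) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}

    def walk(node: SimNode, mean: np.ndarray):
        if node.length > 0:
            mean = np.clip(
                mean + rng.normal(0.0, drift_k * np.sqrt(node.length), size=mean.shape),
                0.0,
                1.0,
            )
        if not node.children:
            out[node.name] = mean
        for c in node.children:
            walk(c, mean)

    walk(tree.root, anc.copy())
    return out


def _pick_clustered(manifest: pd.DataFrame, n_sites: int, rng) -> list[str]:
    """Pick DM sites lying in tight (<=1 kb gap) runs of >= 2 probes."""
    auto = manifest[manifest["chrom"] != "chrX"].sort_values(["chrom", "pos"])
    blocks = []
    cur: list[str] = []
    prev_chrom, prev_pos = None, None
    for pid, row in auto.iterrows():
        if prev_chrom == row["chrom"] and row["pos"] - prev_pos <= 1000:
            cur.append(pid)
        else:
            if len(cur) >= 2:
                blocks.append(cur)
            cur = [pid]
        prev_chrom, prev_pos = row["chrom"], row["pos"]
    if len(cur) >= 2:
        blocks.append(cur)
    rng.shuffle(blocks)
    picked: list[str] = []
    for b in blocks:
        if len(picked) >= n_sites:
            break
        picked.extend(b[: max(2, min(len(b), n_sites - len(picked)))])
    return picked[: max(n_sites, 0)]


def simulate_betas(
    tree: SimTree,
    manifest: pd.DataFrame,
    n_per_taxon: int = 6,
    planted: PlantedConfig | None = None,
    noise_sd: float = 0.05,
    drift_k: float = 0.3,
    seed: int = 0,
):
    """Simulate the beta matrix, sample sheet and planted truth.

    Per-probe ancestral means evolve along ``tree`` by truncated
    Gaussian drift; planted lineage effects shift exactly one genus by
    ``dm_delta`` (direction chosen so the shifted mean stays within
    [0, 1]; raises when neither direction fits); X-linked sex effects
    add ``sex_delta`` to females, except at escape sites in the escape
    lineage where only ``escape_residual`` remains. Individual values
    add N(0, noise_sd), truncated to [0, 1].

    Returns (betas, sheet, truth) with betas probes x samples.
    """
    if n_per_taxon < 2:
        raise ValueError("n_per_taxon must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    planted = planted or PlantedConfig()
    rng = np.random.default_rng(seed)
    taxa = tree.taxa
    n_probes = len(manifest)

    anc = _bimodal_means(rng, n_probes)
    means = _evolve_means(rng, tree, anc, drift_k)
    means = {t: means[t].copy() for t in taxa}

    # ---- planted lineage-specific DM sites (autosomal) ----
    is_x = (manifest["chrom"] == "chrX").to_numpy()
    autosomal_ids = manifest.index[~is_x]
    n_clustered = int(round(planted.clustered_frac * planted.n_dm))
    clustered = _pick_clustered(manifest, n_clustered, rng) if n_clustered else []
    remaining = autosomal_ids.difference(pd.Index(clustered))
    n_rest = planted.n_dm - len(clustered)
    if n_rest > len(remaining):
        raise ValueError("not enough autosomal probes to plant DM sites")
    rest = list(rng.choice(remaining.to_numpy(), size=max(n_rest, 0), replace=False))
    dm_ids = list(clustered) + rest
    lineages = planted.dm_lineages or tuple(taxa)
    dm_rows = []
    loc = manifest.index.get_indexer(dm_ids)
    for k, (pid, i) in enumerate(zip(dm_ids, loc)):
        g = lineages[k % len(lineages)]
        m = means[g][i]
        if m + planted.dm_delta <= 1.0:
            delta = planted.dm_delta
        elif m - planted.dm_delta >= 0.0:
            delta = -planted.dm_delta
        else:
            raise ValueError(f"planted effect at {pid} pushes mean outside [0, 1]")
        means[g][i] = m + delta
        dm_rows.append((pid, g, delta))
    dm_sites = pd.DataFrame(dm_rows, columns=["probe_id", "lineage", "delta"])

    # ---- X-linked sex effects and escape sites ----
    x_ids = manifest.index[is_x]
    n_sex = int(round(planted.sex_effect_frac * len(x_ids)))
    sex_ids = pd.Index(
        rng.choice(x_ids.to_numpy(), size=n_sex, replace=False) if n_sex else []
    )
    sex_loc = manifest.index.get_indexer(sex_ids)
    # male baseline kept clear of the upper bound so the female uplift fits
    base = rng.uniform(0.1, 1.0 - planted.sex_delta - 0.05, size=len(sex_ids))
    for t in taxa:
        means[t][sex_loc] = base
    if planted.n_xci_escape > len(sex_ids):
        raise ValueError("more escape sites requested than sex-effect sites")
    escape_ids = pd.Index(
        rng.choice(sex_ids.to_numpy(), size=planted.n_xci_escape, replace=False)
        if planted.n_xci_escape
        else []
    )
    xci_escape = pd.DataFrame(
        {"probe_id": escape_ids, "lineage": planted.escape_lineage}
    )

    # ---- individuals ----
    sex_effect = np.zeros(n_probes)
    sex_effect[sex_loc] = planted.sex_delta
    escape_loc = manifest.index.get_indexer(escape_ids)

    columns, data, rows = [], [], []
    for t in taxa:
        eff = sex_effect.copy()
        if t == planted.escape_lineage and len(escape_loc):
            eff[escape_loc] = planted.escape_residual
        for i in range(n_per_taxon):
            sex = "F" if i % 2 == 0 else "M"
            sid = f"{t}{i + 1:02d}"
            mean = means[t] + (eff if sex == "F" else 0.0)
            vals = _reflect01(mean + rng.normal(0.0, noise_sd, size=n_probes))
            columns.append(sid)
            data.append(vals)
            rows.append((sid, t, t, sex))
    betas = pd.DataFrame(np.column_stack(data), index=manifest.index, columns=columns)
    sheet = pd.DataFrame(rows, columns=["sample", "species", "genus", "sex"]).set_index(
        "sample"
    )
    truth = PlantedTruth(
        dm_sites=dm_sites,
        xci_escape_sites=xci_escape,
        sex_effect_sites=sex_ids,
        clustered_dm_sites=pd.Index(clustered),
    )
    return betas, sheet, truth


# ---------------------------------------------------------------------------
# signal intensities
# ---------------------------------------------------------------------------

def type2_distortion(beta: np.ndarray, gamma: float = 0.7) -> np.ndarray:
    """Compressive distortion of type II designs: a symmetric power
    squash that fixes 0, 0.5 and 1 but pulls the bimodal extremes
    toward the middle (gamma < 1)."""
    b = np.clip(np.asarray(beta, float), 0.0, 1.0)
    num = b**gamma
    return num / (num + (1.0 - b) ** gamma)


def simulate_signals(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    seed: int = 0,
    mean_intensity: float = 5000.0,
    background: float = 200.0,
    noise_frac: float = 0.02,
    gamma: float = 0.7,
):
    """Methylated/unmethylated intensities whose beta recomputation
    (default offset, after background subtraction) recovers the input
    within tolerance; type II probes carry the compressive distortion
    so BMIQ has work to do. Returns (M, U)."""
    rng = np.random.default_rng(seed)
    b = betas.to_numpy(dtype=float)
    is2 = (manifest["design_type"].reindex(betas.index) == "II").to_numpy()
    b = b.copy()
    b[is2] = type2_distortion(b[is2], gamma)
    A = rng.lognormal(np.log(mean_intensity), 0.3, size=(b.shape[0], 1))
    M = background + A * b * (1 + rng.normal(0, noise_frac, size=b.shape))
    U = background + A * (1 - b) * (1 + rng.normal(0, noise_frac, size=b.shape))
    M = np.maximum(M + rng.normal(0, 3.0, size=b.shape), 1.0)
    U = np.maximum(U + rng.normal(0, 3.0, size=b.shape), 1.0)
    return (
        pd.DataFrame(M, index=betas.index, columns=betas.columns),
        pd.DataFrame(U, index=betas.index, columns=betas.columns),
    )


def simulate_detection_p(
    betas: pd.DataFrame, fail_rate: float = 0.005, seed: int = 0
) -> pd.DataFrame:
    """Per-probe, per-sample detection p-values: overwhelmingly tiny,
    with a ``fail_rate`` fraction of failures above the 0.01 cutoff."""
    rng = np.random.default_rng(seed)
    shape = betas.shape
    p = rng.uniform(1e-8, 0.005, size=shape)
    fail = rng.random(shape) < fail_rate
    p[fail] = rng.uniform(0.02, 0.5, size=int(fail.sum()))
    return pd.DataFrame(p, index=betas.index, columns=betas.columns)


# ---------------------------------------------------------------------------
# mapping reports and SNPs
# ---------------------------------------------------------------------------

DEFAULT_DIVERGENCE = {"Pan": 0.008, "Gorilla": 0.012, "Pongo": 0.03}


def simulate_mapping_and_snps(
    manifest: pd.DataFrame,
    per_species_divergence: dict | None = None,
    seed: int = 0,
    human_snp_rate: float = 0.3,
    species_snp_rate: float = 0.4,
):
    """Per-species mapping reports plus human and species SNP tables.

    Mismatch counts are Binomial(50, divergence); probes exceeding the
    aligner's edit-distance cap (3) come back unmapped (-1), as does a
    small divergence-proportional fraction lost to structural change.
    A CpG-site C>T defect is flagged with probability equal to the
    divergence. SNP counts per probe are Poisson with uniform positions
    and right-skewed minor allele frequencies in [0, 0.5].

    Returns (mapping, human_snps, species_snps).
    """
    div = per_species_divergence or DEFAULT_DIVERGENCE
    for sp, d in div.items():
        if not (0 <= d <= 0.05):
            raise ValueError(f"divergence for {sp} outside [0, 0.05]")
    rng = np.random.default_rng(seed)
    n = len(manifest)
    map_rows = []
    for sp, d in div.items():
        n_mm = rng.binomial(PROBE_LEN, d, size=n)
        unmapped = (n_mm > 3) | (rng.random(n) < d)
        ct = rng.random(n) < d
        for i, pid in enumerate(manifest.index):
            if unmapped[i]:
                map_rows.append((pid, sp, -1, "", False))
                continue
            k = int(n_mm[i])
            pos = sorted(rng.choice(np.arange(1, PROBE_LEN + 1), size=k, replace=False))
            map_rows.append((pid, sp, k, ",".join(map(str, pos)), bool(ct[i])))
    mapping = pd.DataFrame(
        map_rows, columns=["probe_id", "species", "n_mismatch", "positions", "cpg_ct_flag"]
    )

    def _snps(rate, species=None):
        rows = []
        counts = rng.poisson(rate, size=n)
        for i, pid in enumerate(manifest.index):
            for _ in range(int(counts[i])):
                pos = int(rng.integers(1, PROBE_LEN + 1))
                maf = round(float(rng.beta(0.6, 2.5) * 0.5), 4)
                rows.append((pid, pos, maf) if species is None else (pid, species, pos, maf))
        cols = ["probe_id", "position", "maf"] if species is None else [
            "probe_id", "species", "position", "maf"
        ]
        return pd.DataFrame(rows, columns=cols)

    human_snps = _snps(human_snp_rate)
    species_snps = pd.concat(
        [_snps(species_snp_rate, sp) for sp in div], ignore_index=True
    )
    return mapping, human_snps, species_snps


# ---------------------------------------------------------------------------
# blood cell-type reference
# ---------------------------------------------------------------------------

def simulate_blood_reference(
    manifest: pd.DataFrame,
    frac_dm: float = 0.1,
    n_per_group: int = 6,
    noise_sd: float = 0.03,
    seed: int = 0,
):
    """Whole-blood / CD4+ / CD16+ beta matrices with a planted fraction
    of cell-type DM probes (|delta beta| >= 0.15 against whole blood in
    one cell type). Returns (wb, cd4, cd16, truth_index)."""
    rng = np.random.default_rng(seed)
    n = len(manifest)
    base = _bimodal_means(rng, n)
    n_dm = int(round(frac_dm * n))
    dm_loc = rng.choice(n, size=n_dm, replace=False) if n_dm else np.empty(0, int)
    which = rng.random(n_dm) < 0.5
    deltas = rng.uniform(0.15, 0.4, size=n_dm)

    prof = {"wb": base.copy(), "cd4": base.copy(), "cd16": base.copy()}
    for j, i in enumerate(dm_loc):
        cell = "cd4" if which[j] else "cd16"
        m = prof[cell][i]
        d = deltas[j] if m + deltas[j] <= 1 else -deltas[j]
        prof[cell][i] = np.clip(m + d, 0, 1)

    out = {}
    for name, mean in prof.items():
        cols = {
            f"{name}_{k + 1:02d}": _reflect01(mean + rng.normal(0, noise_sd, size=n))
            for k in range(n_per_group)
        }
        out[name] = pd.DataFrame(cols, index=manifest.index)
    truth = manifest.index[np.sort(dm_loc)]
    return out["wb"], out["cd4"], out["cd16"], truth


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------

def simulate_orthologs(
    genes,
    coupling: float = 0.0,
    seed: int = 0,
    frac_dm: float = 0.1,
    aa_rate: float = 0.005,
    kaki_mean: float = 0.23,
    dm_genes=None,
) -> pd.DataFrame:
    """Ortholog table: amino-acid lengths (log-normal, spanning the
    150-1500 filter bounds), Poisson amino-acid change counts and
    Gamma-distributed KA/KI. With ``coupling`` > 0, genes planted as
    promoter-DM get proportionally larger change counts and ratios.
    The DM flags are drawn at ``frac_dm`` unless an explicit
    ``dm_genes`` collection is given.
    """
    if isinstance(genes, int):
        genes = [f"GENE{i:05d}" for i in range(genes)]
    rng = np.random.default_rng(seed)
    n = len(genes)
    aa_len = np.maximum(50, rng.lognormal(np.log(420), 0.55, size=n)).astype(int)
    if dm_genes is not None:
        dm = np.array([g in set(dm_genes) for g in genes])
    else:
        dm = rng.random(n) < frac_dm
    lam = aa_rate * aa_len * (1.0 + coupling * dm)
    aa_changes = np.minimum(rng.poisson(lam), aa_len)
    ka_ki = rng.gamma(2.0, kaki_mean / 2.0 * (1.0 + coupling * dm), size=n)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "aa_length": aa_len,
            "aa_changes": aa_changes,
            "ka_ki": ka_ki,
            "planted_dm": dm,
        }
    )


# ---------------------------------------------------------------------------
# alignment blocks
# ---------------------------------------------------------------------------

BASES = np.array(list("ACGT"))


def simulate_alignment_blocks(
    tree: SimTree,
    length: int = 1000,
    rate: float = 1.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    n_blocks: int = 1,
):
    """Multi-species alignment blocks evolved along ``tree``.

    Each site substitutes on a branch with probability
    1 - exp(-rate * branch_length), to a uniformly random different
    base. Indel columns (gaps in a random proper subset of taxa) are
    inserted at ``indel_rate``. Returns (blocks, truth) where blocks is
    a list of dicts taxon -> sequence and truth the realized pairwise
    substitution rate per kb over gap-free columns.
    """
    rng = np.random.default_rng(seed)
    taxa = tree.taxa
    blocks = []
    diff = np.zeros((len(taxa), len(taxa)))
    total = 0
    for _ in range(n_blocks):
        anc = rng.integers(0, 4, size=length)
        seqs: dict[str, np.ndarray] = {}

        def walk(node: SimNode, seq: np.ndarray):
            if node.length > 0 and rate > 0:
                p = 1.0 - np.exp(-rate * node.length)
                hit = rng.random(length) < p
                if hit.any():
                    seq = seq.copy()
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    seq[hit] = (seq[hit] + shift) % 4
            if not node.children:
                seqs[node.name] = seq
            for c in node.children:
                walk(c, seq)

        walk(tree.root, anc)
        gap = rng.random(length) < indel_rate
        gap_taxa = rng.integers(0, len(taxa), size=length)
        block = {}
        arr = np.stack([seqs[t] for t in taxa])
        chars = BASES[arr]
        for i, t in enumerate(taxa):
            s = chars[i].copy()
            s[gap & (gap_taxa == i)] = "-"
            block[t] = "".join(s)
        blocks.append(block)
        ok = ~gap
        total += int(ok.sum())
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                d = int((arr[i, ok] != arr[j, ok]).sum())
                diff[i, j] += d
                diff[j, i] += d
    if total == 0:
        truth = DistanceMatrix(np.zeros_like(diff), ids=taxa)
    else:
        truth = DistanceMatrix(diff / total * 1000.0, ids=taxa)
    return blocks, truth
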