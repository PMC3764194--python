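# Methods

This note documents the statistical procedures implemented in
`apemeth`, the synthetic-data model used to exercise them, the
numerical choices that were genuinely open, and what the test suite
does and does not demonstrate.

## Measurement model

A CpG's methylation level is summarized as
β = M / (M + U + offset), with M and U the methylated and
unmethylated channel intensities after background subtraction and
`offset = 100` (default) stabilizing low-intensity probes. Background
is estimated per sample as the 1st percentile of all pooled signals (a
proxy for negative-control beads, which the synthetic signals do not
carry), subtracted, and floored at zero. Dye effects are handled by
per-sample, per-channel median scaling to the sample's overall median
before the channels are pooled; this is a deliberately simple,
declared adjustment, not a reimplementation of any published
channel-correction method. Quantile normalization maps each sample's
pooled M∪U signal vector onto the across-sample mean-quantile
reference, preserving within-sample ranks (ties broken by position,
which makes the operation idempotent).

### BMIQ

The two Infinium chemistries produce systematically different β
distributions; type II values are compressed toward the middle. BMIQ
fits a three-state beta mixture (unmethylated U, hemimethylated H,
methylated M) to each design type by EM, assigns type II values to
states by maximum posterior (ties to H), quantile-maps the U and M
states through the fitted beta CDFs onto the corresponding type I
component, and rescales the H state by an affine dilation between the
mapped U and M boundaries. Type I values are never modified and the
transform is monotone within each state.

Two EM configurations coexist on purpose:

- `fit_beta_mixture` is a full maximum-likelihood EM (tolerance 1e-6
  on the relative log-likelihood, at most 500 iterations). Its M-step
  solves the weighted beta MLE exactly (digamma equations via L-BFGS on
  log-parameters), warm-started from the previous parameters, so the
  observed log-likelihood is non-decreasing by construction, not by
  approximation. Initialization is a deterministic hard assignment at
  β = 0.25 / 0.75 with method-of-moments component estimates.
- Inside `bmiq` the two state fits run only 8 EM iterations. On
  sharply bimodal methylation data the fully converged three-component
  ML fit is not identified with the U/H/M semantics — the likelihood
  prefers splitting the heavier extreme mode, and the type I and type
  II fits then misalign, which corrupts the quantile mapping. Keeping
  the fits anchored near their threshold-based initialization (as
  reference implementations of this normalization also do, via a small
  default iteration count) preserves the state semantics. The full-EM
  entry point remains available for mixture estimation as such.

BMIQ is skipped when either design group has fewer than 100 usable
values (the state fits would be meaningless), and on the X-chromosome
path, where males and females are quantile-normalized separately and
the female inactive-X signal makes a shared three-state template
inappropriate.

## Differential methylation

All group comparisons use the two-sided Wilcoxon rank-sum test. With
pooled sample size ≤ 16 and no ties the null distribution of the rank
sum is enumerated exactly by dynamic programming and
p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1; otherwise a normal
approximation with tie correction and a 0.5 continuity correction is
used. FDR control is Benjamini–Hochberg, applied per pairwise
comparison across all probes in the analysis set. Significance is the
conjunction q < 0.05 (strict) and |Δβ| ≥ 0.1 (inclusive); "standard
deviation" always means the n−1 sample SD.

The intragenus variance filter retains a probe only when its sample SD
is strictly below 0.1 within every genus. Genus-specific calls require
all three comparisons of one genus against the others to be
significant, with at most one genus per probe; conserved sites require
all six comparisons to have q > 0.05 and |Δβ| < 0.1 (both strict).
The two-species (human–chimpanzee) caller first drops probes with
SD ≥ 0.1 within either species, then applies the same significance
rule and reports the direction of change.

**A structural consequence of exact tests plus FDR worth knowing:**
with 6-vs-6 groups the smallest attainable p is 2/C(12,6) ≈ 0.00216,
so a probe can reach q < 0.05 only when at least ~4.3% of the family's
probes sit at that floor. Small cohorts or thinly spread effects
therefore yield *zero* discoveries — not reduced power but a hard
cutoff. This drives several scale choices below (per-lineage planting
density, the blood-reference DM fraction, and the 6-per-taxon default
group size; 4-vs-4 groups cannot reach q < 0.05 at any family size).

## Regions, enrichment and rates

DM sites are chained into regions by single linkage along each
chromosome with an inclusive 1,000 bp gap and a 2-site minimum.
Regions link to every gene whose strand-aware extended span
(TSS − 1500 bp through the 3′UTR end) overlaps a member probe.
Cluster-count and positional-enrichment nulls resample the observed
number of DM sites *without replacement* from the analysis universe;
p-values carry the +1 correction (p = (#extreme + 1)/(n_perm + 1)), so
the smallest attainable p at 10,000 permutations is ~1e-4. Enrichment
p-values are two-sided (2·min of the tail counts, capped at 1) with
ratio = observed/null-mean fraction. The β-distribution contrast of DM
versus background sites is a two-sample KS test. Rate heterogeneity
across lineages is a Poisson likelihood-ratio test: H0
counts_i ~ Poisson(λ·L_i) versus per-lineage rates, statistic
2·Σ c_i·log(c_i/e_i), df = k−1; branch lengths L_i default to 1
(pure count homogeneity) and can be set to sequence-divergence
lengths.

## Phylogenetics

Sequence distances count mismatched columns per kb over alignment
columns free of gaps and Ns, pooled across blocks. Methylation
distances are Euclidean on per-probe species means (or individual β
vectors); probes missing in a pair are dropped pairwise and the
distance rescaled by √(total/used), with a per-probe RMS variant
available. Neighbor joining is the Saitou–Nei algorithm, exact on
additive matrices; negative branch lengths are floored at zero with
the deficit moved to the sister edge, and Q-criterion ties break
deterministically in pair order. Bootstrap support resamples probes
(characters) with replacement and scores each reference bipartition by
percent recovery; supports are stored as internal node labels in the
Newick output. The divergence regression is ordinary least squares of
methylation distance on sequence distance over the 6 unordered species
pairs.

With planted lineage effects concentrated in one genus, the affected
taxon's distances inflate non-additively (Euclidean distance is a
square root of summed squares), which can depress internal-branch
supports or, at extreme planted fractions (≳5% of probes on one
lineage), distort the topology. Trees built on the non-DM probe subset
recover full support; the test bench therefore separates tree-recovery
checks (no planted effects) from DM-recovery checks.

## X inactivation

Sex contrasts are per-species female−male mean β differences on
sex-stratified-normalized X-chromosome data, requiring at least two
individuals per sex per species. A lineage-specific inactivation shift
is called when |Δ| < 0.1 in exactly one lineage and Δ > 0.1 in every
other species; the threshold-only gate (no Wilcoxon) is the default
because per-sex group sizes (2–3) sit below the exact-test floor
discussed above, and a documented flag adds the test gate. The
female-hypermethylation fraction uses an exact two-sided binomial test
against 0.5, excluding exact zeros, reported per species and pooled.

## Promoter methylation vs protein evolution

Orthologs outside 150–1500 amino acids are removed first. A gene is
promoter-DM when the mean of the two largest |Δβ| values among its
promoter probes (TSS−1500 bp, 5′UTR, or first exon) is ≥ 0.1; genes
with fewer than two measured promoter probes are excluded from both
groups. Top-2 selection is by |Δβ| with ties broken by probe id. The
association statistic is the difference in group means of amino-acid
change counts (and of K_A/K_I), tested by shuffling the DM labels with
the +1-corrected two-sided permutation p.

## Synthetic-data model

The generator is first-class code with planted, machine-checkable
truth; it emulates:

- **Manifest**: probes across two autosomes and chrX (≈6 kb spacing),
  70% placed around gene TSSs, annotated with the seven gene-centric
  classes (priority TSS200 > TSS1500 > 5′UTR > 1stExon > 3′UTR > Body)
  and island/shore(≤2 kb)/shelf(2–4 kb)/open-sea classes, both derived
  from the emitted gene models and island intervals; design type I
  with probability 0.28. Coordinates are 0-based half-open.
- **β landscape**: ancestral per-probe means from a mixture of
  Beta(0.5, 5) and Beta(5, 0.5) (45% each) plus a minor 10% Beta(5, 5)
  intermediate component. Blood methylomes show a small intermediate
  shoulder, and without it the three-state mixture fit is
  unidentifiable, so a pure two-mode ancestral density would make the
  normalization stage untestable for reasons unrelated to its
  correctness.
- **Evolution**: Gaussian drift N(0, k·√t) per branch, truncated to
  [0, 1], k = 0.3, with branch lengths in expected substitutions per
  site matching great-ape divergences (Human and Pan terminals 0.006,
  their ancestor 0.0035, Gorilla 0.0065, the African-ape ancestor
  0.0075, Pongo 0.014; human–chimp pairwise ≈ 0.012, human–orangutan
  ≈ 0.031). No generative model for methylation evolution is
  established in this literature; bounded drift is the minimal choice
  and is not calibrated to real array data.
- **Individuals**: N(0, noise_sd = 0.05) around the species mean,
  *folded* (reflected) at the [0, 1] boundaries rather than truncated.
  Truncation would place atoms at exactly 0 and 1, creating rank ties
  the assay never produces; ties silently reroute the exact Wilcoxon
  branch to the conservative tie-corrected branch and distort power at
  boundary-adjacent probes.
- **Planted effects**: lineage effects shift exactly one genus by Δβ
  (default 0.3), direction chosen to stay inside [0, 1] (error if
  neither fits); a configurable fraction is placed in pre-existing
  ≤1 kb probe runs so region clustering has true positives. X-linked
  sex effects put a +0.3 female uplift on 60% of X probes (male
  baseline drawn in [0.1, 0.65]); escape sites reduce the focal
  lineage's uplift to 0.02.
- **Signals**: M = bg + A·β′, U = bg + A·(1−β′) with per-probe
  log-normal amplitude (median 5,000), background 200, 2%
  multiplicative noise; type II probes first pass through the
  compressive squash β′ = β^γ/(β^γ + (1−β)^γ), γ = 0.7, which fixes
  0, ½ and 1 but pulls the bimodal extremes toward the middle —
  giving BMIQ a realistic correction task.
- **Mapping/SNPs**: per-species mismatch counts Binomial(50,
  divergence) with uniform positions; probes exceeding the aligner's
  edit-distance cap (3) or hit by a divergence-proportional structural
  loss return unmapped; CpG-site C>T defects at the divergence rate;
  Poisson SNP counts with right-skewed MAFs. Retention is monotone
  non-increasing in divergence.
- **Blood reference**: 10% of probes cell-type DM (|Δβ| ∈ [0.15, 0.4]
  against whole blood, split between CD4+ and CD16+). The fraction is
  the smallest round value at which each per-cell-type BH family can
  clear the exact-test floor at 6-vs-6 (the floor condition
  q = 0.00216/frac is scale-invariant in probe count).
- **Orthologs**: log-normal amino-acid lengths spanning the 150–1500
  filter bounds, Poisson change counts (rate 0.005/residue), Gamma
  K_A/K_I (mean 0.23); a coupling factor scales both for promoter-DM
  genes.
- **Alignments**: per-branch substitution probability
  1 − exp(−rate·t) to a random different base; indel columns gap a
  random taxon; recorded truth is the realized mismatch rate over
  gap-free columns.

Everything is deterministic given its seed; the pipeline expands one
global seed into per-stage substreams via SHA-256 so stages are
independently reproducible.

## What the test bench shows — and does not

Planted-truth recovery on this generator demonstrates that the
*rules are implemented correctly and have the designed operating
characteristics at these scales*: genus-specific sensitivity ≥ 0.9
with false calls ≤ 2% at 5,000 probes / 6 per taxon / Δβ = 0.3,
XCI-escape recall ≥ 0.9 with ≤ 2 false calls per 3,000 X probes,
topology recovery in ≥ 95% of seeds with sister supports > 90, and
calibrated permutation and FDR machinery under the null. It does not
validate the biological model against real arrays: the generator has
no batch effects, no age or cell-composition gradients beyond the
planted cell-type sites, no mQTL structure linking SNPs to
methylation, independent probes (no spatial correlation beyond planted
clusters), and Gaussian noise with a single global SD. Reported
recovery rates are therefore upper bounds on real-data performance.

The planted DM density used in recovery tests concentrates sites on
one lineage; spread across four lineages, the same total count leaves
each pairwise comparison family below the exact-test floor condition
(see the differential-methylation section), which is a property of
small-sample exact tests under FDR, not of this implementation.

Problem sizes throughout (2,000–5,000 probes, 20–50 seed replicates,
200–10,000 permutations, 200–1,000 bootstraps) were chosen as the
smallest scales at which the targeted operating characteristics are
stable; the calibration checks use configurations whose null statistic
takes enough distinct values for a meaningful uniformity test (a
coarse cluster-count lattice makes KS-against-uniform uninformative at
200 replicates).

## Known limitations

- The channel adjustment is a declared stand-in (median scaling), not
  numerically identical to any published package's method.
- The H-state dilation in BMIQ is affine between mapped state
  boundaries; rank order across state boundaries is not guaranteed.
- The Poisson rate LRT is a generic substitute for an unavailable
  published derivation; with branch lengths of 1 it tests count
  homogeneity only.
- The female-hypermethylation fraction on synthetic data is
  generator-determined (≈0.8 under the defaults) and should not be
  read as an estimate of any real-array quantity.
- Multi-mapping probes are treated as unmapped (ambiguity is unsafe);
  the only CpG-disruption rule is the C>T flag at the assayed site.
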