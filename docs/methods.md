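# Methods

This note documents the models and procedures implemented in `crcisc`, the
choices made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Preprocessing and bimodal gating

Raw counts are QC-filtered with strict inequalities: a cell survives when it
has **more than** 200 genes detected and **more than** 1000 total reads.
Strictness also applies at the binarization boundary (a value exactly at the
threshold is negative); the QC wording implies "more than", and the
binarization convention is a documented choice. Normalization scales each
cell to 1e6 total counts (CPM) before `log2(1 + x)`; CPM is the default
because the 0.2 positivity threshold is defined on the log2-CPM scale, and
the scale factor is configurable for toolchains that normalize to median
counts instead. Mitochondrial/ribosomal removal is a configurable
symbol-prefix filter (`MT-`, `RPL`, `RPS`, `MRPL`, `MRPS`), since pattern
sources vary between annotation bundles.

`detect_bimodal_threshold` evaluates a Gaussian KDE on a 512-point grid and
returns the density minimum between the two highest modes. A numerical
safeguard treats a secondary peak carrying less than 5% of the top peak's
density as a KDE wiggle rather than a mode; degenerate or unimodal inputs
fall back to the canonical 0.2 with a warning.

## Signaling modules

The 39-gene tumor-reactive universe consists of 21 exhaustion genes, 17
cytokine/TCR-signaling and transcription-factor genes, and *IFNG*. Module
discovery computes the gene-gene Spearman matrix across cells (average ranks
for ties), embeds each gene by its row of correlations, and clusters the
Euclidean distances between those profiles with complete linkage, cutting at
k = 5. Complete linkage is used for both the module discovery and the
patient clustermap at single-cell level — one convention for both steps,
configurable. Zero-variance genes cannot enter a correlation matrix; they are
assigned to the module of the gene with the nearest mean expression, with a
warning.

The shipped GMT (`crcisc/data/tumor_reactive_modules.gmt`) carries ten
modules (five per subtype) whose union is exactly the 39-gene universe. Four
genes (SLAMF6, JAK3, NFATC1, IL18R1) are not explicitly placed by the module
descriptions available to us; they were assigned to biologically plausible
modules (stem-like progenitor; tumor-reactive exhaustion; memory
differentiation; memory differentiation / inflamed memory-like) and flagged
"inferred" in the GMT description field. Within a subtype the five modules
are kept disjoint so they can double as planted simulation blocks; across
subtypes genes recombine freely, which is what `module_overlap` (Jaccard)
quantifies. Empty-set conventions for Jaccard: two empty sets are identical
(J = 1), empty vs non-empty is 0.

Module activity is the mean of binarized expression (strict > 0.2) over a
group's cells and a module's genes, so activation-map entries live in [0, 1]
and are monotone non-increasing in the threshold. A metagene is the plain
arithmetic mean of normalized expression over a gene set.

## Activation axes

Each cell's expression over the signature panel is Spearman-correlated with
the TCR-activation and bystander-activation centroids (average expression
profiles of the corresponding reference conditions; the package treats these
centroids as configuration inputs, and the synthetic generator fabricates
stand-ins with the same role). The reference center for the quadrant system
is the per-axis **mean** of normal-tissue cell scores — the population center
is marked without specifying mean vs median, so mean was chosen and is
configurable. High/Low classification is strict, so cells exactly at the
center are Low/Low. The directionality statistic is
`median(r_TCR) − median(r_bystander)`, antisymmetric under swapping the
centroids, with |d| < 0.2 classified non-directional. Quadrant statistics can
be compared between cohorts as counts or proportions; both are returned.

Welch's t-test is implemented from the closed form with Welch–Satterthwaite
degrees of freedom; scipy's implementation serves as the oracle in tests.

## TCR repertoire

All sequence comparisons use local alignment under BLOSUM62 with gap-open 4
and gap-extension 4 — a gap of length L costs 4 + 4(L−1), i.e. the first gap
residue pays the open penalty. Because open equals extension, the scheme
reduces to a linear 4-per-residue gap cost, which is how the independent
Smith–Waterman oracle in the tests verifies it.

Identity conventions differ by operation, following the analyses they
implement:

* `identity_fraction(query, target)` divides by the **target's** self-score
  (clipped to [0, 1]); MAIT scoring uses this against the known reference
  pairs and takes the best alpha×beta product over pairs and chains.
* `call_exclusive` divides the best tumor-vs-normal score by the **tumor
  query's** self-score and calls a beta chain exclusive when that fraction is
  strictly below 0.80. An empty normal repertoire makes everything exclusive,
  with a warning.

Clonotypes are cells sharing identical CDR3 nucleotide sequences on all their
productive chains; ids are content hashes, so they are stable across runs and
record order. Cells with a single recovered chain form single-chain
clonotypes flagged by an `sc-` prefix. Clonotype clusters connect clonotypes
whose representative CDR3 amino-acid sequences (beta preferred, alpha
fallback) are within alignment distance
`d(a, b) = min(self(a), self(b)) − score(a, b) ≤ 15`; the exact distance form
of the upstream toolkit is not public, so this symmetric, zero-on-identity
definition is isolated behind `alignment_distance` and can be swapped.
Epitope annotation takes all reference CDR3s of the matching locus within the
same cutoff (chain-specific matching is the default), reports the most
frequent (epitope, organism), labels ties `ambiguous` and no-hits `Unknown`,
and overrides exclusive clonotypes to family `exclusive`.

Diversity statistics are written from the formulas — bias-corrected Chao1
`S + F1(F1−1)/(2(F2+1))`, normalized Shannon `H/ln S`, Heip evenness
`(e^H − 1)/(S − 1)` — with scikit-bio as the independent oracle in tests.
Degenerate single-category repertoires return 0 (normalized Shannon) and 1
(Heip) by documented convention.

## ISC stratification

Single-cell level: patients are clustered on per-patient mean module scores
with complete-linkage Euclidean hierarchical clustering (2 clusters for MSI,
3 for MSS in the canonical analysis).

Bulk level: for each module signature, the distance between two patients is
`1 − ρ_Spearman` over the signature's genes — a correlation is a similarity,
so the standard 1 − ρ conversion is used. Distances are computed over all
**ten** module signatures (both subtypes' sets) and averaged; the averaged
matrix is a valid dissimilarity (symmetric, zero diagonal, non-negative).
L1 normalization (each patient's vector divided by its absolute sum) is
provided and is the input transform for the classifier; rank-based distances
are invariant to it, so its position relative to the distance step is
immaterial.

Cluster extraction uses **Ward agglomeration on the precomputed averaged
dissimilarity**, with k chosen by silhouette within 2..5 (a fixed-k override
reproduces the canonical 2 MSI / 5 MSS groups). Average linkage was tried
first and proved fragile here: rank correlations over small gene sets are
noisy, weak-signal patients become outlier singletons, and average linkage
spends its k budget on singletons while merging true groups. Ward's
minimum-variance criterion absorbs outliers into their nearest group and
recovered planted 5-group structure with ARI ≥ 0.95 across seeds where
average linkage scored 0.4–0.8.

Naming: for MSI the cluster with the higher mean stem-like-progenitor
metagene is ISC1a. For MSS, clusters are ordered by overall mean module
metagene; the top of the ordering (up to three clusters) becomes ISC2a ≥
ISC2b ≥ ISC2c and the bottom (up to two) ISC3a ≥ ISC3b, splitting at the
largest gap in overall signal (with five clusters the 3 + 2 capacity forces
the split position). Ties break on the long-term immunosurveillance metagene,
then lexicographically. Naming metagenes are computed on the expression as
given rather than after L1 normalization: per-patient L1 scaling divides
strongly inflamed patients by larger totals and can invert the ISC2/ISC3
ordering that the naming encodes.

Label transfer trains a random forest per fold of a repeated stratified
5-fold split, averages impurity-decrease importances, keeps genes strictly
above 0.001, and fits the final forest (5000 trees by default, seed 12,
balanced class weights) on the selected genes. Missing genes at prediction
time are imputed as 0 with a warning. Harmonization between cohorts is a
pluggable pre-step (identity by default).

## Survival

`km_estimate` is the product-limit estimator; ties between events and
censorings at the same time are resolved events-first (the censored subject
remains at risk for that event), the standard convention. `logrank_test` is
the two-group observed-minus-expected chi-square with hypergeometric
variance, 1 df. Both are deliberately re-implemented from the formulas and
oracle-tested against lifelines; multivariate Cox modeling is out of scope
and left to established packages.

## Synthetic data: what it emulates, and what it does not

**Single-cell expression.** Genes are generated as a Gaussian copula on the
log scale: module genes share a latent factor with loading chosen as
`2 sin(π rho / 6)` so the pairwise Spearman correlation approaches the
configured rho, then values are shifted by per-gene baselines and truncated
at 0 (the pipeline consumes log-normalized values, so count-level realism is
unnecessary). The IFNG marginal is replaced by a two-component mixture — a
near-zero detection component and an expressing component starting around
0.45 — with the configured positive fraction; the replacement is
rank-coupled to IFNG's latent factor, so planted correlations survive the
override and the detection valley sits between 0.2 and 0.45. Defaults: 8
patients × 250 cells, rho = 0.8 on the five MSI modules, 40% IFNG+, noise SD
0.6.

**TCR repertoire.** Clone sizes are a discretized Pareto
(`floor(Pareto(α)) + 1`, survival exactly `k^−α`), α = 1.5 by default —
heavy-tailed expansion as seen in real repertoires. Clonotype families follow
configurable proportions over {viral, bacterial, self, shared, exclusive,
unknown}; annotatable families copy a reference CDR3 with per-residue
substitution at `mutation_rate` (0 by default), and every non-exclusive
clonotype also seeds the normal-adjacent repertoire. Exclusive clonotypes are
rejection-sampled below 75% identity (tumor-self-score normalized) against
the references **and** every normal-tissue beta chain, guaranteeing they stay
under the 0.80 calling threshold. MAIT cells are appended as dedicated cells
carrying exact alpha/beta pairs from the synthetic stand-in table. CDR3
nucleotide sequences use one fixed codon per residue so nucleotide equality
coincides with amino-acid equality.

**Bulk cohort.** Expression is gene baseline + group effect + Gaussian noise,
truncated at 0. Group effects are the product of the configured per-module
metagene shift (in units of the noise SD) and per-gene response factors drawn
U(−1, 3) with mean forced to 1 over the module — the metagene moves by
exactly the configured shift while genes respond with different magnitudes
and signs, as real module genes do. This heterogeneity is essential:
a shift uniform across a module's genes leaves within-patient ranks, and
hence the Spearman patient distances, unchanged. Baselines and response
factors are keyed by gene/group/module names only — they are population-level
biology shared by every draw — while noise, group assignment and survival
draw from the seed; this is what makes classifier transfer between
independent draws meaningful. Survival times are exponential with hazard
`baseline_hazard × group_hazard_ratio`, and censoring replaces the time by a
uniform fraction of the event time with probability `censor_rate`.

Default planted designs: the MSI cohort has two groups — stem-like-dominant
(stem shift 3 SD, immunosurveillance 2.5) vs mixed-inflammatory (exhaustion
3 SD, follicular and memory 2.5) — mirroring the two MSI patient clusters'
described profiles; the MSS cohort has five groups shifting all five MSS
modules with magnitudes graded 1.0/0.8/0.6/0.4/0.2 of 3 SD from most inflamed
to most silent, with a 2.5× hazard on the silent side.

**Not emulated:** read-level noise, doublets, batch effects, V(D)J
recombination statistics, insertion/deletion mutations in CDR3s, non-module
transcriptome background, and correlated censoring. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it assumes
(co-expression blocks, identity neighborhoods, group-dependent module shifts
and hazards) — not robustness to artifacts these generators do not produce.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 2,000 cells for module
recovery, 60-patient MSI and 150-patient MSS cohorts, 150 planted clonotypes,
500 null and 200 alternative log-rank replicates (n = 30 and 100 per group),
1,000 random CDR3s for identity checks, and a 500-tree transfer forest. One
global seed fans out to per-generator child streams via
`numpy.random.SeedSequence`; every stochastic routine takes an explicit seed
and fixed seeds reproduce byte-identical outputs (the pipeline manifest
records output hashes to make this checkable).
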