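# crcisc

CD8+ T cell tumor-reactive signaling modules, TCR repertoire analysis, and the
Immune Subtype Classification (ISC) for colorectal cancer transcriptomes.

## The problem

Microsatellite-instable (MSI) colorectal cancer responds to immune checkpoint
blockade; microsatellite-stable (MSS) colorectal cancer mostly does not, even
though both carry CD8+ T cell infiltrates with superficially similar
phenotypes. The difference lies in *what those T cells recognize*: MSI tumors
enrich tumor-reactive, exhausted, neoantigen-directed clones, while MSS tumors
are dominated by bystander cells with viral or microbial TCR specificities.
`crcisc` implements an analysis chain that makes this distinction measurable
and carries it from single cells to bulk tumor cohorts:

1. **Preprocessing and gating** — QC filtering (> 200 genes and > 1000 reads
   per cell), CPM normalization with log2(1 + x), and bimodal gating of *IFNG*
   at the density valley between its detection and expression modes
   (0.2 log2-CPM).
2. **Signaling-module discovery** — over a fixed 39-gene tumor-reactive
   universe, the gene–gene Spearman correlation matrix of IFNG+ cells is
   embedded by correlation profiles, and complete-linkage hierarchical
   clustering of Euclidean distances between profiles is cut into five modules
   per subtype (stem-like progenitor, inflamed follicular-like, long-term
   immunosurveillance, tumor-reactive exhaustion, memory differentiation for
   MSI; their MSS counterparts including tolerogenic c-Maf signaling). Module
   activity is scored as mean binarized expression.
3. **TCR vs bystander activation axes** — each cell's expression over a
   signature panel is rank-correlated against TCR-activation and
   bystander-activation reference centroids; cells fall into quadrants around
   a normal-tissue reference center, and the directionality statistic
   `median(R_TCR) − median(R_bystander)` (|d| < 0.2 = non-directional)
   summarizes a population.
4. **TCR repertoire** — local amino-acid alignment under BLOSUM62 with gap
   open/extend penalties of 4; identity as a fraction of self-alignment
   score; clonotypes by shared CDR3 nucleotide sequences; clonotype clusters
   as connected components at alignment distance
   `min(self(a), self(b)) − score(a, b) ≤ 15`; epitope annotation by the
   most-frequent reference hit (ties → `ambiguous`, no hit → `Unknown`);
   tumor-exclusive calls below 80% identity to every normal-adjacent beta
   chain; MAIT identity as the best alpha×beta product against known pairs;
   Chao1 richness, normalized Shannon entropy, and Heip evenness of clone
   sizes.
5. **ISC stratification** — per-signature patient distances
   `1 − ρ_Spearman` over each module's genes, averaged across the ten
   signatures; agglomerative (Ward) clustering of the averaged dissimilarity
   with silhouette-chosen k ≤ 5; clusters named ISC1a/1b (MSI, by stem-like
   metagene) or ISC2a–c / ISC3a–b (MSS, by overall module signal); label
   transfer by a feature-selected random forest (mean impurity decrease
   > 0.001 over repeated 5-fold CV, then a balanced 5000-tree forest).
6. **Survival** — Kaplan–Meier product-limit curves and the two-group
   log-rank test, written from the standard formulas.

A `synthetic_data` module generates all inputs with the statistical structure
the analysis assumes — block-correlated modules, bimodal *IFNG*, power-law
clonal expansion with planted epitope families and tumor-exclusive CDR3s, and
bulk cohorts with planted ISC groups plus group-dependent exponential
survival — so the whole chain is testable end to end without any download.

## Worked example

```bash
python examples/04_isc_stratification_and_survival.py
```

prints

```
chosen number of clusters: 5
recovery ARI vs planted groups: 1.000
ISC label counts:
ISC2a    30
ISC2b    30
ISC2c    30
ISC3a    30
ISC3b    30
log-rank ISC2 vs ISC3: chi2 = 26.97, p = 2.06e-07
```

The silhouette criterion picks five clusters, the clustering reproduces the
planted groups exactly (adjusted Rand index 1.0), naming orders them by
overall module signal, and the log-rank test detects the planted 2.5× hazard
of the immune-silent ISC3 side. The other examples cover IFNG gating, module
discovery, repertoire annotation, and classifier label transfer; each prints
the numbers it computes with a comment on what they mean.

A thin CLI wraps the same pipeline:

```bash
isc run --seed 1 --out run1/         # full synthetic pipeline with manifest
isc simulate tcr --seed 1 --out sim/ # one generator only
```

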