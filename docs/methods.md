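# Methods

Statistical model, parameter choices and limitations of each `fimbria`
module. Notation: genes × cells count matrix `X`, cohorts ("groups")
carrier/control, samples `carrier_1..3`, `control_1..3`.

## QC and normalization (`fimbria.qc`)

- **Mitochondrial fraction** per cell: sum of counts of genes whose symbol
  starts with `MT-` divided by total counts. Cells with total count 0 get
  fraction 0 with a warning.
- **Filter**: cells with mito fraction ≥ `mito_threshold` (default 0.15)
  are removed; the boundary value is removed. Removing all cells is an
  error. Filtering is idempotent.
- **Normalization**: `ln(1 + count / cell_total × scale_factor)` with
  `scale_factor = 1e4` (counts-per-10k log transform). Natural log; the DE
  stage divides by `ln 2` where log2 units are required.

Assumptions: mito prefix identifies the mitochondrial genome (human
nomenclature); library-size normalization assumes composition effects are
negligible at panel level.

## Cell typing (`fimbria.cell_typing`)

- **Score**: per cell and type, the mean log-normalized expression of a
  marker panel (epithelial EPCAM/KRT18; fibroblast DCN; T CD3D/E/G;
  macrophage CD68; endothelial PECAM1). Missing markers are dropped with a
  warning; a panel with no present marker is an error.
- **Cluster annotation**: clusters (any labeling; the built-in plumbing is
  PCA + k-means) are assigned the type with the highest mean score over
  member cells; exact ties → `unassigned`.
- **Clustering plumbing** (`cluster_cells`): genes are centered and scaled
  to unit variance before PCA. Without centering, the leading component of
  log-normalized data tracks sequencing depth through the dropout pattern
  and shallow cells of all types collapse into one cluster.
- **Epithelial subtypes**: detection-based rule on *raw* counts —
  PAX8 ≥ 1 & TP73 = 0 → secretory; TP73 ≥ 1 & PAX8 = 0 → ciliated; both →
  transition; neither → unassigned. Non-epithelial cells are
  `not_applicable`.

Limitation: panel-mean scoring has no per-gene scaling, so a single
high-expressed marker can dominate a panel; detection-based subtyping is
sensitive to depth (shallow secretory cells can drop PAX8).

## Differential expression (`fimbria.diffexpr`)

Empirical-Bayes moderated t (limma-style) on log2 expression:

- Per gene: group means, log2 fold change `lfc = mean₁ − mean₂`, pooled
  variance `s² = ((n₁−1)s₁² + (n₂−1)s₂²) / d` with `d = n₁+n₂−2`.
- Prior `(d₀, s₀²)` by moment matching on `ln s²`:
  `Var(ln s²) − ψ₁(d/2) = ψ₁(d₀/2)` solved for `d₀` by Newton on the
  trigamma inverse; `s₀²` from the mean with digamma corrections. If the
  excess variance is ≤ 0, `d₀ = ∞` (variances fully pooled).
- Posterior variance `s²_post = (d₀ s₀² + d s²)/(d₀ + d)`, moderated
  `t = lfc / sqrt(s²_post (1/n₁ + 1/n₂))`, reference t with `d + d₀`
  degrees of freedom (normal when `d₀ = ∞`), two-sided p, BH q.
- Call rule: `up`/`down` at q < 0.05 and |lfc| ≥ 0.25, else `ns`.

`ModeratedTTest` is a scikit-learn-style estimator
(`fit(X_cells×genes, groups)` → `log2fc_`, `t_`, `p_`, `q_`, `call_`,
`prior_`).

Assumptions/limitations: treats cells as independent replicates
(pseudoreplication — no random effect for sample/donor), Gaussian
log-expression within groups. On NB-generated counts the null is
measurably calibrated (KS-uniform p-values, tested), but heavy tails at
very low expression can inflate tail rates slightly.

## Preranked GSEA (`fimbria.gsea`)

Weighted running-sum enrichment on a ranked gene list (here ranked by
log2FC):

- Hit step `|metric|^p / Σ_members |metric|^p` (default weight p = 1);
  miss step `−1/(N − n_hits)`; ES = value of maximal |running sum|.
- Null: gene-label permutation — random same-size sets of ranked-list
  positions; one shared null per set size (the null depends only on
  (metric, k)).
- `p = (1 + #{same-sign null with |ES| ≥ |ES_obs|}) / (1 + #same-sign)`;
  `NES = ES / mean |same-sign null ES|`; BH across sets.

Limitation: gene-label permutation ignores inter-gene correlation (the
standard caveat vs phenotype permutation); p-values have resolution
1/(n_perm+1).

## ROE enrichment (`fimbria.roe`)

For a marker and a cell partition into G groups: observed expressing-cell
counts `N_o(g)` (detection = raw count ≥ 1), expected under independence
`N_e(g) = ΣN_o × n_cells(g)/Σn_cells`, `ROE = N_o/N_e` (> 1 =
enrichment). ΣN_e = ΣN_o by construction. Significance: Pearson
chi-squared on the 2×G expressing/non-expressing table (df = G−1), with
Yates continuity correction **by default for 2×2 tables** — the convention
matching published tubal-mucosa clonality statistics — and BH across a
marker panel. Markers absent or never detected are reported NaN and
excluded from BH. The Yates-corrected p is deliberately conservative;
calibration checks therefore use the uncorrected statistic.

## Cluster similarity (`fimbria.similarity`)

Mirrors the subsample-MNN recipe used to compare query epithelial clusters
against reference secretory subtypes:

- Subsample `k = 20` cells per query cluster (clusters below
  `min_cluster_size = 21` are excluded with a warning) to remove
  cluster-size bias.
- Mutual nearest neighbors between subsampled query and reference cells,
  cosine distance, `k_nn = 20`, brute force (deterministic ties).
- `score(cluster, subtype) = #MNN pairs(cluster, subtype) / #pairs total`
  — all scores sum to 1; interpret by row-wise argmax.

`MNNSimilarityScorer` is the estimator wrapper (`fit(reference, subtypes)`,
`transform(query, clusters)`).

Limitation: the pair-share score couples all clusters through the common
denominator; with very different cluster counts, compare argmax patterns,
not absolute scores.

## TCR repertoire (`fimbria.tcr`)

- **Pairing**: keep contigs that are called cells, productive, full
  length, TRA/TRB; per cell and locus keep the highest-UMI chain (ties:
  lexicographically smallest CDR3 nucleotide sequence); keep cells with
  both loci.
- **Clonotype**: key = (TRA CDR3aa, TRB CDR3aa) by default (`cdr3_nt` and
  `v_cdr3_aa` available); clone size pools all samples; clonal ⟺ size ≥ 2.
- **Clonality test**: 2×2 clonal × cohort Yates chi-squared; reported with
  per-group clonal percentages. The pipeline computes this on CD8⁺ cells
  (CD8A detected, CD4 undetected).
- **Exhaustion**: per marker — cohort ROE + chi-squared (BH across the
  panel), clonal-vs-nonclonal and carrier-vs-control two-sided Wilcoxon
  rank-sum on log-normalized expression (exact for ≤ 8 values without
  ties, normal approximation with tie correction otherwise).

Limitation: no doublet detection beyond highest-UMI-per-locus; convergent
clonotypes across donors are merged by design (clone size pools samples).

## Synthetic cohorts (`fimbria.synthetic`)

Negative-binomial counts (`NB(mean, θ = 2)`) around log-normal gene base
rates; all planted effects are multiplicative mean shifts on the natural-log
scale. Defaults (`CohortConfig`): 6 samples (3/3), 500 cells/sample, 2000
genes, library ≈ 1000 counts/cell — a deliberately desk-scale problem (the
motivating studies have ~19,000 cells and ~20,000 genes; every size is
configurable). Planted structure:

- type proportions (0.45, 0.25, 0.17, 0.08, 0.05) with marker floors and a
  30-gene expression program per type (clustering rides on the programs);
- secretory/ciliated/transition epithelium via PAX8/TP73 means; an EMT
  program (sharing genes with the fibroblast repertoire, e.g. DCN, VIM,
  COL1A1 — faithful to mesenchymal biology) in 25% of one carrier
  sample's secretory cells;
- EMT-TF enrichment in carrier fibroblasts; 5% high-mito cells;
- paired TCR: per-group clonal fractions (0.73, 0.62) over CD8 cells,
  geometric clone sizes ≥ 2, unique CDR3s, 5% unpaired and 5%
  non-productive contig noise; PDCD1 re-drawn with shifted mean for clonal
  cells (plus an extra carrier shift).

Everything is reproducible from one seed; `truth` tables carry all planted
labels.

## Acceptance properties

`scripts/acceptance.py` (and `tests/test_acceptance.py`) recompute:

- published-scale statistics: clonality p (t1 = 2.48 × 10⁻⁶), carrier
  clonal percentage (t2 = 73.5), T-cell percentage (t3 = 17.1);
- oracle equivalence of chi-squared, BH, Wilcoxon, pooled/moderated t, MNN
  and GSEA running sums against independent brute-force implementations;
- null calibration (KS uniformity at α = 0.01) of DE, ROE (uncorrected)
  and GSEA p-values on zero-effect data;
- parameter recovery over 100 seeded runs: EMT similarity argmax,
  clonality significance at paper scale (~900/550 CD8 cells, α = 0.001),
  PD-1 Wilcoxon (p < 0.01; cohort size 400 cells/sample chosen by a power
  calculation giving detection probability ≈ 1 at the planted effects),
  and eBayes prior recovery (d₀ within 15%, s₀² within 10% at 5000 genes);
- conservation invariants: ΣN_e = ΣN_o, similarity scores sum to 1,
  clonal + non-clonal = paired cells.
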