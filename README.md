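# fimbria

Single-cell transcriptome + paired-TCR analysis of fallopian-tube mucosa
cohorts (e.g. *BRCA1* mutation carriers vs controls), as a reproducible,
fully seeded Python package.

The fallopian tube epithelium (FTE) is the proposed tissue of origin of
high-grade serous ovarian carcinoma. Studies of prophylactically removed
tubes profile the mucosa with single-cell RNA-seq plus single-cell TCR-seq
and ask two kinds of questions:

1. **Transcriptome**: which cell types are present (secretory PAX8⁺ vs
   ciliated TP73⁺ epithelium, fibroblasts, T cells, macrophages,
   endothelium), are carrier fibroblasts enriched for cells expressing
   EMT transcription factors (SNAI1/2, ZEB1/2, TWIST1/2), and does any
   epithelial cluster resemble a known EMT-like secretory subtype?
2. **Repertoire**: after calling paired α/β clonotypes from the TCR contigs,
   are CD8⁺ T cells more clonally expanded in carriers, and do clonal cells
   express more exhaustion markers (PD-1/PDCD1, TIM3/HAVCR2, LAG3, CTLA4,
   TOX, CD39/ENTPD1)?

`fimbria` implements the full chain — file formats, QC, normalization,
marker-based cell typing, empirical-Bayes moderated-t differential
expression, preranked GSEA, observed/expected (ROE) enrichment with
chi-squared tests, mutual-nearest-neighbor (MNN) cluster similarity,
paired-TCR clonotyping with clonality statistics — plus a seeded synthetic
cohort generator with planted ground truth, so every statistical claim in
the package is testable against known effects.

## Worked example 1: published clonality counts

A study reports 1009 clonal vs 452 non-clonal CD8⁺ T cells, with 672
clonal / 242 non-clonal in carriers and 337 / 210 in controls. Reproduce
the headline statistics:

```python
import numpy as np
from fimbria import tcr

flags  = np.array([True]*672 + [False]*242 + [True]*337 + [False]*210)
groups = np.array(["carrier"]*914 + ["control"]*547, dtype=object)
out = tcr.clonality_contingency(flags, groups)   # Yates-corrected chi-squared
print(out["p"])                                  # 2.4821698803720797e-06
print(out["clonal_percent"])                     # {'carrier': 73.52..., 'control': 61.60...}
```

The Yates continuity correction is the default for 2×2 tables (it is what
reproduces the published p = 2.48 × 10⁻⁶; the uncorrected Pearson test
gives 1.9 × 10⁻⁶).

## Worked example 2: synthetic cohort through the full pipeline

Generate a six-sample cohort (3 carriers / 3 controls) with planted
structure — marker-typed cell populations, an EMT secretory subpopulation
in one carrier sample, EMT-TF enrichment in carrier fibroblasts, a 5%
high-mitochondrial tail, and a paired-TCR repertoire with clonal fractions
0.73 vs 0.62 and PD-1/clonality coupling:

```bash
cat > gen.yaml <<'YAML'
cells_per_sample: 300
n_genes: 600
library_size: 600
YAML
fimbria synth --config gen.yaml --seed 7 --out cohort
```

```
cohort written to cohort
```

Each `cohort/<sample>/` directory holds `matrix.mtx`, `features.tsv`,
`barcodes.tsv`, `cells.tsv` and `filtered_contig_annotations.csv`;
`cohort/truth.tsv` carries the planted labels. Then:

```bash
cat > pipeline.yaml <<'YAML'
sample_dirs: [cohort/carrier_1, cohort/carrier_2, cohort/carrier_3,
              cohort/control_1, cohort/control_2, cohort/control_3]
out_dir: out
gmt_path: sets.gmt     # any GMT gene-set file
seed: 7
YAML
fimbria run-all --config pipeline.yaml
```

```
{"n_completed": 7, "out": "out"}
```

Actual output from this run (seed 7): QC removed the high-mito tail
(1800 → 1717 cells), and `out/type_summary.tsv` recovers the planted type
proportions (0.45 / 0.25 / 0.17 / …):

```
major_type   n_cells  percent
epithelial   782      45.54
fibroblast   447      26.03
T            286      16.66
...
```

`out/roe.tsv` shows the planted carrier enrichment of EMT-TFs in
fibroblast cells (ROE > 1 in carriers, BH q across the panel):

```
marker  group    N_o   N_e    ROE    chi2   p          q
SNAI1   carrier  42.0  31.0   1.35   8.49   3.57e-03   1.07e-02
SNAI1   control  18.0  29.0   0.62   ...
SNAI2   carrier  60.0  36.2   1.66   36.9   1.24e-09   7.44e-09
```

`out/gsea.tsv` ranks the planted EMT-like set above a random set:

```
set       ES     NES    p       q       size
EMT_LIKE  0.624  1.559  0.0393  0.0786  10
RANDOM15  0.209  0.586  0.9649  0.9649  15
```

and `out/report.json` records per-stage parameters, timings and the CD8⁺
clonality table. (At this demo size — ~170 CD8⁺ cells — the clonality
difference is *not* significant, p ≈ 0.56; the power analysis in
`docs/methods.md` shows ~900/550 cells are needed, which is what the
acceptance suite uses.)

Every stage is also exposed as its own subcommand (`fimbria qc`,
`annotate`, `de`, `gsea`, `roe`, `similarity`, `tcr`) and as a plain
Python API (`fimbria.qc`, `fimbria.cell_typing`, `fimbria.diffexpr`,
`fimbria.gsea`, `fimbria.roe`, `fimbria.similarity`, `fimbria.tcr`,
`fimbria.synthetic`, `fimbria.pipeline`). `ModeratedTTest` and
`MNNSimilarityScorer` follow scikit-learn estimator conventions.

## Reproduction

Deterministic: the same config + seed reproduces every output file
byte-for-byte (tested). One global seed is split into per-stage seeds by
hashing the stage name, so skipping or inserting a stage does not perturb
the others.

To reproduce the acceptance quantities (published-scale statistics plus
recovery/calibration rates on the synthetic generator):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which recomputes, among others (`value` / `n`):

- `t1` = 2.48 × 10⁻⁶ — Yates chi-squared p of the published clonality table
- `t2` = 73.5 — carrier clonal percentage
- `t3` = 17.1 — T-cell percentage of the cohort (3243 / 19,008 cells)
- `emt_similarity_recovery_rate`, `clonality_detection_rate`,
  `pd1_detection_rate` — fraction of 100 seeded runs in which the planted
  effect is recovered (all 1.0 at seed 1)
- null-calibration KS p-values and eBayes prior-recovery errors

The test suite mirrors these as acceptance tests:

```bash
python -m pytest -q tests/
```

## Layout

```
src/fimbria/        package modules
tests/              unit + property + acceptance tests
scripts/acceptance.py   standalone acceptance computation
docs/methods.md     statistical methods, assumptions and limitations
```
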