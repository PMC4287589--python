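# mscportrait

Genome-scale characterization pipeline for human mesenchymal stromal/stem
cells (MSCs), for transcriptomics researchers who want a tested, reusable
implementation of the classic bulk RNA-seq "expression footprint" analysis:
calling the set of expressed genes from FPKM matrices, testing gene-set
enrichment on that footprint, identifying **meta-regulator** transcription
factors by consensus TFBS over-representation in promoter windows,
profiling promoter methylation of the footprint's TF genes with Illumina
450k Beta values, intersecting two independent differential-expression
engines between tissue origins (bone marrow vs placenta), and assembling
the evidence-weighted TF–TF protein-interaction network.

Every input the pipeline consumes can be generated synthetically with
planted ground truth (`mscportrait.simdata`), so all statistical claims are
backed by recovery and null-calibration tests.

## The statistics at the core

- **Footprint calling.** Per gene, log2(FPKM sum) per tissue and
  log2(mean FPKM) across all samples. The threshold is either the lower-tail
  5% quantile of the positive log2 means (retain the top 95% of the
  expressed component) or the fixed cut-off log2(mean FPKM) ≥ 2 — i.e. 4
  FPKM, roughly one transcript per cell. Zero aggregates map to a
  "not detected" sentinel outside the density.
- **Gene-set enrichment.** Upper-tail hypergeometric test
  p = P(X ≥ k), X ~ Hypergeom(N, K, n) of footprint/set overlap, BH-adjusted
  across sets; rank-sum comparison of expression levels between functional
  categories (housekeeping vs stem-cell vs TF sets).
- **Meta-regulator engine.** PSSMs are built with background-weighted
  pseudocounts and scanned as log2-odds over both strands of three promoter
  windows around the TSS: (−2000, −1), (−5000, −800), (−5000, +200). Hit
  significance uses the *exact* score distribution under the background,
  computed by dynamic programming on a 0.01-log-odds grid (default
  α = 1e−4). Per window, gene-level hits feed a hypergeometric
  over-representation test, BH-corrected across matrices (q < 0.05). A TF
  is selected when significant in ≥ 2 of the 3 window configurations, with
  a −1 penalty if it is ever significant on a random reference gene set
  (RRS) of matched size. Meta-regulators are the TFs selected both for the
  whole footprint (pass one) and for the footprint's TF genes (pass two).
- **Methylation.** Illumina Beta = M/(M + U + 100); CpGs with detection
  p > 0.01 removed; per-CpG median Beta across samples; expressed-TF target
  set vs randomly drawn control TF sets by two-sided rank-sum, overall and
  per CpG-island sub-region (island, N/S shores, N/S shelves, open sea).
- **Differential expression.** An FPKM engine (Welch t on log2(FPKM+1))
  and a count engine (negative-binomial conditional test with
  median-of-ratios size factors and method-of-moments dispersion). The
  consensus set intersects q < 0.05 (FPKM engine) with q < 0.001 (count
  engine); fold-change direction is taken from the FPKM engine and
  disagreements are flagged, not dropped.
- **TF network.** Undirected graph over the footprint's TF genes; duplicate
  PPI evidence rows merge into integer edge weights; unconnected paralogs
  of connected nodes join as flagged isolated nodes.

## Worked example

The numbered drivers under `analysis/` run the whole study on one
deterministic synthetic bundle (1,000 genes, 2 tissues × 3 replicates,
5 planted regulator TFs, 100 planted DE genes at |log2FC| = 3):

```bash
python analysis/01_simulate.py
python analysis/02_footprint.py
python analysis/04_meta_regulators.py
python analysis/06_differential_expression.py
```

which prints (abridged):

```
genes with positive log2 mean FPKM: 501
quantile threshold (q = 0.05):      2.430
footprint at fixed cut-off:         486 genes (402 protein-coding)

pass-one selected TFs: ['G00135', 'G00252', 'G00388', 'G00651', 'G00968']
meta-regulators:       ['G00135', 'G00252', 'G00388', 'G00651', 'G00968']
planted regulators:    ['G00135', 'G00252', 'G00388', 'G00651', 'G00968']
recovery: precision 1.00, recall 1.00

fpkm engine  q < 0.05:  94 genes
count engine q < 0.001: 104 genes
consensus: 92 genes (97.9% of the fpkm-engine set), 37 up / 55 down in the
second group, 0 direction disagreements
planted-truth recovery: recall 0.92, empirical FDR 0.000
```

Reading: of 501 genes in the expressed component, 486 clear the fixed
log2 ≥ 2 cut-off; the two-pass TFBS consensus recovers exactly the five
planted regulators and nothing else; and the dual-engine consensus calls
92 DE genes, all of them planted, missing only the weakest 8% of the
planted set. The same stages are scriptable via the `mscportrait` CLI
(`simulate`, `footprint`, `enrich`, `motifs`-equivalent drivers, `methyl`,
`de`, `network`, `run-all`).

## Layout

```
src/mscportrait/   simdata, footprint, geneset, motifreg, methyl,
                   diffexpr, tfnet, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             unit, property and acceptance suites
docs/methods.md    models, assumptions, parameter choices, limitations
```
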