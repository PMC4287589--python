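# Methods

## Scope and design

The package implements a bulk-RNA-seq characterization pipeline for a
two-tissue MSC design (bone marrow vs placenta, three replicates each) as a
library of independently testable stages plus a synthetic-data module that
generates every input with planted ground truth. The original analysis
leaned on several external tools (transcript assemblers, three separate
TFBS-enrichment web tools, an array-processing stack); here each of those
steps is re-specified as an explicit, seedable statistical procedure so the
pipeline's claims can be verified by recovery and calibration tests rather
than by tool citation.

## Expression footprint

Per-tissue "summarized" expression is the log2 of the FPKM sum over that
tissue's samples; the across-sample mean is summarized as log2(mean FPKM).
Genes whose aggregate is exactly zero receive a *not detected* sentinel
(NaN) and never enter density or quantile computations — log2 of zero would
otherwise inject −∞ into a scale that is conceptually bounded below by
"absent".

Threshold selection supports two modes. The quantile rule computes the
lower-tail q-quantile (default q = 0.05, linear interpolation between order
statistics) **only over genes with positive log2 means**: the positive
region is where the expressed component of the bimodal FPKM mixture lives,
and the rule retains its top 1 − q. The fixed mode uses
log2(mean FPKM) ≥ 2: 4 FPKM is about one transcript per cell for typical
mammalian transcriptomes, making the footprint interpretable as "genes with
at least ~1 mRNA copy per cell". The boundary is inclusive in both modes,
and thresholding is monotone (higher threshold ⇒ subset), which the suite
checks as a property.

## Gene-set enrichment

Overlap significance is the upper-tail hypergeometric probability with the
universe equal to all genes in the supplied annotation — not an implicit
genome-size constant — so N, K, n and k are all reported and reproducible.
Raw p-values are emitted alongside BH-adjusted q across the tested sets.
Category-level expression comparisons use the two-sided rank-sum test
(exact null for small tie-free samples, tie-corrected normal approximation
otherwise).

## Meta-regulator engine

**PSSMs.** Count matrices become frequencies with a background-weighted
pseudocount (total mass 1.0 by default) and log2-odds scores against the
background composition (uniform unless provided).

**Exact score p-values.** Scores are discretized to a 0.01 log-odds grid
and the exact pmf of the window score under the background model is built
by dynamic programming over motif positions (convolution of per-position
4-outcome distributions). The scan threshold at level α is the smallest
grid score s with P(score ≥ s) ≤ α; scanning uses the same integer grid, so
threshold and scores are exactly consistent. The pmf must sum to 1 within
1e−9 and is tested against exhaustive 4^w enumeration for w ≤ 8.

**Scanning.** Both strands are scanned (reverse strand = forward scan with
the reverse-complement matrix); windows containing non-ACGT letters are
skipped. Default α = 1e−4.

**Promoter windows.** Three presets around the TSS — (−2000, −1),
(−5000, −800), (−5000, +200) — in transcription direction. Coordinates are
1-based with **no offset 0**: the TSS is offset +1, so offset o maps to
genomic TSS+o upstream and TSS+o−1 downstream (mirrored and
reverse-complemented on the minus strand). Windows that run past a contig
end are truncated. The engine scans the widest covering window once and
answers per-preset hit queries by offset filtering.

**Voting.** A gene is a "hit" for a matrix if it has ≥ 1 scan hit in the
window (presence/absence, matching gene-level set counting). Per window
configuration, target-vs-background over-representation is the upper-tail
hypergeometric on hit genes, BH-adjusted across matrices; significance is
q < 0.05. A TF is significant in a configuration when any of its matrices
is (the matrix → TF map is an explicit input). The consensus score counts
significant configurations (NA where a TF has no matrix), minus 1 if the
TF was significant on **any** random reference set (RRS) run; selection
requires score ≥ 2, i.e. the "2 of 3 methods" rule. The three external
enrichment tools of the original procedure are represented by the one
engine run under the three window configurations; RRS runs (default 10,
fresh uniform gene sets of the target-set size) are evaluated under the
first configuration, mirroring a single-tool negative control. The penalty
is applied once regardless of how many runs hit.

**Two passes.** Pass one targets all footprint genes against the rest of
the annotation; pass two targets the footprint's TF genes against the rest
of the footprint. Meta-regulators are the intersection of the two
selections.

## Methylation

Beta = M/(M + U + 100) exactly (the +100 regularizer is the platform
standard and bounds Beta in [0, 1)). CpGs with detection p > 0.01 in any
sample are dropped (boundary kept). Per-CpG medians across samples feed all
comparisons; when a gene-level value is needed it is the median of that
gene's CpG medians. The target set (expressed TF genes) is compared against
`n_random` (default 3) control sets drawn without replacement from
non-target TFs — optionally restricted to TFs outside the expressed set —
by two-sided rank-sum, overall and within each island sub-region
(island, N/S-shore, N/S-shelf, open sea). Region classes come from the
input annotation; no genomic re-derivation is attempted. Fewer candidate
controls than the target size is an error rather than a silent shrink.

## Differential expression

The FPKM engine is a per-gene Welch t-test on log2(FPKM + 1); the +1
pseudo-FPKM bounds fold changes for near-zero genes. The count engine
follows the classic negative-binomial conditional-test recipe: size factors
by median-of-ratios against the geometric-mean reference; per-gene
dispersion by method of moments on normalized counts, pooled across the two
groups with (n−1) weights and corrected for the mean inverse size factor;
the per-gene estimate is then floored at the across-gene median dispersion
(a "maximum" sharing rule) because raw moment estimates at n = 3 are noisy
enough to make the test anticonservative — with this floor the null
rejection rate at p < 0.05 sits inside [0.025, 0.075] on no-signal
simulations, which the acceptance suite verifies. The test conditions on
the total normalized count of a gene and sums the probabilities of all
group splits no more likely than the observed one, with group sums
modelled as NB(n·μ, size n/α); the summation window is mean ± 12 SD (exact
to well below double precision). BH adjustment is the direct step-up
definition, cross-checked against statsmodels.

Consensus: q < 0.05 (FPKM engine) ∧ q < 0.001 (count engine). The
asymmetric thresholds compensate for the count engine's laxer behaviour.
Direction is taken from the FPKM engine; sign disagreements between engines
are flagged and retained. Isoform-overlap statistics are pure set
intersections with percentages over the footprint (for the footprint
overlap) and over the consensus set (for the signature overlap); the
differential-isoform gene list is consumed as an input.

## TF network

Edges are kept when both endpoints are in the TF list; duplicate evidence
rows for a pair sum into an integer `evidence` weight (edge multiplicity is
interpreted as "number of experimental evidences", so a pair is one edge).
Isolated TFs are excluded at build time; `add_paralogs` then adds
unconnected TFs that are paralogs of a connected node as flagged isolated
nodes and never adds edges. Exports: SIF and GraphML.

## Synthetic data: what it emulates and what it does not

`simdata` generates, from one seeded config:

- **Expression.** Gene-level log2 FPKM from a two-component Gaussian
  mixture — expressed N(5, 1.5), unexpressed N(−3, 1) — so the components
  are separable and the 95%-quantile rule behaves like the real density;
  within-gene across-sample noise sd 0.25; 10% of unexpressed genes are
  exact zeros to exercise the sentinel. DE genes shift by ±de_log2fc in the
  second group. Counts are round(FPKM · length_kb · library_millions) with
  gene lengths U(0.5, 10) kb and library sizes U(15, 25) million — the
  defining identity of the FPKM unit.
- **Promoters.** One 2,200-bp contig per gene with the TSS placed so the
  contig covers offsets −2000..+200 (the wider presets truncate); i.i.d.
  uniform background; for each regulator TF, sites sampled from its PSSM
  (re-drawn until they clear the α = 1e−4 scan threshold, so planted means
  detectable) are planted at recorded offsets/strands in a fixed fraction
  of target promoters, confined to (−1900, −900) — inside every window
  preset. An optional boost rate plants more densely in TF-gene promoters
  so second-pass enrichment has signal. Motif matrices concentrate 97/100
  counts per column (~15 bits at width 10).
- **Methylation.** M and U solved from a target Beta (0.1 hypomethylated
  vs 0.6 control, Gaussian noise sd 0.05) at fixed total intensity 2,000,
  so Beta recovers the target exactly; 6 region classes with fixed
  proportions; ~1% of detection p-values fail the 0.01 cutoff.
- **PPI.** Independent edges with probability `ppi_edge_prob` and evidence
  1 + Poisson(1.5); a small random paralogy table.

Not emulated: read-level sequencing (no fastq), transcript assembly,
array probe chemistry and normalization, realistic genome coordinates,
correlated motif co-occurrence, and CpG spatial autocorrelation. Passing
recovery tests therefore demonstrates that the *statistical machinery* is
correct under the assumed generative structure, not that real MSC data
would yield the published gene lists.

## Problem sizes and numerical choices

The analysis drivers run one 1,000-gene study (60 TFs, 5 regulators,
30 matrices screened); the acceptance suite uses 300-gene replicates for
the 20-fold regulator-ranking check, 2,000 genes for DE recovery and null
calibration, and a 10,000-gene matrix for the quantile-retention quantity —
sizes at which every result is stable across seeds while the full suite
runs in about a minute. Score discretization is 0.01 log-odds units; the
score pmf must sum to 1 ± 1e−9; quantile convention is linear
interpolation with inclusive boundaries; ties at the footprint threshold
are included; BH maps step-up minima back to input order; the conditional
NB test returns 1.0 for all-zero genes.

## Known limitations

- The engines are deliberately simple re-specifications; they reproduce the
  *consensus layer* semantics, not any external tool bit-for-bit.
- Dispersion sharing by median floor is conservative for genuinely
  low-dispersion genes.
- The RRS control is evaluated under one window configuration; a
  per-configuration RRS would be stricter.
- Promoter extraction assumes TSS annotations are correct and contigs are
  long enough that truncation is rare; heavy truncation weakens the wider
  window presets.
- With only three replicates per group, the count engine's dispersion
  estimates rely on pooling; single-outlier genes can escape detection.
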