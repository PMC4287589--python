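"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a bulk RNA-seq study of
two tissue groups (bone marrow and placenta MSC cultures, three replicates
each): a two-component expressed/unexpressed FPKM distribution, promoters
carrying planted binding sites for designated regulator transcription
factors, Illumina-450k-style M/U methylation intensities, and a TF-TF
protein-interaction edge list.  Every generator records the planted ground
truth so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth

BASES = np.array(list("ACGT"))
REGION_CLASSES = ("island", "N-shore", "S-shore", "N-shelf", "S-shelf", "open-sea")
REGION_PROBS = (0.30, 0.15, 0.15, 0.10, 0.10, 0.20)

#: methylation intensities are generated at a fixed total M+U so that the
#: Illumina Beta = M/(M+U+100) of each record equals its sampled target value
METHYL_TOTAL_INTENSITY = 2000.0

# promoter contigs span offsets -2000..+200 around the TSS (no offset 0)
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200
PLANT_WINDOW = (-1900, -900)  # inside the intersection of all window presets


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study; defaults mirror the real design
    (two tissues x 3 replicates, ~half the genome expressed)."""

    n_genes: int = 2000
    n_samples_per_group: int = 3
    groups: tuple[str, str] = ("BM", "PL")
    expressed_fraction: float = 0.5
    expressed_log2fpkm_mean: float = 5.0
    expressed_log2fpkm_sd: float = 1.5
    unexpressed_log2fpkm_mean: float = -3.0
    unexpressed_log2fpkm_sd: float = 1.0
    sample_log2fpkm_sd: float = 0.25
    n_de_genes: int = 100
    de_log2fc: float = 3.0
    n_tfs: int = 200
    n_regulator_tfs: int = 5
    motif_width: int = 10
    motif_planting_rate: float = 0.5
    promoter_length: int = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
    n_cpg_per_gene: int = 10
    hypomethyl_beta_mean: float = 0.1
    control_beta_mean: float = 0.6
    beta_noise_sd: float = 0.05
    ppi_edge_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("expressed_fraction", "motif_planting_rate", "ppi_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("hypomethyl_beta_mean", "control_beta_mean"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0,1), got {v}")
        for name in (
            "n_genes", "n_samples_per_group", "n_de_genes", "n_tfs",
            "n_regulator_tfs", "motif_width", "promoter_length", "n_cpg_per_gene",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.n_regulator_tfs <= self.n_tfs <= self.n_genes:
            raise ValueError("need n_regulator_tfs <= n_tfs <= n_genes")
        if self.motif_width > self.promoter_length:
            raise ValueError("motif_width must not exceed promoter_length")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def gen_annotation(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene annotation: biotype, contig, strand, TSS, length (kb).

    Each gene owns its own promoter contig; the TSS sits so the contig covers
    offsets -2000..+200 in transcription direction on either strand.
    """
    genes = _gene_ids(cfg.n_genes)
    biotype = np.where(rng.random(cfg.n_genes) < 0.8, "protein_coding", "lincRNA")
    strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    tss = np.where(strand == "+", PROMOTER_UPSTREAM + 1, PROMOTER_DOWNSTREAM)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "biotype": biotype,
            "chrom": [f"contig_{g}" for g in genes],
            "strand": strand,
            "tss": tss,
            "length_kb": rng.uniform(0.5, 10.0, cfg.n_genes),
        }
    ).set_index("gene_id")


def gen_expression(
    cfg: SimConfig, annotation: pd.DataFrame | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Draw FPKM and derived read-count matrices with planted DE genes.

    Returns ``(fpkm, counts, truth, annotation)``.  Counts are obtained as
    ``round(FPKM * gene_length_kb * library_size_millions)`` with per-sample
    library sizes, which is the defining identity of the FPKM unit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if annotation is None:
        annotation = gen_annotation(cfg, rng)
    genes = list(annotation.index)
    n = cfg.n_genes

    n_expr = int(round(cfg.expressed_fraction * n))
    if cfg.n_de_genes > n_expr:
        raise ValueError("n_de_genes exceeds the number of expressed genes")
    order = rng.permutation(n)
    expressed_idx = order[:n_expr]
    expressed = np.zeros(n, dtype=bool)
    expressed[expressed_idx] = True

    base = np.where(
        expressed,
        rng.normal(cfg.expressed_log2fpkm_mean, cfg.expressed_log2fpkm_sd, n),
        rng.normal(cfg.unexpressed_log2fpkm_mean, cfg.unexpressed_log2fpkm_sd, n),
    )

    de_idx = rng.choice(expressed_idx, size=cfg.n_de_genes, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=cfg.n_de_genes)

    # a slice of unexpressed genes is fully silent (exact zeros) to exercise
    # the "not detected" sentinel downstream
    silent = np.zeros(n, dtype=bool)
    unexpr_idx = order[n_expr:]
    silent[unexpr_idx[rng.random(len(unexpr_idx)) < 0.1]] = True

    samples, group_of = [], {}
    for g in cfg.groups:
        for r in range(1, cfg.n_samples_per_group + 1):
            s = f"{g}{r}"
            samples.append(s)
            group_of[s] = g

    log2 = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        log2[:, j] = base + rng.normal(0.0, cfg.sample_log2fpkm_sd, n)
        if group_of[s] == cfg.groups[1]:
            log2[de_idx, j] += de_sign * cfg.de_log2fc
    fpkm = np.exp2(log2)
    fpkm[silent, :] = 0.0

    lib_millions = rng.uniform(15.0, 25.0, len(samples))
    length_kb = annotation["length_kb"].to_numpy()
    counts = np.rint(fpkm * length_kb[:, None] * lib_millions[None, :])

    gene_arr = np.asarray(genes)
    tf_pool_expr = rng.choice(expressed_idx, size=min(cfg.n_tfs // 2, n_expr), replace=False)
    n_rest = cfg.n_tfs - len(tf_pool_expr)
    tf_pool_unexpr = rng.choice(unexpr_idx, size=min(n_rest, len(unexpr_idx)), replace=False)
    tf_idx = np.concatenate([tf_pool_expr, tf_pool_unexpr]).astype(int)
    regulator_idx = rng.choice(tf_pool_expr, size=cfg.n_regulator_tfs, replace=False)

    annotation = annotation.copy()
    annotation["is_tf"] = False
    annotation.iloc[tf_idx, annotation.columns.get_loc("is_tf")] = True
    # regulator TF genes are protein-coding expressed genes by construction
    annotation.iloc[regulator_idx, annotation.columns.get_loc("biotype")] = "protein_coding"

    truth = GroundTruth(
        expressed_gene_ids=frozenset(map(str, gene_arr[expressed & ~silent])),
        de_genes={str(gene_arr[i]): s * cfg.de_log2fc for i, s in zip(de_idx, de_sign)},
        tf_ids=tuple(map(str, gene_arr[tf_idx])),
        regulator_tf_ids=tuple(map(str, gene_arr[regulator_idx])),
        hypomethylated_gene_ids=frozenset(
            map(str, gene_arr[np.intersect1d(tf_idx, np.flatnonzero(expressed & ~silent))])
        ),
    )
    fpkm_m = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples), group_of)
    counts_m = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), dict(group_of))
    return fpkm_m, counts_m, truth, annotation


def gen_motifs(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Random sharp count matrices (one per TF) plus the matrix->TF map.

    Each column concentrates 97 of 100 counts on one base (~1.6 bits per
    position), so a width-10 motif carries ~15 bits and planted sites score
    far above the scan threshold.
    """
    from .motifreg import Pssm, build_pssm

    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    pssms: list[Pssm] = []
    for i, tf in enumerate(range(cfg.n_tfs), start=1):
        consensus = rng.integers(0, 4, cfg.motif_width)
        counts = np.full((4, cfg.motif_width), 1.0)
        counts[consensus, np.arange(cfg.motif_width)] = 97.0
        pssms.append(build_pssm(counts, matrix_id=f"MAT{i:04d}", tf=f"TF{i:04d}"))
    return pssms


def gen_promoters(
    cfg: SimConfig,
    pssms,
    truth: GroundTruth,
    annotation: pd.DataFrame,
    tf_of_pssm: dict[str, str] | None = None,
    targets=None,
    boost_genes=None,
    boost_rate: float | None = None,
    scan_alpha: float = 1e-4,
) -> tuple[dict[str, str], GroundTruth]:
    """Per-gene promoter contigs with binding sites planted for regulators.

    Background bases are i.i.d. uniform.  For every regulator TF a site drawn
    from its PSSM frequencies (re-drawn until it scores at or above the scan
    threshold at ``scan_alpha``, so every planted site is detectable) is
    planted, at a recorded offset and strand, in ``motif_planting_rate`` of
    the target promoters (default: the expressed "footprint" genes);
    non-regulator motifs are never planted.  ``boost_genes``/``boost_rate``
    optionally plant a different fraction of a subset (e.g. TF-gene
    promoters) so second-pass enrichment has signal.  Sites are confined to
    the region every promoter-window preset covers.  Returns
    ``(contig->sequence, truth)`` with ``truth.planted_sites`` filled in.
    """
    from .motifreg import score_pvalue_table

    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    n_contig = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
    seqs = {
        row.chrom: rng.integers(0, 4, n_contig)
        for row in annotation.itertuples()
    }

    reg_ids = list(truth.regulator_tf_ids)
    pssm_by_tf = {}
    for p in pssms:
        tf = tf_of_pssm.get(p.matrix_id, p.tf) if tf_of_pssm else p.tf
        pssm_by_tf.setdefault(tf, p)
    if targets is None:
        targets = truth.expressed_gene_ids
    targets = sorted(targets)
    boost = sorted(set(boost_genes or ()) & set(targets))
    base_targets = [g for g in targets if g not in set(boost)]
    records = []
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in targets}

    for k, reg in enumerate(reg_ids):
        pssm = pssms[k] if reg not in pssm_by_tf else pssm_by_tf[reg]
        w = pssm.width
        thr = score_pvalue_table(pssm).threshold(scan_alpha)
        int_scores = pssm.int_scores
        chosen = []
        for pool, rate in ((base_targets, cfg.motif_planting_rate),
                           (boost, boost_rate if boost_rate is not None
                            else cfg.motif_planting_rate)):
            n_plant = int(round(rate * len(pool)))
            if n_plant:
                chosen.extend(np.asarray(pool)[rng.choice(len(pool), n_plant, replace=False)])
        for gene in chosen:
            row = annotation.loc[gene]
            for _ in range(100):
                off = int(rng.integers(PLANT_WINDOW[0], PLANT_WINDOW[1] - w + 2))
                span = (off, off + w - 1)
                if all(span[1] < a or span[0] > b for a, b in occupied[gene]):
                    break
            else:
                raise RuntimeError(f"could not place non-overlapping site in {gene}")
            occupied[gene].append(span)
            for _ in range(100):
                site = np.array([rng.choice(4, p=pssm.freqs[:, i]) for i in range(w)])
                if int_scores[site, np.arange(w)].sum() >= thr:
                    break
            else:
                raise RuntimeError("could not draw a site above the scan threshold")
            site_strand = "+" if rng.random() < 0.5 else "-"
            if site_strand == "-":
                site = 3 - site[::-1]
            # offset -> 0-based position within the promoter (offsets skip 0)
            pos0 = off + PROMOTER_UPSTREAM if off < 0 else off - 1 + PROMOTER_UPSTREAM
            contig = seqs[row.chrom]
            if row.strand == "+":
                contig[pos0 : pos0 + w] = site
            else:
                contig[n_contig - pos0 - w : n_contig - pos0] = 3 - site[::-1]
            records.append(
                {"gene": gene, "tf": reg, "matrix_id": pssm.matrix_id,
                 "offset": off, "strand": site_strand}
            )

    fasta = {name: "".join(BASES[v]) for name, v in seqs.items()}
    planted = pd.DataFrame(records, columns=["gene", "tf", "matrix_id", "offset", "strand"])
    return fasta, replace(truth, planted_sites=planted)


def gen_methylation(cfg: SimConfig, truth: GroundTruth, n_samples: int = 5) -> pd.DataFrame:
    """Illumina-450k-style M/U intensity table for the TF genes (5 samples).

    CpGs of hypomethylated genes target Beta ``hypomethyl_beta_mean``, the
    rest ``control_beta_mean``; M and U are solved from the target Beta at a
    fixed total intensity, so Beta = M/(M+U+100) recovers the target exactly.
    About 1% of detection p-values exceed the 0.01 filter cutoff.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3)
    genes = [g for g in truth.tf_ids for _ in range(cfg.n_cpg_per_gene)]
    n = len(genes)
    if n == 0:
        cols = ["cpg", "gene", "region"]
        for j in range(1, n_samples + 1):
            cols += [f"M_S{j}", f"U_S{j}", f"detp_S{j}"]
        return pd.DataFrame(columns=cols).set_index("cpg")

    hypo = np.array([g in truth.hypomethylated_gene_ids for g in genes])
    target = np.where(hypo, cfg.hypomethyl_beta_mean, cfg.control_beta_mean)
    region = rng.choice(REGION_CLASSES, size=n, p=REGION_PROBS)

    out = {"cpg": [f"cg{i:07d}" for i in range(1, n + 1)], "gene": genes, "region": region}
    T = METHYL_TOTAL_INTENSITY
    for j in range(1, n_samples + 1):
        b = np.clip(target + rng.normal(0.0, cfg.beta_noise_sd, n), 0.0, T / (T + 100.0))
        m = b * (T + 100.0)
        out[f"M_S{j}"] = m
        out[f"U_S{j}"] = T - m
        detp = rng.uniform(0.0, 0.01, n)
        fail = rng.random(n) < 0.01
        detp[fail] = rng.uniform(0.011, 0.5, fail.sum())
        out[f"detp_S{j}"] = detp
    return pd.DataFrame(out).set_index("cpg")


def gen_ppi(
    cfg: SimConfig, tf_ids, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random TF-TF evidence edge list plus a small paralogy table."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 4)
    tf_ids = list(tf_ids)
    edges = []
    for i in range(len(tf_ids)):
        for j in range(i + 1, len(tf_ids)):
            if rng.random() < cfg.ppi_edge_prob:
                edges.append((tf_ids[i], tf_ids[j], int(1 + rng.poisson(1.5))))
    edges_df = pd.DataFrame(edges, columns=["tf_a", "tf_b", "evidence"])
    n_par = max(len(tf_ids) // 10, 0)
    pairs = []
    if len(tf_ids) >= 2:
        for _ in range(n_par):
            a, b = rng.choice(len(tf_ids), size=2, replace=False)
            pairs.append((tf_ids[a], tf_ids[b]))
    par_df = pd.DataFrame(pairs, columns=["tf", "paralog_of"])
    return edges_df, par_df


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write
    from Bio.SeqRecord import SeqRecord

    write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        path,
        "fasta",
    )
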