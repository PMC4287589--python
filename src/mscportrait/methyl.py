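"""Illumina 450k-style methylation profiling of TF genes.

Beta values follow the platform's standard Beta = M/(M+U+100); CpGs failing
the detection p-value filter (p > 0.01) are removed; per-CpG medians across
samples feed the comparisons; the expressed-TF target set is compared with
randomly drawn control TF sets per CpG-island sub-region (island, shores,
shelves, open sea) with two-sided rank-sum tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import REGION_CLASSES

DETECTION_P_CUTOFF = 0.01


def beta(M, U, offset: float = 100.0):
    """Illumina Beta value: M / (M + U + 100)."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be non-negative")
    out = M / (M + U + offset)
    return float(out) if out.ndim == 0 else out


def _sample_ids(records: pd.DataFrame) -> list[str]:
    return [c[2:] for c in records.columns if c.startswith("M_")]


def filter_detection(records: pd.DataFrame, cutoff: float = DETECTION_P_CUTOFF) -> pd.DataFrame:
    """Drop CpGs with detection p > cutoff in any sample (boundary kept)."""
    if records.empty:
        return records
    detp = records[[f"detp_{s}" for s in _sample_ids(records)]]
    return records[(detp <= cutoff).all(axis=1)]


def beta_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG, per-sample Beta values."""
    out = {}
    for s in _sample_ids(records):
        out[s] = beta(records[f"M_{s}"].to_numpy(), records[f"U_{s}"].to_numpy())
    return pd.DataFrame(out, index=records.index)


def median_beta(records: pd.DataFrame) -> pd.Series:
    """Median Beta across samples per CpG (even count: mean of central pair)."""
    b = beta_matrix(records)
    return b.median(axis=1).rename("median_beta")


def gene_beta(records: pd.DataFrame) -> pd.Series:
    """Gene-level Beta: median of the gene's per-CpG median Betas."""
    med = median_beta(records)
    return med.groupby(records["gene"]).median()


def compare_tf_sets(records: pd.DataFrame, target_tf_genes, all_tf_genes,
                    n_random: int = 3, seed: int = 0,
                    expressed_tf_genes=None) -> pd.DataFrame:
    """Target-TF vs random-control-TF hypomethylation comparison.

    Controls are drawn without replacement from the non-target TFs (by
    default from TFs outside the target set; pass ``expressed_tf_genes`` to
    restrict the pool to TFs not in that set, i.e. "not expressed").  One
    two-sided rank-sum test per random set over all CpGs and per island
    sub-region.
    """
    if n_random < 1:
        raise ValueError("need at least one random control set")
    rng = np.random.default_rng(seed)
    target = set(target_tf_genes)
    pool = set(all_tf_genes) - target
    if expressed_tf_genes is not None:
        pool -= set(expressed_tf_genes)
    pool = sorted(pool)
    if len(pool) < len(target):
        raise ValueError(
            f"only {len(pool)} non-target TFs available for controls of size {len(target)}"
        )
    med = median_beta(records)
    gene = records["gene"]
    region = records["region"]

    rows = []
    tgt_mask = gene.isin(target)
    for r in range(1, n_random + 1):
        ctrl = set(rng.choice(pool, size=len(target), replace=False))
        ctrl_mask = gene.isin(ctrl)
        for reg in ("all",) + REGION_CLASSES:
            m = np.ones(len(records), dtype=bool) if reg == "all" else (region == reg).to_numpy()
            x = med[tgt_mask.to_numpy() & m]
            y = med[ctrl_mask.to_numpy() & m]
            if len(x) == 0 or len(y) == 0:
                p = np.nan
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append({
                "random_set": r, "region": reg,
                "n_target_cpgs": int(len(x)), "n_control_cpgs": int(len(y)),
                "target_median": float(np.median(x)) if len(x) else np.nan,
                "control_median": float(np.median(y)) if len(y) else np.nan,
                "p": p,
            })
    return pd.DataFrame(rows)
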