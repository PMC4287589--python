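"""Expression-footprint calling from an FPKM matrix.

Per-tissue summarized log2(FPKM sums), overall log2(FPKM means), the
lower-tail quantile cut-off rule (keep the top 95% of genes with positive
log2 means) or a fixed threshold (log2 mean FPKM >= 2, about one transcript
per cell), and the biotype-filtered footprint itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

#: fixed cut-off used in the published analysis: log2(FPKM mean) >= 2
DEFAULT_FIXED_THRESHOLD = 2.0


def summarize(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log2 of the FPKM sum per group and of the overall mean.

    Genes whose aggregate is zero get NaN ("not detected"); they are
    excluded from density/quantile computations downstream.
    """
    def safe_log2(v: np.ndarray) -> np.ndarray:
        out = np.full(v.shape, np.nan)
        np.log2(v, out=out, where=v > 0)
        return out

    out = pd.DataFrame(index=mat.gene_ids)
    for g in mat.group_labels():
        s = mat.data[mat.samples_in(g)].sum(axis=1).to_numpy()
        out[f"log2_sum_{g}"] = safe_log2(s)
    out["log2_mean"] = safe_log2(mat.data.mean(axis=1).to_numpy())
    return out


def quantile_threshold(log2_means, q: float = 0.05) -> float:
    """Lower-tail q-quantile of the positive log2 means.

    The distribution is built only over genes with log2 mean > 0; the
    returned threshold therefore retains the top 1-q of those genes.
    Linear interpolation between order statistics; NaNs ignored.
    """
    v = np.asarray(log2_means, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        raise ValueError("no positive log2 means to compute a quantile over")
    return float(np.quantile(v, q))


@dataclass
class Footprint:
    gene_ids: tuple
    threshold: float
    biotype_filtered: bool
    table: pd.DataFrame  # gene_id-indexed: log2_mean + per-group log2 sums

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene) -> bool:
        return gene in set(self.gene_ids)


def call_footprint(summary: pd.DataFrame, threshold: float,
                   annotation: pd.DataFrame | None = None,
                   biotype_filter: str | None = None) -> Footprint:
    """Genes with log2 mean FPKM >= threshold (boundary inclusive),
    optionally restricted to one biotype (e.g. ``protein_coding``)."""
    keep = summary["log2_mean"] >= threshold
    if biotype_filter is not None:
        if annotation is None:
            raise ValueError("biotype filtering requires an annotation")
        missing = summary.index.difference(annotation.index)
        if len(missing):
            raise ValueError(f"annotation missing {len(missing)} gene ids")
        keep &= annotation.loc[summary.index, "biotype"] == biotype_filter
    table = summary[keep.fillna(False)]
    return Footprint(
        gene_ids=tuple(table.index),
        threshold=threshold,
        biotype_filtered=biotype_filter is not None,
        table=table,
    )


def report_markers(summary: pd.DataFrame, marker_ids,
                   sentinel: str = "not detected") -> pd.DataFrame:
    """Per-group log2(FPKM sum) table for a handful of marker genes."""
    cols = [c for c in summary.columns if c.startswith("log2_sum_")]
    rows = {}
    for m in marker_ids:
        if m not in summary.index:
            rows[m] = {c: sentinel for c in cols}
        else:
            rows[m] = {
                c: (sentinel if not np.isfinite(summary.loc[m, c]) else summary.loc[m, c])
                for c in cols
            }
    return pd.DataFrame.from_dict(rows, orient="index")[cols]
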