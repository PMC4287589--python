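"""Two-engine differential expression with an asymmetric-threshold consensus.

The FPKM engine is a Welch t-test on log2(FPKM+1); the count engine is a
negative-binomial conditional (exact-style) test with median-of-ratios size
factors and method-of-moments dispersion.  Genes significant in both
engines at the asymmetric q-value thresholds (0.05 for the FPKM engine,
0.001 for the count engine) form the consensus set; fold-change direction
is taken from the FPKM engine, with a flag where the engines disagree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

Q_FPKM = 0.05
Q_COUNT = 0.001


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _two_groups(mat: ExpressionMatrix) -> tuple[str, str]:
    groups = mat.group_labels()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    return groups[0], groups[1]


def fpkm_engine(fpkm: ExpressionMatrix) -> pd.DataFrame:
    """Welch t-test per gene on log2(FPKM+1); log2fc = second group over first."""
    g_ref, g_alt = _two_groups(fpkm)
    x = np.log2(fpkm.data[fpkm.samples_in(g_ref)].to_numpy() + 1.0)
    y = np.log2(fpkm.data[fpkm.samples_in(g_alt)].to_numpy() + 1.0)
    lfc = y.mean(axis=1) - x.mean(axis=1)
    res = stats.ttest_ind(y, x, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame(
        {"engine": "fpkm_engine", "log2fc": lfc, "p": p, "q": bh_adjust(p)},
        index=fpkm.gene_ids,
    )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization (geometric-mean reference)."""
    with np.errstate(divide="ignore"):
        log_gm = np.log(counts).mean(axis=1)
    ok = np.isfinite(log_gm)
    if not ok.any():
        raise ValueError("no gene with all-positive counts for size factors")
    ratios = np.log(counts[ok]) - log_gm[ok, None]
    return np.exp(np.median(ratios, axis=0))


def _dispersion(q: np.ndarray, group_cols: list[np.ndarray], inv_sf_mean: float) -> np.ndarray:
    """Per-gene NB dispersion, method of moments pooled across the groups,
    stabilized by the across-gene median (a maximum sharing rule)."""
    alphas = np.zeros(q.shape[0])
    wsum = 0.0
    for cols in group_cols:
        sub = q[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * inv_sf_mean) / m**2
        a = np.where(np.isfinite(a), a, 0.0)
        w = len(cols) - 1
        alphas += w * a
        wsum += w
    alpha = np.clip(alphas / wsum, 0.0, 10.0)
    floor = max(float(np.median(alpha)), 1e-8)
    return np.maximum(alpha, floor)


def count_engine(counts: ExpressionMatrix) -> pd.DataFrame:
    """NB conditional test per gene on read counts.

    Given the total normalized count of a gene across both groups, the
    two-sided p-value sums the probabilities of all group-A totals no more
    likely than the observed one, with group totals modelled as NB with the
    pooled mean and the estimated dispersion.
    """
    g_ref, g_alt = _two_groups(counts)
    cols_ref = [counts.sample_ids.index(s) for s in counts.samples_in(g_ref)]
    cols_alt = [counts.sample_ids.index(s) for s in counts.samples_in(g_alt)]
    c = counts.data.to_numpy(dtype=float)
    sf = size_factors(c)
    q = c / sf[None, :]
    alpha = _dispersion(q, [np.array(cols_ref), np.array(cols_alt)],
                        float(np.mean(1.0 / sf)))

    m_ref = q[:, cols_ref].mean(axis=1)
    m_alt = q[:, cols_alt].mean(axis=1)
    lfc = np.log2((m_alt + 0.5) / (m_ref + 0.5))
    m_all = q.mean(axis=1)

    n_ref, n_alt = len(cols_ref), len(cols_alt)
    ka = np.rint(q[:, cols_ref].sum(axis=1)).astype(np.int64)
    kb = np.rint(q[:, cols_alt].sum(axis=1)).astype(np.int64)
    p = np.ones(c.shape[0])
    for i in range(c.shape[0]):
        p[i] = _conditional_nb_p(int(ka[i]), int(ka[i] + kb[i]), float(m_all[i]),
                                 float(alpha[i]), n_ref, n_alt)
    return pd.DataFrame(
        {"engine": "count_engine", "log2fc": lfc, "p": p, "q": bh_adjust(p)},
        index=counts.gene_ids,
    )


def _conditional_nb_p(ka: int, total: int, mean: float, alpha: float,
                      n_ref: int, n_alt: int) -> float:
    """P-value of the observed split of ``total`` between the groups."""
    if total == 0 or mean <= 0:
        return 1.0
    mu_ref, mu_alt = mean * n_ref, mean * n_alt
    # sum over a window where the conditional mass lives
    frac = n_ref / (n_ref + n_alt)
    center = total * frac
    sd = np.sqrt(total * frac * (1 - frac) + alpha * center**2 / n_ref)
    lo = int(max(0, np.floor(min(center, ka) - 12 * sd - 10)))
    hi = int(min(total, np.ceil(max(center, ka) + 12 * sd + 10)))
    grid = np.arange(lo, hi + 1)
    if alpha < 1e-8:
        lp = stats.poisson.logpmf(grid, mu_ref) + stats.poisson.logpmf(total - grid, mu_alt)
    else:
        r_ref, r_alt = n_ref / alpha, n_alt / alpha
        lp = (stats.nbinom.logpmf(grid, r_ref, r_ref / (r_ref + mu_ref))
              + stats.nbinom.logpmf(total - grid, r_alt, r_alt / (r_alt + mu_alt)))
    lp -= lp.max()
    w = np.exp(lp)
    obs = w[ka - lo] if lo <= ka <= hi else 0.0
    return float(min(1.0, w[w <= obs * (1 + 1e-12)].sum() / w.sum()))


def consensus_de(res_fpkm: pd.DataFrame, res_count: pd.DataFrame,
                 q_fpkm: float = Q_FPKM, q_count: float = Q_COUNT) -> pd.DataFrame:
    """Intersection of the engines' significant sets at asymmetric q cut-offs.

    Direction comes from the FPKM engine; rows where the engines' fold
    changes point opposite ways are kept but flagged.
    """
    genes = res_fpkm.index.intersection(res_count.index)
    a = res_fpkm.loc[genes]
    b = res_count.loc[genes]
    member = (a["q"] < q_fpkm) & (b["q"] < q_count)
    out = pd.DataFrame(
        {
            "log2fc_fpkm": a["log2fc"], "q_fpkm": a["q"],
            "log2fc_count": b["log2fc"], "q_count": b["q"],
            "direction": np.where(a["log2fc"] >= 0, "up", "down"),
            "direction_disagrees": np.sign(a["log2fc"]) * np.sign(b["log2fc"]) < 0,
            "consensus": member,
        },
        index=genes,
    )
    return out


def de_summary(cons: pd.DataFrame, q_fpkm: float = Q_FPKM, q_count: float = Q_COUNT) -> dict:
    n_a = int((cons["q_fpkm"] < q_fpkm).sum())
    n_b = int((cons["q_count"] < q_count).sum())
    n_both = int(cons["consensus"].sum())
    return {
        "n_significant_fpkm_engine": n_a,
        "n_significant_count_engine": n_b,
        "n_consensus": n_both,
        "consensus_pct_of_fpkm_engine": 100.0 * n_both / n_a if n_a else 0.0,
        "n_direction_disagreements": int((cons["consensus"] & cons["direction_disagrees"]).sum()),
        "n_up": int((cons["consensus"] & (cons["direction"] == "up")).sum()),
        "n_down": int((cons["consensus"] & (cons["direction"] == "down")).sum()),
    }


def isoform_overlap(splicing_genes, consensus_genes, footprint_genes) -> dict:
    """Overlap of differential-isoform genes with the footprint and the
    consensus DE signature, as counts and percentages."""
    sp = set(splicing_genes)
    fp = set(footprint_genes)
    cons = set(consensus_genes)
    n_fp = len(sp & fp)
    n_cons = len(sp & cons)
    return {
        "n_splicing": len(sp),
        "n_in_footprint": n_fp,
        "pct_of_footprint": 100.0 * n_fp / len(fp) if fp else 0.0,
        "n_in_consensus": n_cons,
        "pct_of_consensus": 100.0 * n_cons / len(cons) if cons else 0.0,
    }
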