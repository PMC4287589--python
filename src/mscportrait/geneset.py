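"""Gene-set mapping onto the footprint: hypergeometric enrichment and
rank-based comparison of expression-level distributions between functional
categories (housekeeping, stem-cell, transcription-factor sets)."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    name: str
    universe_size: int  # N
    footprint_size: int  # K
    set_size: int  # n
    overlap: int  # k
    p: float
    q: float | None = None

    def as_dict(self) -> dict:
        return {
            "set": self.name, "N": self.universe_size, "K": self.footprint_size,
            "n": self.set_size, "k": self.overlap, "p": self.p, "q": self.q,
        }


def hypergeom_test(gene_set: GeneSet, footprint, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric test of footprint/set overlap.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size, K the
    footprint size, n the set size and k the overlap.  Ids outside the
    universe are dropped (with a logged count).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = set(gene_set.members)
    dropped = len(members - universe)
    if dropped:
        log.info("%s: dropped %d ids outside the universe", gene_set.name, dropped)
    members &= universe
    fp = set(footprint) & universe
    k = len(members & fp)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(fp), len(members)))
    return EnrichmentResult(gene_set.name, len(universe), len(fp), len(members), k, p)


def enrich_all(sets, footprint, universe) -> pd.DataFrame:
    """Run hypergeom_test for each set; add BH-adjusted q across sets."""
    from .diffexpr import bh_adjust

    results = [hypergeom_test(s, footprint, universe) for s in sets]
    df = pd.DataFrame([r.as_dict() for r in results]).set_index("set")
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def compare_categories(values_by_category: dict) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between category value vectors.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise (scipy's Mann-Whitney U).
    """
    rows = []
    names = list(values_by_category)
    for a, b in itertools.combinations(names, 2):
        x = np.asarray(values_by_category[a], float)
        y = np.asarray(values_by_category[b], float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append({"category_a": a, "category_b": b,
                     "n_a": len(x), "n_b": len(y),
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
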