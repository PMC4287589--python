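"""Map reference gene sets onto the footprint and test enrichment.

The planted-expressed set plays the role of an always-expressed reference
(housekeeping-like); the TF gene set mirrors the census-of-TFs mapping.
Also compares expression-level distributions between functional categories
with rank-sum tests.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, load_study

from mscportrait import footprint
from mscportrait.geneset import compare_categories, enrich_all


def main() -> None:
    inputs, truth = load_study()
    summary = footprint.summarize(inputs.fpkm)
    fp = footprint.call_footprint(summary, footprint.DEFAULT_FIXED_THRESHOLD)
    universe = list(inputs.annotation.index)

    enr = enrich_all(inputs.gene_sets, fp.gene_ids, universe)
    print("hypergeometric enrichment on the footprint:")
    print(enr[["N", "K", "n", "k", "p", "q"]].to_string())
    enr.to_csv(RESULTS / "enrichment.tsv", sep="\t")

    tf_in_fp = sorted(set(truth.tf_ids) & set(fp.gene_ids))
    other_fp = sorted(set(fp.gene_ids) - set(tf_in_fp))
    cats = {
        "TF": summary.loc[tf_in_fp, "log2_mean"].to_numpy(),
        "non-TF": summary.loc[other_fp, "log2_mean"].to_numpy(),
    }
    comp = compare_categories(cats)
    print("\nexpression-level comparison between categories:")
    print(comp.to_string(index=False))
    comp.to_csv(RESULTS / "category_comparison.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
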