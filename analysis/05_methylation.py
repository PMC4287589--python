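"""Methylation Beta-value profiling of the footprint's TF genes.

Filters CpGs by detection p-value, computes per-CpG median Betas across the
five samples, and compares the expressed-TF target set against random
control TF sets, overall and per CpG-island sub-region.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, RUN, STUDY, load_study

from mscportrait import footprint, methyl


def main() -> None:
    inputs, truth = load_study()
    summary = footprint.summarize(inputs.fpkm)
    fp = footprint.call_footprint(summary, footprint.DEFAULT_FIXED_THRESHOLD)
    target = sorted(set(inputs.tf_ids) & set(fp.gene_ids))

    kept = methyl.filter_detection(inputs.methylation)
    print(f"CpGs: {len(inputs.methylation)} in, {len(kept)} pass the "
          f"detection p <= {methyl.DETECTION_P_CUTOFF} filter")
    print(f"target: {len(target)} expressed TF genes; controls drawn from "
          f"{len(set(inputs.tf_ids)) - len(target)} other TFs")

    res = methyl.compare_tf_sets(kept, target, inputs.tf_ids,
                                 n_random=RUN.n_random_methyl_sets, seed=STUDY.seed)
    res.to_csv(RESULTS / "methylation_comparison.tsv", sep="\t", index=False)
    overall = res[res["region"] == "all"]
    print("\ntarget vs random control TF sets (median Beta, rank-sum p):")
    print(overall[["random_set", "target_median", "control_median", "p"]]
          .to_string(index=False))
    by_region = res[res["region"] != "all"].groupby("region")["p"].median()
    print("\nmedian p per island sub-region:")
    print(by_region.to_string())


if __name__ == "__main__":
    main()
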