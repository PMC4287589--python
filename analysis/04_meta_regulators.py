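"""Two-pass meta-regulator search over the study promoters.

Pass one votes on TFBS over-representation in the promoters of all
footprint genes under the three promoter-window configurations; pass two
repeats the vote on the footprint's TF genes alone, with random reference
sets (RRS) as a negative control.  TFs selected by both passes are the
meta-regulators; the script scores recovery of the planted regulators.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import N_MATRICES_SCREENED, RESULTS, RUN, STUDY, load_study

from mscportrait import footprint, motifreg


def main() -> None:
    inputs, truth = load_study()
    summary = footprint.summarize(inputs.fpkm)
    fp = footprint.call_footprint(summary, footprint.DEFAULT_FIXED_THRESHOLD)
    tf_genes = sorted(set(inputs.tf_ids) & set(fp.gene_ids))

    panel = inputs.pssms[:N_MATRICES_SCREENED]
    tfs = sorted(inputs.tf_of_matrix[p.matrix_id] for p in panel)
    print(f"screening {len(panel)} matrices over {len(inputs.genome)} promoters, "
          f"alpha = {RUN.scan_alpha:g}, {RUN.rrs_runs} RRS runs")
    screen = motifreg.MotifScreen(panel, inputs.annotation, inputs.genome,
                                  alpha=RUN.scan_alpha)
    res = motifreg.meta_regulators(screen, fp.gene_ids, tf_genes,
                                   set(inputs.annotation.index),
                                   inputs.tf_of_matrix, tfs,
                                   rrs_runs=RUN.rrs_runs, seed=STUDY.seed)

    res["pass1"].to_csv(RESULTS / "tfbs_pass1.tsv", sep="\t")
    res["pass2"].to_csv(RESULTS / "tfbs_pass2.tsv", sep="\t")

    planted = set(truth.regulator_tf_ids)
    meta = set(res["meta_regulators"])
    print(f"pass-one selected TFs: {res['selected']}")
    print(f"meta-regulators:       {sorted(meta)}")
    print(f"planted regulators:    {sorted(planted)}")
    tp = len(meta & planted)
    print(f"recovery: precision {tp / len(meta) if meta else float('nan'):.2f}, "
          f"recall {tp / len(planted):.2f}")


if __name__ == "__main__":
    main()
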