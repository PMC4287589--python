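"""Generate the synthetic study bundle and write it to disk.

Emulates the inputs of a two-tissue MSC RNA-seq study: FPKM and read-count
matrices with planted DE genes, promoter contigs with planted regulator
binding sites, a 450k-style methylation table, and a TF-TF PPI edge list.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, STUDY, load_study

from mscportrait.motifreg import write_jaspar
from mscportrait.simdata import write_fasta


def main() -> None:
    inputs, truth = load_study()
    out = RESULTS / "simulated_inputs"
    out.mkdir(parents=True, exist_ok=True)

    inputs.fpkm.to_tsv(out / "fpkm.tsv")
    inputs.counts.to_tsv(out / "counts.tsv")
    inputs.annotation.to_csv(out / "annotation.tsv", sep="\t")
    write_fasta(inputs.genome, out / "promoters.fa")
    write_jaspar(inputs.pssms, out / "motifs.jaspar")
    inputs.methylation.to_csv(out / "methylation.tsv", sep="\t")
    inputs.ppi_edges.to_csv(out / "ppi.tsv", sep="\t", index=False)
    inputs.paralogy.to_csv(out / "paralogs.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps({
        "n_expressed": len(truth.expressed_gene_ids),
        "regulator_tfs": list(truth.regulator_tf_ids),
        "n_de_genes": len(truth.de_genes),
        "n_planted_sites": int(len(truth.planted_sites)),
    }, indent=2))

    print(f"study: {STUDY.n_genes} genes, seed {STUDY.seed}")
    print(f"  expressed (truth): {len(truth.expressed_gene_ids)}")
    print(f"  planted DE genes:  {len(truth.de_genes)} at |log2FC| = {STUDY.de_log2fc}")
    print(f"  regulator TFs:     {list(truth.regulator_tf_ids)}")
    print(f"  planted TFBS:      {len(truth.planted_sites)}")
    print(f"bundle written to {out}")


if __name__ == "__main__":
    main()
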