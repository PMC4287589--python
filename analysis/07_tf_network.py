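"""Assemble the evidence-weighted TF-TF interaction network.

Restricts the PPI edge list to the footprint's TF genes, merges duplicate
evidence rows into integer edge weights, adds unconnected paralogs of
connected nodes as flagged isolated nodes, and writes SIF/GraphML exports.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, load_study

from mscportrait import footprint, tfnet


def main() -> None:
    inputs, truth = load_study()
    summary = footprint.summarize(inputs.fpkm)
    fp = footprint.call_footprint(summary, footprint.DEFAULT_FIXED_THRESHOLD)
    tf_genes = sorted(set(inputs.tf_ids) & set(fp.gene_ids))

    net = tfnet.build(tf_genes, inputs.ppi_edges)
    net = tfnet.add_paralogs(net, inputs.paralogy, tf_genes)
    s = tfnet.summarize(net)

    print(f"TF genes in footprint: {len(tf_genes)}")
    print(f"network: {s['n_nodes']} nodes, {s['n_edges']} edges, "
          f"{s['n_paralog_nodes']} paralog-added isolated nodes, "
          f"total evidence {s['total_evidence']}")
    if s["degrees"]:
        hub, deg = max(s["degrees"].items(), key=lambda kv: kv[1])
        print(f"highest-degree node: {hub} (degree {deg})")

    tfnet.write_sif(net, RESULTS / "tf_network.sif")
    tfnet.write_graphml(net, RESULTS / "tf_network.graphml")
    print(f"exports -> {RESULTS / 'tf_network.sif'} (+ .graphml)")


if __name__ == "__main__":
    main()
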