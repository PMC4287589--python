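"""Shared study conditions for the numbered analysis drivers.

One synthetic study stands in for the six-sample MSC design: 1,000 genes
(half expressed), two tissue groups x 3 replicates, 60 TFs of which 5 are
planted regulators, 100 planted DE genes at |log2FC| = 3.  Every driver
regenerates the same bundle deterministically from this config, so each
stage can be run (and re-run) in isolation.
"""

from pathlib import Path

from mscportrait.pipeline import RunConfig, simulate_inputs
from mscportrait.simdata import SimConfig

STUDY = SimConfig(
    n_genes=1000,
    n_tfs=60,
    n_regulator_tfs=5,
    n_de_genes=100,
    de_log2fc=3.0,
    motif_planting_rate=0.5,
    n_cpg_per_gene=10,
    ppi_edge_prob=0.08,
    seed=20140910,
)

RUN = RunConfig(rrs_runs=10, seed=STUDY.seed)

#: matrices actually screened by the motif drivers (the planted regulators
#: plus a background panel); scanning all 60 adds nothing but runtime
N_MATRICES_SCREENED = 30

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def load_study():
    RESULTS.mkdir(parents=True, exist_ok=True)
    return simulate_inputs(STUDY)
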