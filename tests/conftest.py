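import numpy as np
import pandas as pd
import pytest

from mscportrait import simdata
from mscportrait.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared by read-only tests."""
    cfg = simdata.SimConfig(n_genes=400, n_tfs=40, n_regulator_tfs=3,
                            n_de_genes=30, seed=7)
    fpkm, counts, truth, ann = simdata.gen_expression(cfg)
    return {"cfg": cfg, "fpkm": fpkm, "counts": counts, "truth": truth, "ann": ann}


@pytest.fixture
def tiny_matrix():
    data = pd.DataFrame(
        {
            "BM1": [1.0, 0.0, 8.0], "BM2": [1.0, 0.0, 8.0], "BM3": [1.0, 0.0, 8.0],
            "PL1": [1.0, 0.0, 2.0], "PL2": [1.0, 0.0, 2.0], "PL3": [1.0, 0.0, 2.0],
        },
        index=["flat", "silent", "shifted"],
    )
    groups = {s: s[:2] for s in data.columns}
    return ExpressionMatrix(data, groups)


@pytest.fixture(scope="session")
def motif_bundle():
    """Promoter contigs with planted regulator sites plus the matrix map."""
    cfg = simdata.SimConfig(n_genes=300, n_tfs=8, n_regulator_tfs=3,
                            motif_planting_rate=0.5, seed=21)
    fpkm, counts, truth, ann = simdata.gen_expression(cfg)
    pssms = simdata.gen_motifs(cfg)
    tf_ids = list(truth.regulator_tf_ids) + [
        t for t in truth.tf_ids if t not in truth.regulator_tf_ids
    ]
    tf_of_matrix = {}
    for p, tf in zip(pssms, tf_ids):
        p.tf = tf
        tf_of_matrix[p.matrix_id] = tf
    genome, truth = simdata.gen_promoters(cfg, pssms, truth, ann)
    return {"cfg": cfg, "fpkm": fpkm, "truth": truth, "ann": ann,
            "pssms": pssms, "tf_of_matrix": tf_of_matrix, "genome": genome}
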