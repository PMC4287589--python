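import itertools
import math

import numpy as np
import pytest

from mscportrait import motifreg
from mscportrait.motifreg import (
    SCORE_STEP,
    WINDOW_PRESETS,
    PromoterWindow,
    build_pssm,
    consensus,
    encode,
    extract_promoters,
    scan,
    score_pvalue_table,
    tfbs_enrichment,
)


def exact_match_pssm(word: str):
    counts = np.zeros((4, len(word)))
    for i, b in enumerate(word):
        counts["ACGT".index(b), i] = 100.0
    return build_pssm(counts, pseudocount_total=0.01)


class TestBuildPssm:
    def test_uniform_counts_give_zero_logodds(self):
        p = build_pssm(np.full((4, 3), 5.0))
        assert np.allclose(p.logodds, 0.0)

    def test_hand_arithmetic_single_column(self):
        p = build_pssm(np.array([[10.0], [0.0], [0.0], [0.0]]), pseudocount_total=1.0)
        assert p.freqs[0, 0] == pytest.approx(10.25 / 11)
        assert p.logodds[0, 0] == pytest.approx(math.log2((10.25 / 11) / 0.25))
        assert p.logodds[0, 0] == pytest.approx(1.898, abs=5e-4)

    def test_rejects_bad_background(self):
        with pytest.raises(ValueError):
            build_pssm(np.ones((4, 2)), background=[0.5, 0.5, 0.5, 0.5])

    def test_jaspar_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        pssms = [build_pssm(rng.integers(0, 50, (4, 6)).astype(float),
                            matrix_id=f"MA{i:04d}.1", tf=f"TF{i}") for i in range(3)]
        path = tmp_path / "m.jaspar"
        motifreg.write_jaspar(pssms, path)
        back = motifreg.read_jaspar(path)
        assert [p.matrix_id for p in back] == [p.matrix_id for p in pssms]
        for a, b in zip(pssms, back):
            assert np.allclose(a.counts, b.counts)


class TestScoreDistribution:
    def test_width_one_quarter_mass(self):
        # scores {1,0,0,0} on the grid: an exact-score matrix
        p = build_pssm(np.array([[100.0], [0.0], [0.0], [0.0]]), pseudocount_total=0.0001)
        d = score_pvalue_table(p)
        top = d.offset + len(d.pmf) - 1
        assert d.sf(top) == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [3, 5, 6])
    def test_matches_exhaustive_word_enumeration(self, width):
        rng = np.random.default_rng(width)
        p = build_pssm(rng.integers(0, 30, (4, width)).astype(float))
        d = score_pvalue_table(p)
        scores = p.int_scores
        exact = {}
        for word in itertools.product(range(4), repeat=width):
            s = int(scores[list(word), range(width)].sum())
            exact[s] = exact.get(s, 0) + 0.25**width
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        for s, mass in exact.items():
            sf_exact = sum(m for t, m in exact.items() if t >= s)
            assert d.sf(s) == pytest.approx(sf_exact, abs=1e-9)

    def test_alpha_one_threshold_is_min_score(self):
        rng = np.random.default_rng(1)
        p = build_pssm(rng.integers(0, 30, (4, 4)).astype(float))
        d = score_pvalue_table(p)
        assert d.threshold(1.0) == d.offset

    def test_threshold_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        p = build_pssm(rng.integers(0, 30, (4, 6)).astype(float))
        d = score_pvalue_table(p)
        thrs = [d.threshold(a) for a in (1.0, 0.5, 0.1, 1e-2, 1e-4)]
        assert all(a <= b for a, b in zip(thrs, thrs[1:]))


class TestScan:
    def test_palindrome_hits_both_strands(self):
        p = exact_match_pssm("ACGT")
        hits = scan(p, "AAACGTTT", alpha=0.01)
        fwd = hits[hits.strand == "+"]
        rev = hits[hits.strand == "-"]
        assert list(fwd.offset) == [3]
        assert list(rev.offset) == [3]  # ACGT is its own reverse complement

    def test_empty_sequence_no_hits(self):
        p = exact_match_pssm("ACGT")
        assert scan(p, "").empty

    def test_n_windows_are_skipped(self):
        p = exact_match_pssm("ACGT")
        assert scan(p, "AANGTT", alpha=1.0).query("strand == '+'").empty

    def test_matches_naive_all_window_scan(self):
        rng = np.random.default_rng(17)
        p = build_pssm(rng.integers(0, 40, (4, 7)).astype(float))
        d = score_pvalue_table(p)
        thr = d.threshold(0.01)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 200))
            hits = scan(p, seq, alpha=0.01, dist=d)
            got = {(int(r.offset), r.strand) for r in hits.itertuples()}
            expected = set()
            scores = p.int_scores
            for i in range(len(seq) - 7 + 1):
                win = seq[i : i + 7]
                s_fwd = sum(scores["ACGT".index(b), j] for j, b in enumerate(win))
                rc = "".join(comp[b] for b in reversed(win))
                s_rev = sum(scores["ACGT".index(b), j] for j, b in enumerate(rc))
                if s_fwd >= thr:
                    expected.add((i + 1, "+"))
                if s_rev >= thr:
                    expected.add((i + 1, "-"))
            assert got == expected

    def test_strand_symmetry(self):
        rng = np.random.default_rng(23)
        p = build_pssm(rng.integers(0, 40, (4, 6)).astype(float))
        seq = "".join(rng.choice(list("ACGT"), 300))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc_seq = "".join(comp[b] for b in reversed(seq))
        fwd = scan(p, seq, alpha=0.05)
        rev = scan(p, rc_seq, alpha=0.05)
        # hits on seq mirror hits on revcomp(seq) with strands swapped
        m = {(int(r.offset), r.strand) for r in fwd.itertuples()}
        L = len(seq)
        mirrored = {(L - (o + p.width - 1) + 1, {"+": "-", "-": "+"}[s])
                    for o, s in {(int(r.offset), r.strand) for r in rev.itertuples()}}
        assert m == mirrored


class TestExtractPromoters:
    def make_ann(self, strand, tss, contig="c1"):
        import pandas as pd

        return pd.DataFrame({"gene_id": ["g"], "chrom": [contig], "strand": [strand],
                             "tss": [tss]}).set_index("gene_id")

    def test_plus_strand_upstream_window(self):
        genome = {"c1": "".join(np.random.default_rng(0).choice(list("ACGT"), 12000))}
        ann = self.make_ann("+", 10001)
        seq = extract_promoters(ann, genome, PromoterWindow("w", -2000, -1))["g"]
        assert seq == genome["c1"][8000:10000].upper()

    def test_minus_strand_is_reverse_complemented(self):
        genome = {"c1": "".join(np.random.default_rng(1).choice(list("ACGT"), 8000))}
        ann = self.make_ann("-", 5000)
        seq = extract_promoters(ann, genome, PromoterWindow("w", -2000, -1))["g"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = "".join(comp[b] for b in reversed(genome["c1"][5000:7000]))
        assert seq == expected.upper()

    def test_tss_is_position_plus_one(self):
        genome = {"c1": "ACGTACGTAC"}
        ann = self.make_ann("+", 5)
        # window (+1,+2) must start at the TSS base itself
        assert extract_promoters(ann, genome, PromoterWindow("w", 1, 2))["g"] == "AC"

    def test_window_past_contig_is_truncated(self):
        genome = {"c1": "ACGTACGT"}
        ann = self.make_ann("+", 5)
        seq = extract_promoters(ann, genome, PromoterWindow("w", -100, -1))["g"]
        assert seq == "ACGT"

    def test_recovers_planted_site(self, motif_bundle):
        truth = motif_bundle["truth"]
        ann = motif_bundle["ann"]
        genome = motif_bundle["genome"]
        pssm_by_mat = {p.matrix_id: p for p in motif_bundle["pssms"]}
        win = PromoterWindow("w", -2000, -1)
        proms = extract_promoters(ann, genome, win)
        for row in truth.planted_sites.head(30).itertuples():
            p = pssm_by_mat[row.matrix_id]
            # planted offsets are upstream: position within the window
            pos0 = row.offset - win.start
            site = proms[row.gene][pos0 : pos0 + p.width]
            thr = score_pvalue_table(p).threshold(1e-4)
            enc = encode(site)
            fwd = int(p.int_scores[enc, range(p.width)].sum())
            rc = p.reverse_complement()
            rev = int(rc.int_scores[enc, range(p.width)].sum())
            assert max(fwd, rev) >= thr


class TestEnrichment:
    def test_all_targets_hit_none_background(self):
        targets = [f"t{i}" for i in range(5)]
        background = [f"b{i}" for i in range(15)]
        p = tfbs_enrichment(set(targets), targets, background)
        assert p == pytest.approx(1 / math.comb(20, 5))

    def test_no_hits_gives_p_one(self):
        assert tfbs_enrichment(set(), ["a"], ["b", "c"]) == pytest.approx(1.0)


class TestConsensus:
    def test_two_of_three_selected(self):
        df = consensus({"tf1": (True, True, False)})
        assert df.loc["tf1", "score"] == 2 and bool(df.loc["tf1", "selected"])

    def test_rrs_penalty(self):
        df = consensus({"a": (True, True, True), "b": (True, True, False)},
                       rrs_hits={"a": 1, "b": 2})
        assert df.loc["a", "score"] == 2 and bool(df.loc["a", "selected"])
        assert df.loc["b", "score"] == 1 and not bool(df.loc["b", "selected"])

    def test_all_false_rejected(self):
        df = consensus({"tf": (False, False, False)})
        assert df.loc["tf", "score"] == 0 and not bool(df.loc["tf", "selected"])

    def test_na_flags_excluded_from_count(self):
        df = consensus({"tf": (True, None, True)})
        assert df.loc["tf", "n_configs"] == 2
        assert df.loc["tf", "score"] == 2
        assert df.loc["tf", "config_2"] == "NA"


class TestMetaRegulators:
    def test_second_pass_idempotent_on_same_target(self, motif_bundle):
        b = motif_bundle
        tfs = sorted({b["tf_of_matrix"][p.matrix_id] for p in b["pssms"]})
        screen = motifreg.MotifScreen(b["pssms"], b["ann"], b["genome"])
        targets = sorted(b["truth"].expressed_gene_ids)
        background = sorted(set(b["ann"].index) - set(targets))
        v1 = motifreg.vote_pass(screen, targets, background, b["tf_of_matrix"], tfs,
                                rrs_runs=0)
        v2 = motifreg.vote_pass(screen, targets, background, b["tf_of_matrix"], tfs,
                                rrs_runs=0)
        assert (v1["selected"] == v2["selected"]).all()

    def test_empty_first_pass_gives_empty_meta(self, motif_bundle):
        b = motif_bundle
        screen = motifreg.MotifScreen(b["pssms"][:2], b["ann"], b["genome"])
        # a target set drawn at random has nothing enriched
        rng = np.random.default_rng(0)
        genes = list(b["ann"].index)
        targets = set(rng.choice(genes, 50, replace=False))
        res = motifreg.meta_regulators(
            screen, targets, set(list(targets)[:10]), set(genes),
            b["tf_of_matrix"], sorted({b["tf_of_matrix"][p.matrix_id] for p in b["pssms"][:2]}),
            rrs_runs=2, seed=0,
        )
        assert res["meta_regulators"] == sorted(set(res["selected"]) & set(res["meta_regulators"]))

    def test_regulators_planted_only_in_tf_promoters_survive_both_passes(self):
        from mscportrait import simdata

        # TF genes are a third of the footprint so sites planted only in
        # TF-gene promoters still enrich the full footprint in pass one
        cfg = simdata.SimConfig(n_genes=300, n_tfs=100, n_regulator_tfs=2,
                                motif_planting_rate=1.0, seed=31)
        _, _, truth, ann = simdata.gen_expression(cfg)
        pssms = simdata.gen_motifs(cfg)
        tf_ids = list(truth.regulator_tf_ids) + [
            t for t in truth.tf_ids if t not in truth.regulator_tf_ids
        ]
        tf_of_matrix = {}
        for p, tf in zip(pssms, tf_ids):
            p.tf = tf
            tf_of_matrix[p.matrix_id] = tf
        tf_genes = sorted(set(truth.tf_ids) & truth.expressed_gene_ids)
        genome, truth = simdata.gen_promoters(cfg, pssms, truth, ann,
                                              targets=tf_genes)
        screen = motifreg.MotifScreen(pssms[:8], ann, genome)
        tfs = sorted(tf_of_matrix[p.matrix_id] for p in pssms[:8])
        res = motifreg.meta_regulators(
            screen, truth.expressed_gene_ids, tf_genes, set(ann.index),
            tf_of_matrix, tfs, rrs_runs=5, seed=2,
        )
        assert set(res["meta_regulators"]) == set(truth.regulator_tf_ids)


def test_false_positive_control_no_planting():
    """With no planted motifs the consensus should select almost nothing."""
    from mscportrait import simdata

    selected = 0
    n_tfs = 6
    for seed in range(3):
        cfg = simdata.SimConfig(n_genes=200, n_tfs=n_tfs, n_regulator_tfs=0,
                                motif_planting_rate=0.0, seed=100 + seed)
        _, _, truth, ann = simdata.gen_expression(cfg)
        pssms = simdata.gen_motifs(cfg)
        tf_of_matrix = {p.matrix_id: p.tf for p in pssms}
        genome, truth = simdata.gen_promoters(cfg, pssms, truth, ann)
        screen = motifreg.MotifScreen(pssms, ann, genome)
        v = motifreg.vote_pass(screen, sorted(truth.expressed_gene_ids),
                               sorted(set(ann.index) - truth.expressed_gene_ids),
                               tf_of_matrix, sorted(tf_of_matrix.values()),
                               rrs_runs=3, rng=np.random.default_rng(seed))
        selected += int(v["selected"].sum())
    assert selected / 3 <= 0.05 * n_tfs + 1e-9
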