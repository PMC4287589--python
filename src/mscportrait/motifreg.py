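"""Meta-regulator engine: PSSM scanning of promoter windows, per-window
TFBS over-representation, consensus voting with a random-reference-set
penalty, and the two-pass meta-regulator selection.

A transcription factor is called a *meta-regulator* when its binding sites
are over-represented both in the promoters of all expressed genes (pass one)
and in the promoters of the expressed TF genes alone (pass two).  The
original multi-tool search is recast as a single scanning engine run under
three promoter-window configurations, preserving the "significant in at
least two of three" voting rule and the -1 penalty for any significance on
a randomly drawn reference gene set (RRS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
#: log-odds scores are discretised to this step for both the exact score
#: distribution and scanning, so thresholds and scores live on one grid
SCORE_STEP = 0.01


@dataclass(frozen=True)
class PromoterWindow:
    """Offsets relative to the TSS; negative = upstream, no offset 0."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @property
    def length(self) -> int:
        n = self.end - self.start + 1
        return n - 1 if self.start < 0 < self.end else n


#: the three window presets used as the engine's three configurations
WINDOW_PRESETS = (
    PromoterWindow("upstream2k", -2000, -1),
    PromoterWindow("distal", -5000, -800),
    PromoterWindow("extended", -5000, 200),
)


@dataclass
class Pssm:
    """Position-specific scoring matrix with background and log-odds."""

    matrix_id: str
    tf: str
    counts: np.ndarray  # shape (4, w), rows A,C,G,T
    background: np.ndarray
    pseudocount_total: float
    freqs: np.ndarray = field(init=False)
    logodds: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if counts.shape[0] != 4 or (counts < 0).any():
            raise ValueError("counts must be a non-negative 4 x w matrix")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise ValueError("background must be 4 positive values summing to 1")
        self.counts = counts
        self.background = bg
        col_tot = counts.sum(axis=0)
        self.freqs = (counts + self.pseudocount_total * bg[:, None]) / (
            col_tot + self.pseudocount_total
        )
        self.logodds = np.log2(self.freqs / bg[:, None])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def int_scores(self) -> np.ndarray:
        """Log-odds discretised to the common score grid (integer units)."""
        return np.rint(self.logodds / SCORE_STEP).astype(np.int64)

    def reverse_complement(self) -> "Pssm":
        return Pssm(
            matrix_id=self.matrix_id,
            tf=self.tf,
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount_total=self.pseudocount_total,
        )

    def information_content(self) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.freqs > 0, self.freqs * np.log2(self.freqs / self.background[:, None]), 0.0)
        return float(terms.sum())


def build_pssm(counts, background=None, pseudocount_total: float = 1.0,
               matrix_id: str = "", tf: str = "") -> Pssm:
    """Standard PSSM construction: background-weighted pseudocounts, then
    per-position log2 odds against the background composition."""
    if background is None:
        background = np.full(4, 0.25)
    return Pssm(matrix_id=matrix_id, tf=tf, counts=np.asarray(counts, float),
                background=np.asarray(background, float),
                pseudocount_total=pseudocount_total)


@dataclass
class ScoreDistribution:
    """Exact pmf of the discretised PSSM score under the background model."""

    offset: int  # integer score corresponding to pmf[0]
    pmf: np.ndarray

    def sf(self, int_score: int) -> float:
        """P(score >= int_score)."""
        i = int_score - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.pmf):
            return 0.0
        return float(self.pmf[i:].sum())

    def threshold(self, alpha: float) -> int:
        """Smallest integer score s with P(score >= s) <= alpha."""
        tail = np.cumsum(self.pmf[::-1])[::-1]
        idx = np.flatnonzero(tail <= alpha)
        if len(idx) == 0:
            return self.offset + len(self.pmf)  # above max: nothing passes
        return self.offset + int(idx[0])


def score_pvalue_table(pssm: Pssm) -> ScoreDistribution:
    """Exact score pmf by dynamic programming over motif positions.

    Scores are integers on the SCORE_STEP grid; the distribution of the sum
    is built by convolving the per-position 4-outcome distributions weighted
    by the background composition.
    """
    scores = pssm.int_scores
    bg = pssm.background
    lo = int(scores.min(axis=0).sum())
    hi = int(scores.max(axis=0).sum())
    pmf = np.zeros(hi - lo + 1)
    # running support starts at the sum of per-position minima
    cur = np.array([1.0])
    cur_off = 0
    mins = scores.min(axis=0)
    for i in range(pssm.width):
        width = scores[:, i].max() - mins[i]
        nxt = np.zeros(len(cur) + width)
        for b in range(4):
            d = scores[b, i] - mins[i]
            nxt[d : d + len(cur)] += bg[b] * cur
        cur = nxt
        cur_off += mins[i]
    pmf[: len(cur)] = cur
    total = pmf.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise AssertionError("score pmf does not sum to 1")
    return ScoreDistribution(offset=lo, pmf=pmf)


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other letter (incl. N) -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(enc: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows plus a validity mask (windows containing N skipped)."""
    w = int_scores.shape[1]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    sc = int_scores[safe, np.arange(w)].sum(axis=1)
    return sc, valid


def scan(pssm: Pssm, sequence: str, alpha: float = 1e-4,
         dist: ScoreDistribution | None = None) -> pd.DataFrame:
    """Scan both strands; a hit is any window scoring >= threshold(alpha).

    Offsets are 1-based within the scanned sequence and refer to the
    leftmost base of the occupied window on the forward coordinates;
    reverse-strand hits come from scoring the reverse-complement matrix.
    """
    if dist is None:
        dist = score_pvalue_table(pssm)
    thr = dist.threshold(alpha)
    enc = encode(sequence)
    rows = []
    for strand, mat in (("+", pssm), ("-", pssm.reverse_complement())):
        sc, valid = _window_scores(enc, mat.int_scores)
        for i in np.flatnonzero(valid & (sc >= thr)):
            rows.append(
                {"offset": int(i) + 1, "strand": strand,
                 "score": float(sc[i]) * SCORE_STEP, "pvalue": dist.sf(int(sc[i]))}
            )
    return pd.DataFrame(rows, columns=["offset", "strand", "score", "pvalue"])


def hit_genes(pssm: Pssm, seqs: dict[str, str], alpha: float = 1e-4,
              dist: ScoreDistribution | None = None) -> set[str]:
    """Genes whose sequence carries at least one hit (presence/absence)."""
    if dist is None:
        dist = score_pvalue_table(pssm)
    thr = dist.threshold(alpha)
    rc = pssm.reverse_complement()
    out = set()
    for gene, seq in seqs.items():
        enc = encode(seq)
        hit = False
        for mat in (pssm, rc):
            sc, valid = _window_scores(enc, mat.int_scores)
            if len(sc) and (valid & (sc >= thr)).any():
                hit = True
                break
        if hit:
            out.add(gene)
    return out


_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def _adj(o: int) -> int:
    """Map a no-zero offset onto contiguous integers (TSS = +1 -> 0)."""
    if o == 0:
        raise ValueError("offset 0 does not exist; the TSS is +1")
    return o if o < 0 else o - 1


def _extract_one(contig: str, tss: int, strand: str,
                 window: PromoterWindow) -> tuple[str, int]:
    """One promoter sequence plus the adjusted offset of its first base.

    Windows running past a contig end are truncated (the returned start
    offset reflects the truncation)."""
    a0, a1 = _adj(window.start), _adj(window.end)
    # genomic position for adjusted offset a: plus tss+a, minus tss-a
    if strand == "+":
        a0v = max(a0, 1 - tss)
        a1v = min(a1, len(contig) - tss)
    else:
        a0v = max(a0, tss - len(contig))
        a1v = min(a1, tss - 1)
    if a0v > a1v:
        return "", a0
    if strand == "+":
        seq = contig[tss + a0v - 1 : tss + a1v]
    else:
        lo, hi = tss - a1v, tss - a0v
        seq = contig[lo - 1 : hi].translate(_COMP)[::-1]
    return seq.upper(), a0v


def extract_promoters(annotation: pd.DataFrame, genome, window: PromoterWindow,
                      genes=None, with_offsets: bool = False):
    """Promoter sequence of each gene for one window preset.

    Offsets are 1-based around the TSS with no offset 0 (the TSS is +1):
    offset o maps to genomic TSS+o for o<0 and TSS+o-1 for o>0 on the plus
    strand, mirrored and reverse-complemented on the minus strand.  Windows
    running past a contig end are truncated.  ``genome`` is a mapping
    contig -> sequence (e.g. a pyfaidx.Fasta or a plain dict).  With
    ``with_offsets`` each value is ``(sequence, adjusted_start_offset)``.
    """
    out = {}
    rows = annotation if genes is None else annotation.loc[list(genes)]
    for gene, row in rows.iterrows():
        seq, start = _extract_one(str(genome[row["chrom"]]), int(row["tss"]),
                                  row["strand"], window)
        out[gene] = (seq, start) if with_offsets else seq
    return out


def tfbs_enrichment(hits: set[str], targets, background) -> float:
    """Upper-tail hypergeometric p for over-representation of hit genes in
    the target set against the target+background universe."""
    targets = set(targets)
    universe = targets | set(background)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    K = len(hits & universe)
    n = len(targets)
    k = len(hits & targets)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh(p: np.ndarray) -> np.ndarray:
    from .diffexpr import bh_adjust

    return bh_adjust(p)


def enrichment_table(hits_by_matrix: dict[str, set[str]], targets, background,
                     q_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-matrix enrichment p, BH q across matrices, significance call."""
    mats = sorted(hits_by_matrix)
    p = np.array([tfbs_enrichment(hits_by_matrix[m], targets, background) for m in mats])
    q = bh(p) if len(p) else np.array([])
    return pd.DataFrame(
        {"matrix_id": mats, "p": p, "q": q, "significant": q < q_cutoff}
    ).set_index("matrix_id")


@dataclass
class ConsensusVote:
    tf: str
    flags: tuple  # True/False/None per configuration (None = NA)
    rrs_hit: int
    score: int
    selected: bool


def consensus(flags_by_tf: dict[str, tuple], rrs_hits: dict[str, int] | None = None,
              min_score: int = 2) -> pd.DataFrame:
    """Contingency-table vote: score = #significant configurations minus 1
    if the TF was significant in any RRS run; selected iff score >= 2.

    NA flags (None) are excluded from the count."""
    rrs_hits = rrs_hits or {}
    rows = []
    for tf, flags in flags_by_tf.items():
        n_sig = sum(1 for f in flags if f is True)
        rrs = int(rrs_hits.get(tf, 0))
        score = n_sig - (1 if rrs > 0 else 0)
        rows.append(
            {"tf": tf, "n_configs": sum(f is not None for f in flags),
             "n_significant": n_sig, "rrs_hit": rrs, "score": score,
             "selected": score >= min_score,
             **{f"config_{i+1}": ("NA" if f is None else bool(f))
                for i, f in enumerate(flags)}}
        )
    return pd.DataFrame(rows).set_index("tf").sort_values(
        ["score", "n_significant"], ascending=False
    )


class MotifScreen:
    """Scans every matrix once over the widest window and answers per-window
    hit queries, so enrichment over many target sets (including RRS draws)
    is a cheap recount."""

    def __init__(self, pssms, annotation, genome, alpha: float = 1e-4,
                 windows=WINDOW_PRESETS, genes=None):
        self.pssms = {p.matrix_id: p for p in pssms}
        self.windows = tuple(windows)
        self.alpha = alpha
        lo = min(w.start for w in self.windows)
        hi = max(w.end for w in self.windows)
        full = PromoterWindow("full", lo, hi)
        self.full = full
        with_off = extract_promoters(annotation, genome, full, genes=genes,
                                     with_offsets=True)
        self.seqs = {g: s for g, (s, _) in with_off.items()}
        self._starts = {g: a for g, (_, a) in with_off.items()}
        self.annotation = annotation
        self._dists = {m: score_pvalue_table(p) for m, p in self.pssms.items()}
        self._hits = self._scan_all()

    def _scan_all(self) -> dict[str, pd.DataFrame]:
        """matrix_id -> DataFrame(gene, adj: adjusted start offset of hit)."""
        enc_by_gene = {g: encode(s) for g, s in self.seqs.items() if s}
        hits = {}
        for m, p in self.pssms.items():
            thr = self._dists[m].threshold(self.alpha)
            rc = p.reverse_complement()
            rows_g, rows_a = [], []
            for g, enc in enc_by_gene.items():
                start = self._starts[g]
                for mat in (p, rc):
                    sc, valid = _window_scores(enc, mat.int_scores)
                    for i in np.flatnonzero(valid & (sc >= thr)):
                        rows_g.append(g)
                        rows_a.append(start + int(i))
            hits[m] = pd.DataFrame({"gene": rows_g, "adj": rows_a})
            hits[m]["width"] = p.width
        return hits

    def hit_genes(self, matrix_id: str, window: PromoterWindow) -> set[str]:
        df = self._hits[matrix_id]
        if df.empty:
            return set()
        w = int(df["width"].iloc[0])
        lo, hi = _adj(window.start), _adj(window.end) - w + 1
        sel = df[(df["adj"] >= lo) & (df["adj"] <= hi)]
        return set(sel["gene"])

    def enrichment(self, targets, background, q_cutoff: float = 0.05) -> dict[str, pd.DataFrame]:
        """window name -> per-matrix enrichment table."""
        return {
            win.name: enrichment_table(
                {m: self.hit_genes(m, win) for m in self.pssms}, targets,
                background, q_cutoff,
            )
            for win in self.windows
        }


def _tf_flags(tables: dict[str, pd.DataFrame], tf_of_matrix: dict[str, str],
              tfs) -> dict[str, tuple]:
    """A TF is significant in a configuration if any of its matrices is."""
    flags = {}
    mats_of = {}
    for m, tf in tf_of_matrix.items():
        mats_of.setdefault(tf, []).append(m)
    for tf in tfs:
        mats = mats_of.get(tf, [])
        row = []
        for name in tables:
            t = tables[name]
            present = [m for m in mats if m in t.index]
            row.append(None if not present else bool(t.loc[present, "significant"].any()))
        flags[tf] = tuple(row)
    return flags


def vote_pass(screen: MotifScreen, targets, background, tf_of_matrix: dict[str, str],
              tfs, rrs_runs: int = 10, rng: np.random.Generator | None = None,
              q_cutoff: float = 0.05) -> pd.DataFrame:
    """One full voting pass: per-window enrichment, RRS penalty, consensus.

    RRS runs draw uniform gene sets of the target-set size from the
    target+background universe and are evaluated under the first window
    configuration, mirroring the single-tool negative control of the
    original procedure.
    """
    tables = screen.enrichment(targets, background, q_cutoff)
    flags = _tf_flags(tables, tf_of_matrix, tfs)

    rrs_hits: dict[str, int] = {tf: 0 for tf in tfs}
    if rrs_runs > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        universe = sorted(set(targets) | set(background))
        first = screen.windows[0]
        hits_first = {m: screen.hit_genes(m, first) for m in screen.pssms}
        size = len(set(targets))
        for _ in range(rrs_runs):
            rand_t = set(rng.choice(universe, size=size, replace=False))
            rand_b = set(universe) - rand_t
            tab = enrichment_table(hits_first, rand_t, rand_b, q_cutoff)
            sig_mats = set(tab.index[tab["significant"]])
            for m in sig_mats:
                tf = tf_of_matrix.get(m)
                if tf in rrs_hits:
                    rrs_hits[tf] += 1
    return consensus(flags, rrs_hits)


def meta_regulators(screen: MotifScreen, footprint_genes, tf_genes, universe_genes,
                    tf_of_matrix: dict[str, str], tfs, rrs_runs: int = 10,
                    seed: int = 0) -> dict:
    """Two-pass selection.

    Pass one votes on the promoters of all footprint genes against the rest
    of the universe; pass two repeats the vote with the footprint's TF genes
    as the target set.  Meta-regulators are the TFs selected in both passes.
    """
    rng = np.random.default_rng(seed)
    footprint_genes = set(footprint_genes)
    tf_genes = set(tf_genes)
    universe_genes = set(universe_genes)
    pass1 = vote_pass(screen, footprint_genes, universe_genes - footprint_genes,
                      tf_of_matrix, tfs, rrs_runs=rrs_runs, rng=rng)
    pass2 = vote_pass(screen, tf_genes, footprint_genes - tf_genes,
                      tf_of_matrix, tfs, rrs_runs=rrs_runs, rng=rng)
    sel1 = set(pass1.index[pass1["selected"]])
    sel2 = set(pass2.index[pass2["selected"]])
    return {"pass1": pass1, "pass2": pass2,
            "selected": sorted(sel1), "meta_regulators": sorted(sel1 & sel2)}


# ---------------------------------------------------------------------------
# JASPAR-format I/O (via Bio.motifs) and the matrix -> TF map

def read_jaspar(path) -> list[Pssm]:
    from Bio import motifs

    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
            out.append(build_pssm(counts, matrix_id=m.matrix_id or m.name, tf=m.name))
    return out


def write_jaspar(pssms, path) -> None:
    from Bio import motifs
    from Bio.motifs.jaspar import Motif

    records = []
    for p in pssms:
        counts = {b: list(p.counts[i]) for b, i in BASE_INDEX.items()}
        records.append(Motif(matrix_id=p.matrix_id, name=p.tf, counts=counts))
    with open(path, "w") as fh:
        fh.write(motifs.write(records, "jaspar"))


def read_tf_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
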