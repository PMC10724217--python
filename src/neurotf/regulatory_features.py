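"""From peaks, gene models and motifs to regulator x target accessibility evidence.

All genomic intervals are 0-based half-open (BED convention): a peak
``[100, 200)`` does not overlap a blacklist interval ``[200, 300)``.  The
cis-regulatory region (CRE) of a TF gene is its gene body (exons and
introns) plus a strand-aware 2 kb upstream window; regulator binding inside
accessible CRE peaks is detected by PWM log-odds scanning with an exact
p-value threshold computed by dynamic programming over the background score
distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
DEFAULT_MOTIF_P = 5e-5
DEFAULT_GRANULARITY = 1e-3
NO_HIT_POSSIBLE = math.inf  # sentinel threshold for degenerate PWMs


# ---------------------------------------------------------------------------
# Interval handling
# ---------------------------------------------------------------------------

def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples():
        if row.start >= row.end:
            raise ValueError(f"empty or inverted interval {row.start}-{row.end}")
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def remove_blacklisted(peaks: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    if blacklist.empty:
        return peaks.copy()
    trees = _trees(blacklist)
    if peaks.size and not (set(peaks["chrom"]) & set(trees)):
        warnings.warn("no shared chromosome names between peaks and blacklist; "
                      "check genome namespaces")
    keep = [
        not (row.chrom in trees and trees[row.chrom].overlap(row.start, row.end))
        for row in peaks.itertuples()
    ]
    return peaks.loc[keep].reset_index(drop=True)


def consensus_peaks(sample_peaks: Mapping[str, pd.DataFrame],
                    min_samples: int = 2) -> pd.DataFrame:
    """Merge overlapping peaks across samples; keep merged peaks seen in
    >= ``min_samples`` distinct samples.

    Overlap chains are merged transitively (A∩B and B∩C collapse into one
    consensus interval supported by all three samples).  If the per-sample
    peak tables carry a ``count`` column, per-sample counts are recomputed
    over the merged interval as the sum of that sample's member peaks and
    returned as ``count_<sample>`` columns.
    """
    if len(sample_peaks) < 2:
        raise ValueError("need at least two samples for consensus peaks")
    records = []
    for sample, df in sample_peaks.items():
        cnt = df["count"].to_numpy(dtype=float) if "count" in df.columns \
            else np.zeros(len(df))
        for (chrom, start, end), c in zip(
                df[["chrom", "start", "end"]].itertuples(index=False), cnt):
            records.append((chrom, int(start), int(end), sample, float(c)))
    if not records:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_samples"])
    all_df = pd.DataFrame(records, columns=["chrom", "start", "end", "sample", "count"])
    out = []
    names = list(sample_peaks)
    for chrom, grp in all_df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_start = cur_end = None
        members: list[tuple[str, float]] = []

        def flush():
            support = {s for s, _ in members}
            if len(support) >= min_samples:
                row = {"chrom": chrom, "start": cur_start, "end": cur_end,
                       "n_samples": len(support)}
                for s in names:
                    row[f"count_{s}"] = sum(c for smp, c in members if smp == s)
                out.append(row)

        for row in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
                members = [(row.sample, row.count)]
            elif row.start < cur_end:  # half-open: touching intervals do not merge
                cur_end = max(cur_end, row.end)
                members.append((row.sample, row.count))
            else:
                flush()
                cur_start, cur_end = row.start, row.end
                members = [(row.sample, row.count)]
        if cur_start is not None:
            flush()
    res = pd.DataFrame(out)
    if res.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_samples"])
    return res.reset_index(drop=True)


def cre_of(gene: pd.Series | Mapping, upstream: int = 2000) -> tuple[str, int, int]:
    """Cis-regulatory region: gene body plus strand-aware upstream window.

    For a + strand gene the window precedes ``start``; for a - strand gene it
    follows ``end``.  Coordinates are clipped at zero.
    """
    strand = gene.get("strand") if hasattr(gene, "get") else gene["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"gene model needs a strand, got {strand!r}")
    start, end = int(gene["start"]), int(gene["end"])
    if strand == "+":
        return gene["chrom"], max(0, start - upstream), end
    return gene["chrom"], start, end + upstream


def cre_table(gene_models: pd.DataFrame, upstream: int = 2000) -> pd.DataFrame:
    rows = []
    for _, gene in gene_models.iterrows():
        chrom, start, end = cre_of(gene, upstream=upstream)
        rows.append((gene["gene"], chrom, start, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def assign_peaks_to_cres(peaks: pd.DataFrame, gene_models: pd.DataFrame,
                         upstream: int = 2000,
                         containment: bool = False) -> pd.DataFrame:
    """Map peaks to the TF CREs they overlap (or lie fully within).

    Returns a (peak_id, gene) pair table.  By default any >= 1 bp overlap
    assigns the peak; ``containment=True`` requires the peak to lie entirely
    inside the CRE.
    """
    cres = cre_table(gene_models, upstream=upstream)
    trees: dict[str, IntervalTree] = {}
    for row in cres.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene)
    pairs = []
    for row in peaks.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            if containment and not (iv.begin <= row.start and row.end <= iv.end):
                continue
            pairs.append((row.peak_id, iv.data))
    return pd.DataFrame(pairs, columns=["peak_id", "gene"])


# ---------------------------------------------------------------------------
# PWM scoring with exact p-values
# ---------------------------------------------------------------------------

UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a background, scored as log2 odds."""

    name: str
    matrix: np.ndarray                      # 4 x L, rows A/C/G/T
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PWM must be 4 x L with L >= 1")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 strictly positive probabilities")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg / bg.sum())

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, floor: float = 1e-9) -> np.ndarray:
        return np.log2(np.maximum(self.matrix, floor) / self.background[:, None])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=0))


def _int_scores(pwm: PWM, granularity: float) -> np.ndarray:
    """Log-odds discretized to integer multiples of ``granularity``."""
    return np.round(pwm.log_odds() / granularity).astype(np.int64)


def score_distribution(pwm: PWM, granularity: float = DEFAULT_GRANULARITY
                       ) -> tuple[np.ndarray, int]:
    """Exact background distribution of the discretized log-odds score.

    Dynamic programming over positions: the score of a random background
    word is the sum of independent per-position contributions, so the
    distribution is the convolution of L four-point distributions on the
    integer grid.  Returns ``(probabilities, offset)`` where probability of
    integer score s is ``probabilities[s - offset]``.
    """
    ints = _int_scores(pwm, granularity)
    lo = int(ints.min(axis=0).sum())
    hi = int(ints.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # start: degenerate distribution at 0, tracked relative to running lo/hi
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.length):
        col = ints[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        nxt = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(col[b]) - new_lo
            nxt[off:off + len(cur)] += pwm.background[b] * cur
        cur, cur_lo = nxt, new_lo
    dist[cur_lo - lo: cur_lo - lo + len(cur)] = cur
    return dist, lo


def pwm_pvalue_threshold(pwm: PWM, p: float = DEFAULT_MOTIF_P,
                         granularity: float = DEFAULT_GRANULARITY) -> float:
    """Smallest discretized log-odds score whose background tail is <= ``p``.

    Returns the sentinel ``math.inf`` ("no hit possible") when even the
    maximal score is too probable -- e.g. a uniform PWM on a uniform
    background, where every word scores 0.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    dist, lo = score_distribution(pwm, granularity)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P(score >= lo + i)
    ok = np.nonzero(tail <= p)[0]
    if ok.size == 0:
        return NO_HIT_POSSIBLE
    return float((lo + ok[0]) * granularity)


def score_pvalue(pwm: PWM, score: float,
                 granularity: float = DEFAULT_GRANULARITY) -> float:
    """Exact background P(score' >= score) on the discretized grid."""
    dist, lo = score_distribution(pwm, granularity)
    tail = np.cumsum(dist[::-1])[::-1]
    k = int(round(score / granularity)) - lo
    if k <= 0:
        return 1.0
    if k >= len(tail):
        return 0.0
    return float(tail[k])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_CODE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _scan_one_strand(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Integer scores at every offset; N bases contribute 0 (background)."""
    L = ints.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    lookup = np.vstack([ints, np.zeros((1, L), dtype=np.int64)])  # row 4 = N
    scores = np.zeros(n, dtype=np.int64)
    for j in range(L):
        scores += lookup[codes[j:j + n], j]
    return scores


def scan_motifs(
    pwms: Sequence[PWM] | Mapping[str, PWM],
    sequences: Mapping[str, str],
    p: float = DEFAULT_MOTIF_P,
    granularity: float = DEFAULT_GRANULARITY,
) -> pd.DataFrame:
    """All motif hits at exact p <= threshold on both strands of each sequence.

    Reverse-strand hits are found by scanning the reverse complement; their
    reported offset is the hit's left edge on the forward strand.  Returns a
    table (peak_id, tf, offset, strand, score, p_value).
    """
    if isinstance(pwms, Mapping):
        pwms = list(pwms.values())
    hits = []
    for pwm in pwms:
        thr = pwm_pvalue_threshold(pwm, p=p, granularity=granularity)
        if thr is NO_HIT_POSSIBLE or math.isinf(thr):
            continue
        thr_int = int(round(thr / granularity))
        ints = _int_scores(pwm, granularity)
        dist, lo = score_distribution(pwm, granularity)
        tail = np.cumsum(dist[::-1])[::-1]
        L = pwm.length
        for peak_id, seq in sequences.items():
            codes = _CODE[_encode(seq)]
            fwd = _scan_one_strand(codes, ints)
            rc_codes = _CODE[_encode(reverse_complement(seq))]
            rev = _scan_one_strand(rc_codes, ints)
            for strand, scores in (("+", fwd), ("-", rev)):
                for off in np.nonzero(scores >= thr_int)[0]:
                    s_int = int(scores[off])
                    offset = int(off) if strand == "+" else len(seq) - L - int(off)
                    pv = float(tail[min(max(s_int - lo, 0), len(tail) - 1)])
                    hits.append((peak_id, pwm.name, offset, strand,
                                 s_int * granularity, pv))
    return pd.DataFrame(
        hits, columns=["peak_id", "tf", "offset", "strand", "score", "p_value"])


# ---------------------------------------------------------------------------
# Pair features and ChIP proximity
# ---------------------------------------------------------------------------

def summed_peak_reads(peak_counts: pd.DataFrame,
                      samples: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate columns per timepoint: peaks x timepoints read totals."""
    out = {}
    for tp, grp in samples.groupby("timepoint", sort=False):
        cols = [s for s in grp["sample"] if s in peak_counts.columns]
        if not cols:
            raise ValueError(f"no count columns for timepoint {tp!r}")
        out[tp] = peak_counts[cols].sum(axis=1)
    return pd.DataFrame(out)


def build_pair_features(
    hits: pd.DataFrame,
    peak_genes: pd.DataFrame,
    peak_reads_by_tp: pd.DataFrame,
    regulators: Sequence[str],
    targets: Sequence[str],
) -> pd.DataFrame:
    """Regulator x target accessibility evidence over the full cross product.

    A peak supports the pair (R, T) when it is assigned to T's CRE and
    carries >= 1 hit of R's motif; ``reads_<tp>`` columns sum the supporting
    peaks' reads (all replicates) at each timepoint.  Every pair appears in
    the output even without support (``has_motif`` False, zero reads).
    """
    unknown = set(hits["peak_id"]) - set(peak_reads_by_tp.index)
    if unknown:
        raise ValueError(f"hits reference unknown peaks: {sorted(unknown)[:5]}")
    tps = list(peak_reads_by_tp.columns)
    reg_hits = hits.loc[hits["tf"].isin(regulators), ["peak_id", "tf"]].drop_duplicates()
    support = reg_hits.merge(peak_genes, on="peak_id")
    support = support[support["gene"].isin(targets)]
    support = support.rename(columns={"tf": "regulator", "gene": "target"})

    joined = support.merge(peak_reads_by_tp, left_on="peak_id", right_index=True)
    sums = joined.groupby(["regulator", "target"])[tps].sum()
    peak_lists = support.groupby(["regulator", "target"])["peak_id"] \
        .apply(lambda s: ";".join(sorted(set(s))))

    index = pd.MultiIndex.from_product([regulators, targets],
                                       names=["regulator", "target"])
    out = pd.DataFrame(index=index)
    out["has_motif"] = False
    out["supporting_peaks"] = ""
    for tp in tps:
        out[f"reads_{tp}"] = 0
    if len(sums):
        out.loc[sums.index, [f"reads_{tp}" for tp in tps]] = sums[tps].to_numpy()
        out.loc[peak_lists.index, "supporting_peaks"] = peak_lists
        out.loc[sums.index, "has_motif"] = True
    return out.reset_index()


def chip_proximity_enrichment(
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    chip_peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    window: int = 2000,
) -> dict[str, float]:
    """Fold enrichment of ChIP-peak presence in up- vs down-regulated genes.

    A gene "has binding" when its CRE (gene body + ``window`` upstream)
    overlaps >= 1 ChIP peak.  Returns the two fractions, their ratio and a
    two-sided Fisher exact p on the 2x2 table.  When both fractions are zero
    the fold is NaN (sentinel for "undefined").
    """
    up, down = set(up_genes), set(down_genes)
    if not up or not down:
        raise ValueError("both gene sets must be non-empty")
    if up & down:
        raise ValueError("gene sets must be disjoint")
    trees = _trees(chip_peaks) if len(chip_peaks) else {}
    cres = cre_table(gene_models, upstream=window).set_index("gene")

    def has_peak(gene: str) -> bool:
        if gene not in cres.index:
            return False
        row = cres.loc[gene]
        tree = trees.get(row["chrom"])
        return bool(tree and tree.overlap(row["start"], row["end"]))

    k_up = sum(has_peak(g) for g in up)
    k_down = sum(has_peak(g) for g in down)
    frac_up = k_up / len(up)
    frac_down = k_down / len(down)
    from scipy.stats import fisher_exact

    table = [[k_up, len(up) - k_up], [k_down, len(down) - k_down]]
    _, pval = fisher_exact(table, alternative="two-sided")
    if frac_down > 0:
        fold = frac_up / frac_down
    else:
        fold = math.nan if frac_up == 0 else math.inf
    return {"fraction_up": frac_up, "fraction_down": frac_down,
            "fold": fold, "fisher_p": float(pval),
            "n_up": len(up), "n_down": len(down)}


# ---------------------------------------------------------------------------
# Plain-text readers
# ---------------------------------------------------------------------------

def read_bed(path, names=("chrom", "start", "end", "name", "score", "strand")
             ) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def read_gene_models_bed(path) -> pd.DataFrame:
    df = read_bed(path)
    return df.rename(columns={"name": "gene"})[
        ["gene", "chrom", "start", "end", "strand"]]


def read_narrowpeak(path) -> pd.DataFrame:
    cols = ("chrom", "start", "end", "peak_id", "score", "strand",
            "signalValue", "pValue", "qValue", "peak")
    return read_bed(path, names=cols)


def read_jaspar_pfms(path, background: np.ndarray | None = None) -> dict[str, PWM]:
    """Load JASPAR-format position-frequency matrices as probability PWMs."""
    from Bio import motifs as bio_motifs

    out = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            probs = counts / counts.sum(axis=0, keepdims=True)
            name = m.name or m.matrix_id
            out[name] = PWM(name=name, matrix=probs,
                            background=UNIFORM_BG if background is None else background)
    return out
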