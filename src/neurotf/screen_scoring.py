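"""Scoring of pooled TF-knockout screens sorted by a differentiation reporter.

The screen compares guide RNA representation in a reporter-negative sorted
population (cells that failed to differentiate) against the unsorted input
and the reporter-positive population.  Gene calls use an empirical null built
from non-targeting control (NTC) guides: a guide is "enriched" when its log2
enrichment strictly exceeds the NTC 90th percentile (empirical FDR < 0.1),
and a TF is called when >= 2 of its guides are enriched in *both*
comparisons.  A RIGER-style weighted top-two rank statistic with gene-label
permutation provides an orthogonal gene ranking.
"""

from __future__ import annotations

import gzip
import math
import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ADAPTER = "TCTTGTGGAAAGGACGAAACACCG"  # hU6 promoter 3' end, used as 5' adapter
GUIDE_LEN = 20


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _trim_adapter(read: str, adapter: str, error_rate: float,
                  min_overlap: int) -> str | None:
    """Remove a 5' adapter, returning the downstream sequence (None if absent).

    Mirrors cutadapt ``-g`` semantics: the adapter may occur anywhere in the
    read (full occurrences, up to ``floor(error_rate * len)`` mismatches) or
    as a suffix overlapping the read start with >= ``min_overlap`` bases.
    The best occurrence (most adapter bases matched, then fewest errors,
    then leftmost) wins.
    """
    best: tuple[int, int, int] | None = None  # (-matched, errors, end position)
    alen = len(adapter)
    max_err_full = math.floor(error_rate * alen)
    for start in range(0, len(read) - min_overlap + 1):
        frag = read[start:start + alen]
        if len(frag) == alen:
            err = _hamming(frag, adapter)
            if err <= max_err_full:
                cand = (-alen, err, start + alen)
                if best is None or cand < best:
                    best = cand
    for olap in range(min_overlap, alen):  # adapter suffix at the read start
        frag = read[:olap]
        if len(frag) < olap:
            break
        err = _hamming(frag, adapter[alen - olap:])
        if err <= math.floor(error_rate * olap):
            cand = (-olap, err, olap)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return read[best[2]:]


def _one_mismatch_index(manifest: pd.DataFrame) -> tuple[dict, dict]:
    """Exact and 1-mismatch lookup tables (ambiguous variants map to None)."""
    exact: dict[str, str] = {}
    near: dict[str, str | None] = {}
    for gid, seq in zip(manifest["guide_id"], manifest["sequence"]):
        if seq in exact:
            raise ValueError(f"duplicate guide sequence in manifest: {seq}")
        exact[seq] = gid
    for gid, seq in zip(manifest["guide_id"], manifest["sequence"]):
        for i in range(len(seq)):
            for b in "ACGT":
                if b == seq[i]:
                    continue
                var = seq[:i] + b + seq[i + 1:]
                if var in near and near[var] != gid:
                    near[var] = None  # ambiguous between two guides
                else:
                    near[var] = gid
    return exact, near


def _iter_fastq(source) -> Iterable[str]:
    from Bio import SeqIO

    if hasattr(source, "read") or not isinstance(source, (str, bytes)):
        handle = source
        yield from (str(rec.seq) for rec in SeqIO.parse(handle, "fastq"))
        return
    opener = gzip.open if str(source).endswith(".gz") else open
    with opener(source, "rt") as fh:
        yield from (str(rec.seq) for rec in SeqIO.parse(fh, "fastq"))


def count_guides_from_reads(
    reads,
    manifest: pd.DataFrame,
    adapter: str = ADAPTER,
    error_rate: float = 0.2,
    min_overlap: int = 5,
    min_length: int = GUIDE_LEN,
) -> tuple[pd.Series, dict[str, int]]:
    """Quantify one population from raw reads (FASTQ path/handle or sequences).

    Each read is 5'-adapter trimmed, then its first 20 nt are matched to the
    manifest on the sense strand allowing at most one mismatch; reads hitting
    two guides at one mismatch are discarded as ambiguous.  Returns the guide
    count column and a tally of unmatched / discarded reads.
    """
    if isinstance(reads, (list, tuple)) and (not reads or isinstance(reads[0], str)):
        seqs: Iterable[str] = reads
    else:
        seqs = _iter_fastq(reads)
    exact, near = _one_mismatch_index(manifest)
    counts = pd.Series(0, index=manifest["guide_id"].to_numpy(), dtype=np.int64)
    stats = {"matched": 0, "no_adapter": 0, "too_short": 0,
             "unmatched": 0, "ambiguous": 0, "total": 0}
    for read in seqs:
        stats["total"] += 1
        read = read.upper()
        trimmed = _trim_adapter(read, adapter, error_rate, min_overlap)
        if trimmed is None:
            stats["no_adapter"] += 1
            continue
        if len(trimmed) < min_length:
            stats["too_short"] += 1
            continue
        probe = trimmed[:GUIDE_LEN]
        gid = exact.get(probe)
        if gid is None:
            gid = near.get(probe)
            if probe in near and gid is None:
                stats["ambiguous"] += 1
                continue
        if gid is None:
            stats["unmatched"] += 1
            continue
        counts[gid] += 1
        stats["matched"] += 1
    if stats["total"] == 0:
        warnings.warn("empty read stream: returning all-zero counts")
    return counts, stats


# ---------------------------------------------------------------------------
# Enrichment and empirical-null gene calling
# ---------------------------------------------------------------------------

def guide_enrichment(counts: pd.DataFrame, numerator: str, denominator: str,
                     pseudocount: float = 1.0) -> pd.Series:
    """Per-guide log2 ratio of pseudocounted reads-per-million.

    log2((RPM_num + c) / (RPM_den + c)); the pseudocount keeps sparse sorted
    populations finite and maps 0-vs-0 to exactly 0.
    """
    for pop in (numerator, denominator):
        if pop not in counts.columns:
            raise KeyError(f"population {pop!r} not in count table")
        if counts[pop].sum() <= 0:
            raise ValueError(f"population {pop!r} has zero total counts")
    rpm_n = counts[numerator] * 1e6 / counts[numerator].sum()
    rpm_d = counts[denominator] * 1e6 / counts[denominator].sum()
    enr = np.log2((rpm_n + pseudocount) / (rpm_d + pseudocount))
    enr.name = f"{numerator}_vs_{denominator}"
    return enr


def nearest_rank(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the k-th smallest value with k = ceil(q * n)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty value set")
    k = max(1, math.ceil(q * v.size))
    return float(v[k - 1])


def empirical_threshold(enrichment: pd.Series, manifest: pd.DataFrame,
                        q: float = 0.90) -> float:
    """Enrichment cutoff at the NTC ``q`` nearest-rank percentile.

    With distinct values exactly a fraction ``1 - q`` of NTC guides lie
    strictly above the threshold, which is what makes the downstream gene
    calls an empirical FDR < ``1 - q`` construction.
    """
    is_ntc = manifest.set_index("guide_id")["is_ntc"]
    ntc_vals = enrichment[is_ntc.reindex(enrichment.index).fillna(False).astype(bool)]
    if len(ntc_vals) < 10:
        raise ValueError("need at least 10 non-targeting guides for an empirical null")
    return nearest_rank(ntc_vals.to_numpy(), q)


def enriched_guides(enrichment: pd.Series, threshold: float) -> pd.Series:
    """Boolean mask of guides strictly above the empirical threshold."""
    return enrichment > threshold


def call_netfs(
    enrichment_a: pd.Series,
    enrichment_b: pd.Series,
    manifest: pd.DataFrame,
    q: float = 0.90,
    min_guides: int = 2,
) -> pd.DataFrame:
    """Call essential TFs from two sorted-population comparisons.

    Per comparison, guides strictly above that comparison's own NTC
    percentile threshold are counted per gene; a gene is called when the
    count reaches ``min_guides``, and ``is_netf`` marks genes called in both
    comparisons (the intersection rule).
    """
    gene_of = manifest.set_index("guide_id")["gene"]
    out = None
    thresholds = {}
    for label, enr in (("a", enrichment_a), ("b", enrichment_b)):
        missing = enr.index.difference(gene_of.index)
        if len(missing):
            raise ValueError(f"guides absent from manifest: {list(missing[:5])}")
        thr = empirical_threshold(enr, manifest, q=q)
        thresholds[f"threshold_{label}"] = thr
        mask = enriched_guides(enr, thr)
        genes = gene_of.reindex(enr.index)
        n_enr = mask.groupby(genes).sum().astype(int)
        col = n_enr.rename(f"n_enriched_{label}").to_frame()
        col[f"called_{label}"] = n_enr >= min_guides
        out = col if out is None else out.join(col, how="outer")
    out = out.fillna({"n_enriched_a": 0, "n_enriched_b": 0,
                      "called_a": False, "called_b": False})
    out["is_netf"] = out["called_a"] & out["called_b"]
    out.index.name = "gene"
    out.attrs.update(thresholds)
    return out


# ---------------------------------------------------------------------------
# RIGER weighted top-two rank statistic
# ---------------------------------------------------------------------------

def _normalized_ranks(enrichment: pd.Series) -> np.ndarray:
    """Rank 1 = most enriched, normalized to (0, 1]; ties get average ranks."""
    from scipy.stats import rankdata

    ranks = rankdata(-enrichment.to_numpy(), method="average")
    return ranks / len(ranks)


def _top2_score(norm_ranks: np.ndarray, weights: tuple[float, float]) -> float:
    two = np.partition(norm_ranks, 1)[:2]
    return float(weights[0] * two[0] + weights[1] * two[1])


def riger(
    enrichment: pd.Series,
    manifest: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
    exact: bool = False,
) -> pd.DataFrame:
    """Gene scores from the weighted sum of each gene's top two guide ranks.

    Guides are ranked by enrichment (rank 1 = most enriched) and ranks are
    normalized by the library size; the gene score is ``w1 * r(1) + w2 *
    r(2)`` over its two best guides, so it is invariant to everything below
    the top two.  Significance comes from permuting gene labels over guides:
    each permutation hands a gene a uniform random size-matched set of guide
    ranks, drawn independently per gene so that permutation p-values are
    independent across genes under the null.  ``perm_p = (#null <= observed
    + 1) / (n_perm + 1)``.  With ``exact=True`` the null is enumerated over
    all size-matched guide subsets instead (small libraries only) and the
    p-value is the exact fraction ``#(score <= observed) / #subsets``.
    """
    gene_of = manifest.set_index("guide_id")["gene"].reindex(enrichment.index)
    norm = _normalized_ranks(enrichment)
    pool = norm  # the permutation pool spans every scored guide, NTCs included

    grouped: dict[str, list[float]] = {}
    for pos, gene in enumerate(gene_of):
        if pd.isna(gene):
            continue
        grouped.setdefault(gene, []).append(norm[pos])
    n_small = sum(1 for v in grouped.values() if len(v) < 2)
    if n_small:
        warnings.warn(f"excluding {n_small} gene(s) with < 2 guides")
    observed = {g: _top2_score(np.asarray(v), weights)
                for g, v in grouped.items() if len(v) >= 2}
    sizes = {g: len(v) for g, v in grouped.items() if len(v) >= 2}

    records = []
    if exact:
        for gene, obs in observed.items():
            g = sizes[gene]
            total = math.comb(len(pool), g)
            if total > 5_000_000:
                raise ValueError("exact enumeration is only feasible for tiny libraries")
            count = sum(
                _top2_score(np.asarray(sub), weights) <= obs + 1e-12
                for sub in combinations(pool, g)
            )
            records.append((gene, obs, count / total, total))
    else:
        rng = np.random.default_rng(seed)
        by_size: dict[int, list[str]] = {}
        for gene, g in sizes.items():
            by_size.setdefault(g, []).append(gene)
        for g, members in sorted(by_size.items()):
            chunk = max(1, int(2e7 / (n_perm * g)))
            for lo in range(0, len(members), chunk):
                block = members[lo:lo + chunk]
                null = _null_scores(pool, g, len(block) * n_perm, weights, rng)
                null = null.reshape(len(block), n_perm)
                for i, gene in enumerate(block):
                    r = int((null[i] <= observed[gene] + 1e-12).sum())
                    records.append((gene, observed[gene], (r + 1) / (n_perm + 1), n_perm))

    out = pd.DataFrame(records, columns=["gene", "score", "perm_p", "n_perm"])
    return out.sort_values("score").reset_index(drop=True)


def _null_scores(pool: np.ndarray, g: int, n_draws: int,
                 weights: tuple[float, float],
                 rng: np.random.Generator) -> np.ndarray:
    """Null top-two scores for genes with ``g`` guides.

    Each draw samples ``g`` normalized ranks without replacement from the
    pooled library -- exactly the marginal a gene sees under a uniform
    permutation of gene labels over guides.  Draws are independent across
    genes so that null p-values are independent, not merely exchangeable.
    """
    n = len(pool)
    idx = rng.integers(0, n, size=(n_draws, g))
    for _ in range(100):  # vectorized rejection of rows with duplicates
        srt = np.sort(idx, axis=1)
        dup = (np.diff(srt, axis=1) == 0).any(axis=1)
        n_bad = int(np.count_nonzero(dup))
        if n_bad == 0:
            break
        idx[dup] = rng.integers(0, n, size=(n_bad, g))
    vals = pool[idx]
    two = np.partition(vals, 1, axis=1)[:, :2]
    return weights[0] * two[:, 0] + weights[1] * two[:, 1]


# ---------------------------------------------------------------------------
# Library QC and dropout
# ---------------------------------------------------------------------------

def library_qc(counts: pd.DataFrame, population: str,
               pseudocount: float = 1.0) -> dict[str, float]:
    """Representation QC: 90th/10th percentile ratio, zero fraction, coverage."""
    if population not in counts.columns:
        raise KeyError(f"population {population!r} not in count table")
    col = counts[population].to_numpy(dtype=float)
    if col.sum() <= 0:
        raise ValueError(f"population {population!r} has zero total counts")
    p90 = nearest_rank(col, 0.90) + pseudocount
    p10 = nearest_rank(col, 0.10) + pseudocount
    return {
        "percentile_ratio_90_10": p90 / p10,
        "zero_fraction": float((col == 0).mean()),
        "reads_per_guide": float(col.mean()),
        "total_reads": float(col.sum()),
    }


def depletion_ranking(counts: pd.DataFrame, manifest: pd.DataFrame,
                      early_pop: str, late_pop: str,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene median guide log2 depletion (late vs early), most depleted first.

    The non-targeting guide median is attached as ``attrs['ntc_median']`` as
    a calibration reference (it should sit near zero when controls are
    stable across culture).
    """
    enr = guide_enrichment(counts, late_pop, early_pop, pseudocount=pseudocount)
    gene_of = manifest.set_index("guide_id")["gene"].reindex(enr.index)
    med = enr.groupby(gene_of).median().rename("median_log2_change")
    out = med.sort_values().to_frame()
    out.index.name = "gene"
    ntc_mask = manifest.set_index("guide_id")["is_ntc"].reindex(enr.index).astype(bool)
    out.attrs["ntc_median"] = float(enr[ntc_mask].median()) if ntc_mask.any() else float("nan")
    return out
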