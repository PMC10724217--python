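"""Differential expression across timepoints/genotypes with the screen's filters.

The scientific content here is the filtering and integration layer: a gene
counts as changed only with |fold-change| >= 2, BH-adjusted p < 0.05 and a
mean expected count of at least 10, applied on top of a low-count filter of
50 total reads across replicates.  The test engine is a deliberately simple
negative-binomial Wald test (method-of-moments dispersion, t reference) --
externally produced DE tables with the same columns can be slotted in
wherever a DE table is consumed.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: ordered timepoint vocabulary used throughout the package
TIMEPOINT_ORDER = ("ESC", "1h", "4h", "12h", "D1", "D2", "D4", "D5", "D7")

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


def _group_counts(counts: pd.DataFrame, samples: Sequence[str]) -> np.ndarray:
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise KeyError(f"samples not in count matrix: {missing}")
    mat = counts[list(samples)].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    return mat


def _mom_dispersion(mat_a: np.ndarray, mat_b: np.ndarray,
                    floor: float = 0.01, ceiling: float = 10.0) -> np.ndarray:
    """Per-gene NB dispersion, pooled over groups by method of moments.

    For NB counts, var = mu + alpha * mu^2, so alpha = (s^2 - m) / m^2 within
    each group; the two group estimates are pooled by degrees of freedom and
    floored (small-sample estimates are noisy and can go negative).
    """
    def one(mat):
        m = mat.mean(axis=1)
        s2 = mat.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - m) / np.maximum(m, 1e-8) ** 2
        return np.nan_to_num(a, nan=0.0)

    df_a, df_b = mat_a.shape[1] - 1, mat_b.shape[1] - 1
    alpha = (one(mat_a) * df_a + one(mat_b) * df_b) / (df_a + df_b)
    return np.clip(alpha, floor, ceiling)


def differential_expression(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    min_total: float = 50.0,
    min_fold: float = 2.0,
    min_expected: float = 10.0,
) -> pd.DataFrame:
    """NB Wald differential expression of ``group_b`` versus ``group_a``.

    Genes with fewer than ``min_total`` summed reads across the ``group_a``
    (reference) replicates are dropped before testing.  The Wald statistic
    compares log group means with delta-method variance ``(1/n) (1/mu +
    dispersion)`` per group and a t reference with ``n_a + n_b - 2`` degrees
    of freedom; p-values are BH-adjusted across tested genes.  ``log2FC`` is
    the log2 ratio of pseudocounted (+1) group means, and ``status`` applies
    the fold / adjusted-p / count-floor call.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two replicates per group")
    mat_a = _group_counts(counts, group_a)
    mat_b = _group_counts(counts, group_b)

    keep = mat_a.sum(axis=1) >= min_total
    genes = counts.index[keep]
    mat_a, mat_b = mat_a[keep], mat_b[keep]

    m_a = mat_a.mean(axis=1)
    m_b = mat_b.mean(axis=1)
    disp = _mom_dispersion(mat_a, mat_b)
    n_a, n_b = mat_a.shape[1], mat_b.shape[1]

    delta = np.log(m_b + 1.0) - np.log(m_a + 1.0)
    se = np.sqrt((1.0 / (m_a + 0.5) + disp) / n_a + (1.0 / (m_b + 0.5) + disp) / n_b)
    tstat = delta / se
    df = n_a + n_b - 2
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    out = pd.DataFrame(
        {
            "mean_a": m_a,
            "mean_b": m_b,
            "log2FC": delta / np.log(2.0),
            "dispersion": disp,
            "stat": tstat,
            "p": p,
            "p_adj": p_adj,
        },
        index=genes,
    )
    out.index.name = "gene"
    out["status"] = de_call(out, min_fold=min_fold, alpha=alpha,
                            min_expected=min_expected)
    return out


def de_call(table: pd.DataFrame, min_fold: float = 2.0, alpha: float = 0.05,
            min_expected: float = 10.0) -> pd.Series:
    """Three-way call per gene: up / down / ns.

    ``up`` requires log2FC >= log2(min_fold) (inclusive), adjusted p strictly
    below ``alpha`` and the larger group mean at or above ``min_expected``;
    ``down`` is symmetric with log2FC <= -log2(min_fold).
    """
    lfc = table["log2FC"].to_numpy(dtype=float)
    p_adj = table["p_adj"].to_numpy(dtype=float)
    maxmean = np.maximum(table["mean_a"].to_numpy(dtype=float),
                         table["mean_b"].to_numpy(dtype=float))
    thr = np.log2(min_fold)
    ok = (p_adj < alpha) & (maxmean >= min_expected)
    status = np.where(ok & (lfc >= thr), STATUS_UP,
                      np.where(ok & (lfc <= -thr), STATUS_DOWN, STATUS_NS))
    return pd.Series(status, index=table.index, name="status")


def timepoint_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    baseline: str = "ESC",
    timepoints: Sequence[str] | None = None,
    **de_kwargs,
) -> dict[str, pd.DataFrame]:
    """One DE table per post-baseline timepoint, each contrasted against baseline."""
    if timepoints is None:
        timepoints = [t for t in samples["timepoint"].unique() if t != baseline]
    base_samples = samples.loc[samples["timepoint"] == baseline, "sample"].tolist()
    tables = {}
    for tp in timepoints:
        tp_samples = samples.loc[samples["timepoint"] == tp, "sample"].tolist()
        if not tp_samples:
            raise ValueError(f"no samples at timepoint {tp!r}")
        tables[tp] = differential_expression(counts, base_samples, tp_samples,
                                             **de_kwargs)
    return tables


def build_fc_timecourse(
    tables: Mapping[str, pd.DataFrame],
    universe: Sequence[str],
    baseline: str = "ESC",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assemble genes x timepoints log2FC matrix with a significance mask.

    Returns ``(fc, significant, summary)``; the baseline column is identically
    zero, genes missing from a table are masked (NaN fold change) with a
    warning, and ``summary`` counts up/down genes per timepoint.
    """
    if not tables:
        raise ValueError("no DE tables supplied")
    order = [baseline] + list(tables)
    fc = pd.DataFrame(np.nan, index=list(universe), columns=order)
    sig = pd.DataFrame(False, index=list(universe), columns=order)
    fc[baseline] = 0.0
    rows = []
    for tp, tab in tables.items():
        common = fc.index.intersection(tab.index)
        missing = len(fc.index) - len(common)
        if missing:
            warnings.warn(f"{missing} gene(s) absent from {tp} DE table; rows masked")
        fc.loc[common, tp] = tab.loc[common, "log2FC"]
        sig.loc[common, tp] = tab.loc[common, "status"] != STATUS_NS
        rows.append((tp, int((tab["status"] == STATUS_UP).sum()),
                     int((tab["status"] == STATUS_DOWN).sum())))
    summary = pd.DataFrame(rows, columns=["timepoint", "n_up", "n_down"])
    return fc, sig, summary


def genotype_contrast(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genotype: str,
    timepoint: str,
    reference_genotype: str = "parental",
    alpha: float = 0.01,
    **de_kwargs,
) -> pd.DataFrame:
    """Knockout-versus-parental DE at one timepoint (stricter default alpha)."""
    sel = samples["timepoint"] == timepoint
    ref = samples.loc[sel & (samples["genotype"] == reference_genotype), "sample"]
    ko = samples.loc[sel & (samples["genotype"] == genotype), "sample"]
    if ref.empty or ko.empty:
        raise ValueError(
            f"both genotypes must be sampled at {timepoint!r} "
            f"(found {len(ref)} reference, {len(ko)} {genotype!r})")
    return differential_expression(counts, ref.tolist(), ko.tolist(),
                                   alpha=alpha, **de_kwargs)
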