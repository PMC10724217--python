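"""Deterministic three-criterion TF-network inference over differentiation time.

An edge regulator -> target is drawn at a timepoint when, versus the ESC
baseline:

1. the target TF changes at least ``min_fold``-fold with adjusted p below
   ``alpha`` and an expected count of at least ``min_expected_count``;
2. the regulator was itself up-regulated (criterion 1, increase only) at a
   previous network timepoint -- or is one of the doxycycline-driven seed
   regulators, which stay eligible throughout;
3. the summed ATAC reads over peaks in the target's cis-regulatory region
   that carry the regulator's motif exceed ``min_pair_reads`` at the
   timepoint and exceed the same pair's summed reads at the ESC stage.

The edge is activating when the target goes up and repressing when it goes
down.  The procedure is deliberately rule-based, not probabilistic: the
interest is in which pairs satisfy explicit multi-omic evidence criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from neurotf.expression_stats import STATUS_DOWN, STATUS_UP, de_call

ACTIVATING = "activating"
REPRESSING = "repressing"


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds and schedule for the three edge criteria."""

    min_fold: float = 2.0
    alpha: float = 0.05
    min_expected_count: float = 10.0
    min_pair_reads: float = 50.0
    baseline: str = "ESC"
    timepoints: tuple[str, ...] = ("12h", "D1", "D4")
    seed_regulators: tuple[str, ...] = ("NEUROG1", "NEUROG2")
    #: 'cumulative' pools every previously up-regulated TF as a candidate
    #: regulator; 'previous-only' restricts to the immediately preceding
    #: network timepoint.
    regulator_window: str = "cumulative"

    def __post_init__(self) -> None:
        if min(self.min_fold, self.alpha, self.min_expected_count,
               self.min_pair_reads) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.baseline in self.timepoints:
            raise ValueError("the baseline cannot also be a network timepoint")
        if self.regulator_window not in ("cumulative", "previous-only"):
            raise ValueError("regulator_window must be 'cumulative' or 'previous-only'")

    def is_looser_or_equal(self, other: "CriteriaConfig") -> bool:
        """True when self is no stricter than ``other`` in every component."""
        return (self.min_fold <= other.min_fold
                and self.alpha >= other.alpha
                and self.min_expected_count <= other.min_expected_count
                and self.min_pair_reads <= other.min_pair_reads)


def _statuses(de_table: pd.DataFrame, config: CriteriaConfig) -> pd.Series:
    """Re-derive up/down/ns calls from the raw DE columns at config thresholds."""
    return de_call(de_table, min_fold=config.min_fold, alpha=config.alpha,
                   min_expected=config.min_expected_count)


def eligible_regulators(
    timepoint: str,
    de_tables: Mapping[str, pd.DataFrame],
    config: CriteriaConfig,
    motif_tfs: Sequence[str],
) -> set[str]:
    """Candidate regulators at ``timepoint`` (criterion 2).

    The first network timepoint admits exactly the seed regulators.  Later
    timepoints additionally admit any motif-bearing TF that was up-regulated
    at a previous network timepoint (all of them under the default
    cumulative window, only the immediately preceding one otherwise).  Seeds
    stay eligible throughout because their induction persists.
    """
    if timepoint not in config.timepoints:
        raise ValueError(f"{timepoint!r} is not a configured network timepoint")
    i = config.timepoints.index(timepoint)
    regs = set(config.seed_regulators)
    if i == 0:
        return regs
    previous = config.timepoints[:i] if config.regulator_window == "cumulative" \
        else config.timepoints[i - 1:i]
    motif_set = set(motif_tfs)
    for tp in previous:
        status = _statuses(de_tables[tp], config)
        up = set(status.index[status == STATUS_UP])
        regs |= (up & motif_set)
    return regs


def infer_edges(
    timepoint: str,
    regulators: set[str],
    de_table: pd.DataFrame,
    pair_features: pd.DataFrame,
    config: CriteriaConfig,
) -> pd.DataFrame:
    """Edges at one timepoint from the three criteria.

    ``pair_features`` must carry ``reads_<timepoint>`` and
    ``reads_<baseline>`` columns.  Pairs whose target is significant but
    that are absent from the feature table are treated as motif-free (no
    edge).
    """
    status = _statuses(de_table, config)
    sig = status[status.isin([STATUS_UP, STATUS_DOWN])]
    tp_col, base_col = f"reads_{timepoint}", f"reads_{config.baseline}"
    for col in (tp_col, base_col):
        if col not in pair_features.columns:
            raise KeyError(f"pair features lack column {col!r}")
    pf = pair_features
    mask = (
        pf["regulator"].isin(regulators)
        & pf["target"].isin(sig.index)
        & pf["has_motif"]
        & (pf[tp_col] > config.min_pair_reads)
        & (pf[tp_col] > pf[base_col])
    )
    hits = pf.loc[mask, ["regulator", "target"]].copy()
    hits["timepoint"] = timepoint
    hits["sign"] = sig.reindex(hits["target"]).map(
        {STATUS_UP: ACTIVATING, STATUS_DOWN: REPRESSING}).to_numpy()
    return hits.reset_index(drop=True)


@dataclass
class TFNetwork:
    """Per-timepoint signed edge sets plus convenience accessors."""

    edges: pd.DataFrame          # regulator, target, timepoint, sign
    config: CriteriaConfig

    def unique_edges(self) -> pd.DataFrame:
        """(regulator, target, sign) deduplicated across timepoints."""
        return self.edges.drop_duplicates(["regulator", "target", "sign"])

    def at(self, timepoint: str) -> pd.DataFrame:
        return self.edges[self.edges["timepoint"] == timepoint]

    def nodes(self) -> set[str]:
        return set(self.edges["regulator"]) | set(self.edges["target"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.unique_edges().itertuples():
            g.add_edge(row.regulator, row.target, sign=row.sign)
        return g

    def summary(self) -> pd.DataFrame:
        rows = []
        cum = []
        for tp in self.config.timepoints:
            sub = self.at(tp)
            cum.append(sub)
            cum_df = pd.concat(cum) if cum else sub
            uniq = cum_df.drop_duplicates(["regulator", "target", "sign"])
            rows.append({
                "timepoint": tp,
                "n_edges": len(sub),
                "n_activating": int((sub["sign"] == ACTIVATING).sum()),
                "n_repressing": int((sub["sign"] == REPRESSING).sum()),
                "n_regulators": sub["regulator"].nunique(),
                "n_targets": sub["target"].nunique(),
                "cum_unique_edges": len(uniq),
                "cum_regulators": uniq["regulator"].nunique(),
                "cum_targets": uniq["target"].nunique(),
                "cum_activating": int((uniq["sign"] == ACTIVATING).sum()),
                "cum_repressing": int((uniq["sign"] == REPRESSING).sum()),
            })
        return pd.DataFrame(rows)

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.unique_edges().itertuples():
                fh.write(f"{row.regulator}\t{row.sign}\t{row.target}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary().to_dict(orient="records"), fh, indent=2)


def assemble_network(
    de_tables: Mapping[str, pd.DataFrame],
    pair_features: pd.DataFrame,
    config: CriteriaConfig,
    motif_tfs: Sequence[str] | None = None,
) -> TFNetwork:
    """Run the three criteria at every configured timepoint."""
    missing = [tp for tp in config.timepoints if tp not in de_tables]
    if missing:
        raise ValueError(f"missing DE tables for timepoints: {missing}")
    if motif_tfs is None:
        motif_tfs = pair_features.loc[pair_features["has_motif"], "regulator"].unique()
    parts = []
    for tp in config.timepoints:
        regs = eligible_regulators(tp, de_tables, config, motif_tfs)
        parts.append(infer_edges(tp, regs, de_tables[tp], pair_features, config))
    edges = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["regulator", "target", "timepoint", "sign"])
    return TFNetwork(edges=edges, config=config)


def relaxed_network(
    de_tables: Mapping[str, pd.DataFrame],
    pair_features: pd.DataFrame,
    reference: CriteriaConfig,
    relaxed: CriteriaConfig,
    motif_tfs: Sequence[str] | None = None,
) -> TFNetwork:
    """Re-build the network under uniformly loosened thresholds.

    Every threshold of ``relaxed`` must be no stricter than in
    ``reference``; mixing looser and stricter components voids the
    superset guarantee and raises instead.
    """
    if not relaxed.is_looser_or_equal(reference):
        raise ValueError("relaxed config must be no stricter than the reference "
                         "in every threshold")
    return assemble_network(de_tables, pair_features, relaxed, motif_tfs=motif_tfs)


def outdegree_comparison(
    network: TFNetwork,
    early: Sequence[str],
    late: Sequence[str],
) -> dict[str, float]:
    """Welch t comparison of cumulative out-degrees of two TF sets.

    Out-degree counts unique targets over the full (deduplicated) network.
    TFs without outgoing edges count as degree zero.  With zero variance in
    both groups the t statistic is undefined and reported as NaN.
    """
    early, late = list(early), list(late)
    if not early or not late:
        raise ValueError("both TF sets must be non-empty")
    if set(early) & set(late):
        raise ValueError("TF sets must be disjoint")
    deg = network.unique_edges().groupby("regulator")["target"].nunique()
    d_early = np.array([deg.get(tf, 0) for tf in early], dtype=float)
    d_late = np.array([deg.get(tf, 0) for tf in late], dtype=float)
    mean_e, mean_l = d_early.mean(), d_late.mean()
    ratio = mean_e / mean_l if mean_l > 0 else np.inf
    if d_early.std() == 0 and d_late.std() == 0:
        t, p = (np.nan, 1.0) if mean_e == mean_l else (np.nan, np.nan)
    else:
        t, p = stats.ttest_ind(d_early, d_late, equal_var=False)
    return {"mean_early": float(mean_e), "mean_late": float(mean_l),
            "ratio": float(ratio), "t": float(t), "p": float(p)}
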