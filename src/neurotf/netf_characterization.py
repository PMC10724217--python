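"""Characterization of called essential TFs (neTFs).

Four analyses downstream of the screen calls and the inferred network:
temporal k-means clustering of expression profiles into archetypes A-D,
size-matched resampling enrichment with empirical p-values, accessibility of
each cluster's target sites over time, and the directional hierarchy between
clusters inside the TF network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

CLUSTER_LABELS = ("A", "B", "C", "D")


@dataclass
class ClusterAssignment:
    """TF -> temporal cluster label, with the centroids that named them."""

    labels: pd.Series                  # TF -> label
    centroids: pd.DataFrame            # label x timepoint mean log2FC profile
    k: int
    seed: int
    restarts: int
    inertia: float
    degenerate: bool = False

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _half_max_rise_time(profile: np.ndarray) -> float:
    """Fractional index where the profile first crosses half of its range."""
    lo, hi = profile.min(), profile.max()
    if hi - lo <= 0:
        return float(len(profile))
    half = lo + 0.5 * (hi - lo)
    above = np.nonzero(profile >= half)[0]
    if above.size == 0:
        return float(len(profile))
    t = int(above[0])
    if t == 0:
        return 0.0
    frac = (half - profile[t - 1]) / (profile[t] - profile[t - 1])
    return t - 1 + float(frac)


def _label_clusters(centroids: np.ndarray) -> dict[int, str]:
    """Map k=4 cluster indices to A-D by centroid shape.

    D = flattest (smallest range); C = rise-then-fall (peak strictly before
    the final timepoint and final value below half the peak); A = earliest
    half-maximum rise of the remaining pair; B = the other.  Ties resolve
    deterministically by rise time then amplitude.
    """
    k = centroids.shape[0]
    remaining = list(range(k))
    rng_of = centroids.max(axis=1) - centroids.min(axis=1)
    mapping: dict[int, str] = {}

    d = min(remaining, key=lambda i: (rng_of[i], i))
    mapping[d] = "D"
    remaining.remove(d)

    def is_peak_fall(i: int) -> bool:
        prof = centroids[i]
        peak = int(np.argmax(prof))
        return peak < len(prof) - 1 and prof[peak] > 0 and prof[-1] < prof[peak] / 2

    c_candidates = [i for i in remaining if is_peak_fall(i)]
    if c_candidates:
        c = max(c_candidates, key=lambda i: (centroids[i].max() - centroids[i][-1], -i))
    else:  # fall back to the strongest decline from peak to end
        c = max(remaining, key=lambda i: (centroids[i].max() - centroids[i][-1], -i))
    mapping[c] = "C"
    remaining.remove(c)

    rise = {i: _half_max_rise_time(centroids[i]) for i in remaining}
    a = min(remaining, key=lambda i: (rise[i], -rng_of[i], i))
    mapping[a] = "A"
    remaining.remove(a)
    mapping[remaining[0]] = "B"
    return mapping


def cluster_netfs(
    fc: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    restarts: int = 50,
    sd_floor: float = 0.25,
) -> ClusterAssignment:
    """k-means clustering of per-TF standardized log2 fold-change profiles.

    ``fc`` is TFs x ordered timepoints (baseline column included, all
    zeros).  Profiles are centered and scaled by ``max(sd, sd_floor)``: the
    floor (a quarter of one 2-fold change by default) keeps essentially flat
    profiles compact near the origin instead of blowing their measurement
    noise up to unit variance, which is what lets a "no-change" archetype
    form its own cluster.  The best of ``restarts`` seeded initializations
    by within-cluster sum of squares is kept, and for k = 4 cluster indices
    are renamed A-D from the shape of each cluster's mean raw profile, so
    labels carry meaning independent of k-means initialization order.
    """
    from sklearn.cluster import KMeans

    if fc.isna().any().any():
        raise ValueError("profiles must be complete (no missing timepoints)")
    n = fc.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available TFs")
    mat = fc.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    degenerate = np.unique(mat, axis=0).shape[0] < k
    if degenerate:
        warnings.warn("fewer distinct profiles than clusters; clustering is degenerate")
    z = (mat - mat.mean(axis=1, keepdims=True)) / np.maximum(sd, sd_floor)[:, None]

    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    idx = km.fit_predict(z)

    raw_centroids = np.vstack([
        mat[idx == i].mean(axis=0) if (idx == i).any() else mat.mean(axis=0)
        for i in range(k)
    ])
    if k == len(CLUSTER_LABELS):
        mapping = _label_clusters(raw_centroids)
    else:
        mapping = {i: f"C{i + 1}" for i in range(k)}
    labels = pd.Series([mapping[i] for i in idx], index=fc.index, name="cluster")
    centroids = pd.DataFrame(raw_centroids, columns=fc.columns,
                             index=[mapping[i] for i in range(k)]).sort_index()
    return ClusterAssignment(labels=labels, centroids=centroids, k=k, seed=seed,
                             restarts=restarts, inertia=float(km.inertia_),
                             degenerate=degenerate)


# ---------------------------------------------------------------------------
# Size-matched resampling enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentStat:
    observed: int
    null: np.ndarray
    fold: float
    p: float
    n_resample: int


def resample_enrichment(
    query: Sequence[str],
    category: Sequence[str],
    universe: Sequence[str],
    n: int = 10_000,
    seed: int | None = None,
) -> EnrichmentStat:
    """Empirical enrichment of ``query`` in ``category`` by size-matched resampling.

    ``n`` random sets of |query| TFs are drawn without replacement from the
    universe; the empirical p uses the +1/+1 correction, ``p = (#null >=
    observed + 1) / (n + 1)``, so it can never be zero.  Fold is observed
    over the null mean.
    """
    uni = pd.unique(pd.Series(list(universe)))
    cat = set(category)
    qry = set(query)
    if len(uni) == 0 or not cat:
        raise ValueError("universe and category must be non-empty")
    if not qry <= set(uni):
        raise ValueError("query must be a subset of the universe")
    if not cat <= set(uni):
        raise ValueError("category must be a subset of the universe")
    rng = np.random.default_rng(seed)
    member = np.isin(uni, list(cat))
    m = len(qry)
    observed = len(qry & cat)
    null = np.empty(n, dtype=np.int64)
    for i in range(n):
        pick = rng.choice(len(uni), size=m, replace=False)
        null[i] = int(member[pick].sum())
    r = int((null >= observed).sum())
    p = (r + 1) / (n + 1)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    return EnrichmentStat(observed=observed, null=null, fold=float(fold),
                          p=float(p), n_resample=n)


# ---------------------------------------------------------------------------
# Accessibility by cluster
# ---------------------------------------------------------------------------

def accessibility_by_cluster(
    pair_features: pd.DataFrame,
    assignment: ClusterAssignment,
    library_sizes: Mapping[str, float],
    timepoints: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Normalized target-site accessibility per cluster over time.

    Per regulator and timepoint, the supporting-peak read sums are converted
    to reads-per-million using the timepoint's ATAC library size and
    averaged over the regulator's supported targets; the cluster profile is
    the mean over member TFs.  Returns ``(cluster_profile, per_tf, ratio)``
    where ``ratio`` compares cluster A to the mean of B and C at the final
    timepoint.
    """
    if timepoints is None:
        timepoints = [c[len("reads_"):] for c in pair_features.columns
                      if c.startswith("reads_")]
    supported = pair_features[pair_features["has_motif"]]
    clustered = set(assignment.labels.index)
    present = clustered & set(supported["regulator"])
    dropped = clustered - present
    if not present:
        raise ValueError("no clustered TF appears as a supported regulator")
    if dropped:
        warnings.warn(f"{len(dropped)} clustered TF(s) have no supported targets; dropped")

    rows = {}
    for tf, grp in supported.groupby("regulator"):
        if tf not in present:
            continue
        vals = {}
        for tp in timepoints:
            size = library_sizes[tp]
            if size <= 0:
                raise ValueError(f"library size for {tp!r} must be positive")
            vals[tp] = float((grp[f"reads_{tp}"] / size * 1e6).mean())
        rows[tf] = vals
    per_tf = pd.DataFrame.from_dict(rows, orient="index")[list(timepoints)]
    per_tf["cluster"] = assignment.labels.reindex(per_tf.index)
    profile = per_tf.groupby("cluster")[list(timepoints)].mean()

    last = timepoints[-1]
    a = profile.loc["A", last] if "A" in profile.index else np.nan
    bc = profile.reindex(["B", "C"])[last].mean()
    ratio = float(a / bc) if bc and not np.isnan(bc) and bc > 0 else np.nan
    return profile, per_tf, ratio


# ---------------------------------------------------------------------------
# Hierarchy and subnetworks
# ---------------------------------------------------------------------------

def hierarchy_fractions(
    edges: pd.DataFrame,
    assignment: ClusterAssignment,
) -> dict:
    """Directed cross-cluster edge counts and network-presence fractions.

    Counts unique (regulator, target) edges between every ordered pair of
    cluster labels, reports A->(B∪C) versus (B∪C)->A, and for each cluster
    the fraction of members present in the network as a regulator, as a
    target, and as either.
    """
    lab = assignment.labels
    uniq = edges.drop_duplicates(["regulator", "target"])
    reg_lab = uniq["regulator"].map(lab)
    tgt_lab = uniq["target"].map(lab)
    pairs = pd.DataFrame({"from": reg_lab, "to": tgt_lab}).dropna()
    counts = pairs.value_counts().rename("n_edges").reset_index()

    a_to_bc = int(((pairs["from"] == "A") & pairs["to"].isin(["B", "C"])).sum())
    bc_to_a = int((pairs["from"].isin(["B", "C"]) & (pairs["to"] == "A")).sum())

    regulators = set(edges["regulator"])
    targets = set(edges["target"])
    presence = {}
    for label in sorted(lab.unique()):
        members = set(lab.index[lab == label])
        n = len(members)
        presence[label] = {
            "n_members": n,
            "as_regulator": len(members & regulators) / n if n else 0.0,
            "as_target": len(members & targets) / n if n else 0.0,
            "either": len(members & (regulators | targets)) / n if n else 0.0,
        }
    total_cross = int((pairs["from"] != pairs["to"]).sum())
    return {"pair_counts": counts, "a_to_bc": a_to_bc, "bc_to_a": bc_to_a,
            "total_cross_cluster": total_cross, "presence": presence}


def first_order_subnetwork(
    edges: pd.DataFrame,
    focal: Sequence[str],
    netf_set: Sequence[str],
) -> nx.DiGraph:
    """Subgraph of focal TFs and the neTFs directly connected to them.

    Nodes are the focal set plus any neTF with a direct edge to or from a
    focal TF; edges are restricted to those incident to a focal TF.  Focal
    TFs missing from the network appear as isolated nodes.
    """
    focal = list(dict.fromkeys(focal))
    if not focal:
        raise ValueError("focal set must be non-empty")
    netfs = set(netf_set)
    focal_set = set(focal)
    g = nx.DiGraph()
    g.add_nodes_from(focal)
    for row in edges.drop_duplicates(["regulator", "target"]).itertuples():
        sign = getattr(row, "sign", None)
        if row.regulator in focal_set and (row.target in netfs or row.target in focal_set):
            g.add_edge(row.regulator, row.target, sign=sign)
        elif row.target in focal_set and (row.regulator in netfs or row.regulator in focal_set):
            g.add_edge(row.regulator, row.target, sign=sign)
    return g


def netf_expression_test(
    fc: pd.DataFrame,
    netf_set: Sequence[str],
    baseline: str = "ESC",
) -> pd.DataFrame:
    """Mean neTF log2FC per timepoint with a two-sided one-sample t test vs 0."""
    members = [tf for tf in netf_set if tf in fc.index]
    if len(members) < 2:
        raise ValueError("need at least two neTFs present in the fold-change matrix")
    rows = []
    for tp in fc.columns:
        if tp == baseline:
            continue
        vals = fc.loc[members, tp].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if np.allclose(vals, vals[0] if len(vals) else 0.0):
            t, p = (np.nan, 1.0 if (len(vals) and vals[0] == 0) else np.nan)
        else:
            t, p = stats.ttest_1samp(vals, popmean=0.0)
        rows.append((tp, float(np.mean(vals)), float(t), float(p), len(vals)))
    return pd.DataFrame(rows, columns=["timepoint", "mean_log2FC", "t", "p", "n"])
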