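"""The twelve spanning-tree parameters and their per-subject summaries.

Per time point, node-level parameters are the degree k_i, the normalized
betweenness centrality BC_i, and the eccentricity ecc_i; network-level
parameters are the maximum degree K, leaf fraction L_f, assortativity R,
diameter D, maximum betweenness BC, global efficiency E, characteristic
path length (path-length L), degree divergence kappa = <k^2>/<k>, and tree
hierarchy T_h = leaf_number / (2 * M * BC) with M = N - 1 edges.  All
distances are hop counts on the binarized tree.

Betweenness is normalized by (N-1)(N-2)/2 with path endpoints excluded, so
the hub of a star tree scores exactly 1.

Per subject, each parameter's time course is reduced to its temporal mean
and temporal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .mst import SpanningTree, TreeSeries

NETWORK_METRICS = [
    "k_max", "leaf_fraction", "assortativity", "diameter", "bc_max",
    "global_efficiency", "char_path_length", "degree_divergence", "tree_hierarchy",
]
NODE_METRIC_PREFIXES = ["degree", "betweenness", "eccentricity"]


@dataclass
class NodeMetricsAtT:
    degree: np.ndarray  # int, length N
    betweenness: np.ndarray  # in [0, 1]
    eccentricity: np.ndarray  # int hops


@dataclass
class TreeMetricsAtT:
    k_max: int
    leaf_number: int
    leaf_fraction: float
    assortativity: float  # NaN when undefined (e.g. star)
    diameter: int
    bc_max: float
    global_efficiency: float
    char_path_length: float
    degree_divergence: float
    tree_hierarchy: float


@dataclass
class SubjectSummary:
    subject_id: str
    temporal_mean: dict[str, float]
    temporal_variance: dict[str, float]
    t_len: int
    n_missing: dict[str, int]


def _hop_distances(tree: SpanningTree) -> np.ndarray:
    return shortest_path(tree.adjacency, method="D", unweighted=True)


def node_metrics(tree: SpanningTree, _dist: np.ndarray | None = None) -> NodeMetricsAtT:
    """Degree, normalized betweenness and eccentricity of every node."""
    d = _hop_distances(tree) if _dist is None else _dist
    n = tree.n
    deg = tree.degrees
    # node i lies on the unique s-t path iff d[s,i] + d[i,t] == d[s,t]
    on_path = d[:, :, None] + d.T[None, :, :] == d[:, None, :]  # (s, i, t)
    idx = np.arange(n)
    on_path[idx, idx, :] = False  # s == i
    on_path[:, idx, idx] = False  # t == i
    on_path[idx, :, idx] = False  # s == t
    counts = on_path.sum(axis=(0, 2)) / 2  # unordered pairs
    denom = (n - 1) * (n - 2) / 2
    betweenness = counts / denom if denom > 0 else np.zeros(n)
    ecc = d.max(axis=1).astype(np.int64)
    return NodeMetricsAtT(degree=deg, betweenness=betweenness, eccentricity=ecc)


def tree_metrics(tree: SpanningTree, node_m: NodeMetricsAtT | None = None,
                 _dist: np.ndarray | None = None) -> TreeMetricsAtT:
    """All network-level parameters of one spanning tree."""
    d = _hop_distances(tree) if _dist is None else _dist
    if node_m is None:
        node_m = node_metrics(tree, _dist=d)
    n = tree.n
    deg = node_m.degree
    leaf_number = int((deg == 1).sum())
    bc_max = float(node_m.betweenness.max())
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    # assortativity: Pearson correlation over the 2(N-1) directed endpoint pairs;
    # undefined for a star, where every edge has the hub on one side (zero
    # variance of that endpoint's degree under any edge orientation)
    ends = np.array([(deg[i], deg[j]) for i, j in tree.edges], dtype=float)
    x = np.concatenate([ends[:, 0], ends[:, 1]])
    y = np.concatenate([ends[:, 1], ends[:, 0]])
    if deg.max() == n - 1 or np.ptp(x) == 0 or np.ptp(y) == 0:
        assort = float("nan")
    else:
        assort = float(np.corrcoef(x, y)[0, 1])
    return TreeMetricsAtT(
        k_max=int(deg.max()),
        leaf_number=leaf_number,
        leaf_fraction=leaf_number / (n - 1),
        assortativity=assort,
        diameter=int(pair_d.max()),
        bc_max=bc_max,
        global_efficiency=float((1.0 / pair_d).mean()),
        char_path_length=float(pair_d.mean()),
        degree_divergence=float((deg.astype(float) ** 2).mean() / deg.mean()),
        tree_hierarchy=leaf_number / (2.0 * (n - 1) * bc_max),
    )


def metric_timecourses(trees: TreeSeries) -> pd.DataFrame:
    """One row per time point with all network- and node-level parameters.

    Node-level columns are named ``degree_<i>``, ``betweenness_<i>``,
    ``eccentricity_<i>`` with 1-based node index i.  Undefined assortativity
    values are NaN (missing), never coerced to zero.
    """
    if len(trees) == 0:
        raise ValueError("empty tree series")
    rows = []
    for tree in trees.trees:
        d = _hop_distances(tree)
        nm = node_metrics(tree, _dist=d)
        tm = tree_metrics(tree, node_m=nm, _dist=d)
        row = {name: getattr(tm, name) for name in NETWORK_METRICS}
        row["leaf_number"] = tm.leaf_number
        for i in range(tree.n):
            row[f"degree_{i + 1}"] = nm.degree[i]
            row[f"betweenness_{i + 1}"] = nm.betweenness[i]
            row[f"eccentricity_{i + 1}"] = nm.eccentricity[i]
        rows.append(row)
    return pd.DataFrame(rows)


def summary_metric_names(n_nodes: int) -> list[str]:
    """The 9 network-level + 3N node-level parameter names that get summarized."""
    names = list(NETWORK_METRICS)
    for prefix in NODE_METRIC_PREFIXES:
        names += [f"{prefix}_{i + 1}" for i in range(n_nodes)]
    return names


def temporal_summaries(
    timecourses: pd.DataFrame, subject_id: str = "", ddof: int = 1
) -> SubjectSummary:
    """Temporal mean and variance of every parameter's time course.

    Missing values (undefined assortativity) are excluded per metric with
    their count reported; an all-missing course yields NaN summaries.
    ``ddof=1`` gives the sample-variance estimator (default); 0 the
    population variant.
    """
    if len(timecourses) < 2:
        raise ValueError("need at least 2 time points to summarize")
    n_nodes = sum(c.startswith("eccentricity_") for c in timecourses.columns)
    names = summary_metric_names(n_nodes)
    means, variances, n_missing = {}, {}, {}
    for name in names:
        col = timecourses[name]
        valid = col.dropna()
        n_missing[name] = int(col.isna().sum())
        if len(valid) == 0:
            means[name] = float("nan")
            variances[name] = float("nan")
        else:
            means[name] = float(valid.mean())
            variances[name] = float(valid.var(ddof=ddof)) if len(valid) > 1 else 0.0
    return SubjectSummary(subject_id=subject_id, temporal_mean=means,
                          temporal_variance=variances,
                          t_len=len(timecourses), n_missing=n_missing)


def summaries_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Cohort table: one row per subject, columns ``mean_<m>`` and ``var_<m>``."""
    rows = {}
    for s in summaries:
        row = {f"mean_{k}": v for k, v in s.temporal_mean.items()}
        row.update({f"var_{k}": v for k, v in s.temporal_variance.items()})
        rows[s.subject_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
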