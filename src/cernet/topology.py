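"""Network topology: centralities, power-law fits, rank tests, hubs, modules.

Centrality conventions follow Cytoscape's NetworkAnalyzer, the de facto
standard in this literature: betweenness is normalized by (N-1)(N-2)/2 with
N the node count of the whole graph and endpoints excluded; closeness uses
the within-component convention (reachable - 1) / (sum of distances to
reachable nodes), so values stay in [0, 1] on disconnected graphs and
isolated nodes score 0.

Degree distributions are summarized by an ordinary least-squares line on
log10 P(k) vs log10 k over distinct observed degrees k >= 1 — the fit whose
(slope, R^2) pair is conventionally reported as evidence of scale-free
structure.  A maximum-likelihood exponent (continuous Clauset-style
approximation) is reported alongside for users who prefer it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NodeTopology",
    "PowerLawFit",
    "GroupComparison",
    "HubModule",
    "compute_centralities",
    "fit_power_law",
    "fit_loglog",
    "wilcoxon_rank_sum",
    "compare_classes",
    "select_hubs",
    "extract_module",
]


@dataclass(frozen=True)
class NodeTopology:
    node_id: str
    node_class: str
    degree: int
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    r_squared: float
    n_points: int
    intercept: float
    mle_exponent: float | None = None
    distribution: str = "raw P(k), distinct degrees k>=1"


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    method: str


@dataclass
class HubModule:
    hub_ids: tuple[str, ...]
    graph: nx.Graph

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def genes(self) -> list[str]:
        """mRNA members of the module — the gene set for enrichment."""
        return sorted(
            v for v, d in self.graph.nodes(data=True) if d.get("kind") == "mRNA"
        )


def compute_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node.

    Returns a DataFrame with columns node, node_class, degree, betweenness,
    closeness, sorted by node id; empty graph gives an empty frame.
    """
    cols = ["node", "node_class", "degree", "betweenness", "closeness"]
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(columns=cols)
    bet = nx.betweenness_centrality(graph, normalized=True)
    clo = nx.closeness_centrality(graph, wf_improved=False)
    rows = [
        {
            "node": v,
            "node_class": graph.nodes[v].get("kind", ""),
            "degree": graph.degree(v),
            "betweenness": bet[v],
            "closeness": clo[v],
        }
        for v in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows, columns=cols)


def fit_loglog(k, pk) -> PowerLawFit:
    """OLS of log10 pk on log10 k; exact log-linear input gives R^2 = 1."""
    k = np.asarray(k, dtype=float)
    pk = np.asarray(pk, dtype=float)
    if len(k) < 2:
        raise ValueError("power-law fit needs at least 2 distinct degrees")
    if np.any(k <= 0) or np.any(pk <= 0):
        raise ValueError("degrees and probabilities must be positive")
    x, y = np.log10(k), np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(
        slope=float(slope),
        r_squared=float(r2),
        n_points=len(k),
        intercept=float(intercept),
    )


def fit_power_law(degrees) -> PowerLawFit:
    """Fit the degree distribution of a node list to P(k) ~ k^slope.

    Builds the empirical probability of each distinct degree k >= 1 and
    regresses log10 P(k) on log10 k.  Raises if fewer than two distinct
    positive degrees are observed (a regular graph has no defined fit).
    """
    degrees = np.asarray(list(degrees), dtype=int)
    degrees = degrees[degrees >= 1]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 2:
        raise ValueError(
            "undefined fit: need >= 2 distinct positive degrees, "
            f"got {len(ks)}"
        )
    pk = counts / counts.sum()
    fit = fit_loglog(ks, pk)
    # continuous MLE approximation to the discrete power-law exponent
    kmin = ks.min()
    alpha = 1.0 + len(degrees) / float(np.sum(np.log(degrees / (kmin - 0.5))))
    return PowerLawFit(
        slope=fit.slope,
        r_squared=fit.r_squared,
        n_points=fit.n_points,
        intercept=fit.intercept,
        mle_exponent=float(alpha),
    )


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    w_obs = float(ranks[:na].sum())
    sums = [sum(c) for c in combinations(ranks, na)]
    total = len(sums)
    le = sum(1 for s in sums if s <= w_obs + 1e-9) / total
    ge = sum(1 for s in sums if s >= w_obs - 1e-9) / total
    return w_obs, min(1.0, 2.0 * min(le, ge))


def wilcoxon_rank_sum(values_a, values_b, metric: str = "") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Uses exact enumeration over all rank splits when the split count
    C(na+nb, na) is at most 1e5 and the pooled sample has no ties; otherwise
    the normal approximation with tie and continuity correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and math.comb(len(a) + len(b), len(a)) <= 100_000:
        w, p = _exact_rank_sum_p(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        # report the rank-sum of sample a alongside scipy's U statistic
        w = float(stats.rankdata(pooled)[: len(a)].sum())
        p = float(res.pvalue)
        method = "normal-approx"
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        statistic=w,
        p_value=float(min(1.0, p)),
        method=method,
    )


def compare_classes(
    topology: pd.DataFrame, metric: str, class_a: str, class_b: str
) -> GroupComparison:
    """Rank-sum comparison of one centrality between two node classes."""
    a = topology.loc[topology["node_class"] == class_a, metric]
    b = topology.loc[topology["node_class"] == class_b, metric]
    return wilcoxon_rank_sum(a, b, metric=f"{metric}:{class_a}-vs-{class_b}")


def _top_k_with_ties(topology: pd.DataFrame, metric: str, k: int) -> set[str]:
    vals = topology[metric].to_numpy()
    if len(vals) <= k:
        return set(topology["node"])
    threshold = np.sort(vals)[::-1][k - 1]
    return set(topology.loc[topology[metric] >= threshold, "node"])


def select_hubs(
    topology: pd.DataFrame, k: int = 10, restrict_class: str | None = None
) -> list[str]:
    """Nodes in the top-k by degree AND betweenness AND closeness.

    Each top-k set includes every node tied with the k-th value, so the
    result is independent of input ordering.  ``restrict_class`` limits the
    reported hubs to one node class after the class-agnostic ranking.
    Returned sorted by degree descending, ties by betweenness then id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if topology.empty:
        return []
    hubs = (
        _top_k_with_ties(topology, "degree", k)
        & _top_k_with_ties(topology, "betweenness", k)
        & _top_k_with_ties(topology, "closeness", k)
    )
    sub = topology[topology["node"].isin(hubs)]
    if restrict_class is not None:
        sub = sub[sub["node_class"] == restrict_class]
    sub = sub.sort_values(
        ["degree", "betweenness", "node"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return sub["node"].tolist()


def extract_module(graph: nx.Graph, hub_ids) -> HubModule:
    """Induced subgraph on the hubs and all their neighbors (the key module)."""
    hub_ids = tuple(hub_ids)
    unknown = [h for h in hub_ids if h not in graph]
    if unknown:
        raise KeyError(f"hub ids not in network: {unknown}")
    nodes = set(hub_ids)
    for h in hub_ids:
        nodes.update(graph.neighbors(h))
    return HubModule(hub_ids=hub_ids, graph=graph.subgraph(nodes).copy())
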