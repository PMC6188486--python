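"""Competing-pair scoring and the dysregulated ceRNA network (DCCN).

Two transcripts that are repressed by overlapping sets of miRNAs can buffer
each other's regulation (the competing-endogenous-RNA hypothesis).  This
module scores every circRNA-mRNA pair of a tripartite regulatory network by
the significance of their shared-miRNA overlap:

    p = P(X >= r),   X ~ Hypergeometric(m, t, n)

where ``m`` is the size of the miRNA universe, ``t`` the number of miRNAs
targeting the mRNA, ``n`` the number targeting the circRNA and ``r`` the
number shared.  Pairs with p below ``alpha`` form the edges of a bipartite
circRNA-mRNA network, the DCCN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .interactions import InteractionSet
from .triple import TripleNetwork

__all__ = ["hypergeom_pvalue", "CompetingPair", "CeRNANetwork", "build_dccn"]


def _log_comb(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pvalue(m: int, t: int, n: int, r: int) -> float:
    """Upper tail P(X >= r) of the hypergeometric overlap distribution.

    ``m`` objects, ``t`` of which are marked; ``n`` drawn without
    replacement; ``r`` the observed number of marked draws.  Computed in
    log-space so that universes up to ~1e5 miRNAs do not overflow.

    The tail is symmetric in (t, n) and non-increasing in r; ``r = 0``
    returns exactly 1.
    """
    for name, v in (("m", m), ("t", t), ("n", n), ("r", r)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    m, t, n, r = int(m), int(t), int(n), int(r)
    if not (0 <= t <= m and 0 <= n <= m):
        raise ValueError(f"need 0 <= t, n <= m; got m={m}, t={t}, n={n}")
    if not (0 <= r <= min(t, n)):
        raise ValueError(f"need 0 <= r <= min(t, n); got r={r}, t={t}, n={n}")
    if r == 0:
        return 1.0
    log_denom = _log_comb(m, n)
    terms = [
        _log_comb(t, i) + _log_comb(m - t, n - i) - log_denom
        for i in range(r, min(t, n) + 1)
        if n - i <= m - t  # overlap below n-(m-t) has zero probability
    ]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


@dataclass(frozen=True)
class CompetingPair:
    """One scored circRNA-mRNA pair; the edge unit of the DCCN."""

    circ_id: str
    mrna_id: str
    m: int
    t: int
    n: int
    r: int
    p_value: float
    shared_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (self.r <= min(self.t, self.n) <= max(self.t, self.n) <= self.m):
            raise ValueError(
                f"invalid counts for ({self.circ_id}, {self.mrna_id}): "
                f"m={self.m}, t={self.t}, n={self.n}, r={self.r}"
            )
        if self.shared_ids and len(self.shared_ids) != self.r:
            raise ValueError("shared_ids must have exactly r members")


@dataclass
class CeRNANetwork:
    """Bipartite circRNA-mRNA network of significant competing pairs.

    ``pairs`` holds every tested pair (r >= 1) with p-value and BH FDR;
    ``graph`` contains only pairs passing ``p < alpha``.
    """

    graph: nx.Graph
    pairs: pd.DataFrame
    alpha: float
    universe_size: int

    @property
    def circ_nodes(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d.get("kind") == "circRNA"}

    @property
    def mrna_nodes(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d.get("kind") == "mRNA"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_pairs_tsv(self, path) -> None:
        df = self.pairs.copy()
        df["shared_ids"] = df["shared_ids"].map(lambda s: ";".join(sorted(s)))
        df.to_csv(path, sep="\t", index=False)

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(self.graph.edges()):
                c, g = (u, v) if self.graph.nodes[u]["kind"] == "circRNA" else (v, u)
                fh.write(f"{c}\tceRNA\t{g}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _resolve_universe(universe, network: TripleNetwork) -> int:
    if isinstance(universe, (int, np.integer)):
        m = int(universe)
    elif isinstance(universe, InteractionSet):
        m = len(universe.mirnas())
    elif universe == "triple":
        m = len(network.mirna_nodes)
    else:
        raise ValueError(
            "universe must be an int, an InteractionSet, or the string 'triple'"
        )
    if m < 1:
        raise ValueError("miRNA universe is empty")
    return m


def build_dccn(network: TripleNetwork, universe, alpha: float = 0.05) -> CeRNANetwork:
    """Score all circRNA-mRNA pairs sharing at least one miRNA; keep p < alpha.

    ``universe`` sets m, the miRNA background: pass an
    :class:`~cernet.interactions.InteractionSet` to use every distinct miRNA
    seen before differential-expression filtering (the default analysis
    choice), ``"triple"`` to restrict to the tripartite network itself, or an
    explicit integer for an external (e.g. genome-wide) count.

    Pairs with no shared miRNA have p = 1 by construction and are not
    enumerated.  The raw p < alpha cut (strict) defines the network edges; a
    Benjamini-Hochberg column is reported alongside but not applied.
    """
    m = _resolve_universe(universe, network)
    g = network.graph
    circ_partners = {
        c: {u for u in g.neighbors(c)} for c in sorted(network.circ_nodes)
    }
    mrna_partners = {
        t: {u for u in g.neighbors(t)} for t in sorted(network.mrna_nodes)
    }
    rows = []
    for c, cn in circ_partners.items():
        if len(cn) > m:
            raise ValueError(f"universe m={m} smaller than n={len(cn)} for {c}")
        for t_id, tn in mrna_partners.items():
            if len(tn) > m:
                raise ValueError(f"universe m={m} smaller than t={len(tn)} for {t_id}")
            shared = cn & tn
            if not shared:
                continue
            p = hypergeom_pvalue(m, len(tn), len(cn), len(shared))
            rows.append(
                {
                    "circ_id": c,
                    "mrna_id": t_id,
                    "m": m,
                    "t": len(tn),
                    "n": len(cn),
                    "r": len(shared),
                    "p_value": p,
                    "shared_ids": frozenset(shared),
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=["circ_id", "mrna_id", "m", "t", "n", "r", "p_value", "shared_ids"],
    )
    if len(pairs):
        pairs["fdr"] = multipletests(pairs["p_value"], method="fdr_bh")[1]
        pairs = pairs.sort_values(
            ["p_value", "circ_id", "mrna_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        pairs["fdr"] = pd.Series(dtype=float)

    graph = nx.Graph()
    status = nx.get_node_attributes(g, "status")
    for row in pairs.itertuples():
        if row.p_value < alpha:
            graph.add_node(row.circ_id, kind="circRNA", status=status.get(row.circ_id, ""))
            graph.add_node(row.mrna_id, kind="mRNA", status=status.get(row.mrna_id, ""))
            graph.add_edge(
                row.circ_id, row.mrna_id, p_value=row.p_value, shared=row.r
            )
    return CeRNANetwork(graph=graph, pairs=pairs, alpha=alpha, universe_size=m)
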