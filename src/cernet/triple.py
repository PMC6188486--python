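"""Tripartite circRNA-miRNA-mRNA regulatory network assembly.

The triple network links differentially expressed (DE) miRNAs to the DE
circRNAs and DE mRNAs they are predicted to target.  Only miRNAs that pair
with at least one circRNA AND at least one mRNA are retained, because a
miRNA touching a single transcript class cannot mediate competition; targets
orphaned by that rule are dropped as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .interactions import InteractionSet

logger = logging.getLogger(__name__)

__all__ = ["TripleNetwork", "build_triple_network", "extract_class_subnetwork", "read_sif"]

RELATIONS = {"circRNA": "miRNA-circRNA", "mRNA": "miRNA-mRNA"}


def _as_status_map(de_set) -> dict[str, str]:
    if isinstance(de_set, Mapping):
        return dict(de_set)
    return {x: "DE" for x in de_set}


@dataclass
class TripleNetwork:
    """Undirected tripartite graph; node attr ``kind`` in {miRNA, circRNA,
    mRNA}, node attr ``status`` (UP/DOWN/DE), edge attr ``relation``."""

    graph: nx.Graph

    def _kind(self, kind: str) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d.get("kind") == kind}

    @property
    def mirna_nodes(self) -> set[str]:
        return self._kind("miRNA")

    @property
    def circ_nodes(self) -> set[str]:
        return self._kind("circRNA")

    @property
    def mrna_nodes(self) -> set[str]:
        return self._kind("mRNA")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict[str, int]:
        return {
            "n_mirna": len(self.mirna_nodes),
            "n_circ": len(self.circ_nodes),
            "n_mrna": len(self.mrna_nodes),
            "n_edges": self.n_edges,
        }

    def check_both_classes(self) -> None:
        """Assert every miRNA node touches both a circRNA and an mRNA."""
        g = self.graph
        for mi in self.mirna_nodes:
            kinds = {g.nodes[v]["kind"] for v in g.neighbors(mi)}
            if not {"circRNA", "mRNA"} <= kinds:
                raise AssertionError(f"miRNA {mi} lacks a partner class: {kinds}")

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                mi, tgt = (u, v) if self.graph.nodes[u]["kind"] == "miRNA" else (v, u)
                fh.write(f"{mi}\t{d['relation']}\t{tgt}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def read_sif(path) -> TripleNetwork:
    """Rebuild a triple network from its SIF serialization (edges only;
    statuses are not stored in SIF and come back empty)."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mi, relation, tgt = line.split("\t")
            kind = "circRNA" if relation == RELATIONS["circRNA"] else "mRNA"
            g.add_node(mi, kind="miRNA", status="")
            g.add_node(tgt, kind=kind, status="")
            g.add_edge(mi, tgt, relation=relation)
    return TripleNetwork(graph=g)


def build_triple_network(
    de_mirna, de_circ, de_mrna, interactions: InteractionSet
) -> TripleNetwork:
    """Assemble the DE tripartite network from interaction records.

    ``de_*`` are sets of DE feature ids, or mappings id -> status (UP/DOWN).
    Interactions whose miRNA or target is not DE are discarded; miRNAs then
    lacking a DE partner in either class are dropped with their edges, and
    orphaned targets removed.  Dropping a miRNA cannot restore another
    miRNA's missing class, and orphan removal touches no miRNA edges of the
    survivors, so one pass of each suffices for a fixed point.
    """
    mi_status = _as_status_map(de_mirna)
    circ_status = _as_status_map(de_circ)
    mrna_status = _as_status_map(de_mrna)
    overlap = (set(circ_status) & set(mrna_status)) | (
        set(mi_status) & (set(circ_status) | set(mrna_status))
    )
    if overlap:
        raise ValueError(f"DE sets overlap across classes: {sorted(overlap)[:5]}")

    df = interactions.records
    status_of = {"circRNA": circ_status, "mRNA": mrna_status}
    kept = df[
        df["mirna_id"].isin(mi_status)
        & df.apply(lambda r: r["target_id"] in status_of[r["target_class"]], axis=1)
    ] if len(df) else df

    g = nx.Graph()
    for row in kept.itertuples():
        g.add_node(row.mirna_id, kind="miRNA", status=mi_status[row.mirna_id])
        g.add_node(
            row.target_id,
            kind=row.target_class,
            status=status_of[row.target_class][row.target_id],
        )
        g.add_edge(row.mirna_id, row.target_id, relation=RELATIONS[row.target_class])

    # drop miRNAs missing a partner class, then orphaned targets
    drop = [
        mi
        for mi, d in g.nodes(data=True)
        if d["kind"] == "miRNA"
        and {g.nodes[v]["kind"] for v in g.neighbors(mi)} != {"circRNA", "mRNA"}
    ]
    g.remove_nodes_from(drop)
    g.remove_nodes_from([v for v, deg in g.degree() if deg == 0])

    net = TripleNetwork(graph=g)
    if net.n_edges == 0:
        logger.warning("triple network is empty after DE/both-classes filtering")
    return net


def extract_class_subnetwork(network: TripleNetwork, mrna_subset: Iterable[str]) -> TripleNetwork:
    """Two-hop subnetwork around a set of mRNAs (e.g. one functional category):
    the given mRNAs, every miRNA linked to them, and every circRNA linked to
    those miRNAs; the both-classes rule is then re-enforced."""
    subset = set(mrna_subset)
    unknown = subset - network.mrna_nodes
    if unknown:
        logger.warning("ignoring %d unknown mRNA ids: %s", len(unknown), sorted(unknown)[:5])
        subset -= unknown
    g = network.graph
    mirnas = {mi for t in subset for mi in g.neighbors(t)}
    circs = {
        v for mi in mirnas for v in g.neighbors(mi) if g.nodes[v]["kind"] == "circRNA"
    }
    sub = g.subgraph(subset | mirnas | circs).copy()
    drop = [
        mi
        for mi in mirnas
        if {sub.nodes[v]["kind"] for v in sub.neighbors(mi)} != {"circRNA", "mRNA"}
    ]
    sub.remove_nodes_from(drop)
    sub.remove_nodes_from([v for v, deg in sub.degree() if deg == 0])
    return TripleNetwork(graph=sub)
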