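"""Hypergeometric over-representation analysis of gene lists against GMT sets.

Given a query gene list (here, the mRNA members of a ceRNA module), each
annotation term is tested for over-representation with the hypergeometric
tail P(X >= k) — equivalent to a one-sided Fisher exact test on the 2x2
membership table — followed by Benjamini-Hochberg FDR across terms.
Significance follows the conventional double cut: FDR < 0.05 and raw
p < 0.01, both strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeom_pvalue

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "enrich", "filter_significant"]


@dataclass
class GeneSetCollection:
    """GMT-style term collection over an explicit background universe.

    ``sets``: term id -> (description, member gene ids).  Members outside the
    background are dropped at load time; terms left empty are removed.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = frozenset().union(
                *(genes for _, genes in self.sets.values())
            ) if self.sets else frozenset()
        cleaned = {}
        for term, (desc, genes) in self.sets.items():
            kept = frozenset(genes) & self.background
            if kept:
                cleaned[term] = (desc, kept)
            else:
                logger.warning("term %s empty after background restriction; dropped", term)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path, background=None) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                sets[term] = (desc, frozenset(genes))
        bg = frozenset(background) if background is not None else frozenset()
        return cls(sets=sets, background=bg)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term in sorted(self.sets):
                desc, genes = self.sets[term]
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def enrich(
    gene_list, collection: GeneSetCollection, min_term_size: int = 2
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of ``gene_list``.

    Genes outside the background are dropped (logged).  For each term of
    size K in a background of N genes, with n effective query genes and k
    hits, p = P(X >= k) under Hypergeometric(N, K, n); BH FDR is computed
    across all tested terms.  Returns a DataFrame sorted by p ascending with
    columns term, name, k, K, n, N, p_value, fdr, hit_ids.
    """
    if not len(collection):
        raise ValueError("empty gene-set collection")
    genes = set(gene_list)
    effective = genes & collection.background
    dropped = len(genes) - len(effective)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    if not effective:
        raise ValueError("no query genes remain within the background")
    N = len(collection.background)
    n = len(effective)
    rows = []
    for term in sorted(collection.sets):
        desc, members = collection.sets[term]
        K = len(members)
        if K < min_term_size:
            continue
        hits = effective & members
        p = hypergeom_pvalue(N, K, n, len(hits))
        rows.append(
            {
                "term": term,
                "name": desc,
                "k": len(hits),
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "hit_ids": ";".join(sorted(hits)),
            }
        )
    if not rows:
        raise ValueError("no terms pass min_term_size")
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return df[["term", "name", "k", "K", "n", "N", "p_value", "fdr", "hit_ids"]]


def filter_significant(
    results: pd.DataFrame, max_fdr: float = 0.05, max_p: float = 0.01
) -> pd.DataFrame:
    """Keep terms with fdr < max_fdr AND p < max_p (both strict), in order."""
    if results.empty:
        return results
    keep = (results["fdr"] < max_fdr) & (results["p_value"] < max_p)
    return results[keep].reset_index(drop=True)
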