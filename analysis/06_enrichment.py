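"""Functional enrichment of the key-module mRNAs.

Hypergeometric over-representation of the module gene list against the GMT
collection, BH FDR across terms, significance at FDR < 0.05 and p < 0.01.
The planted term should lead the ranking.
"""

from pathlib import Path

from cernet import enrichment

IN = Path("results/analysis")


def main() -> None:
    genes = [x for x in (IN / "module_genes.txt").read_text().splitlines() if x]
    coll = enrichment.GeneSetCollection.from_gmt(IN / "inputs/gene_sets.gmt")
    results = enrichment.enrich(genes, coll)
    results.to_csv(IN / "enrichment.tsv", sep="\t", index=False)
    sig = enrichment.filter_significant(results, max_fdr=0.05, max_p=0.01)
    sig.to_csv(IN / "enrichment_significant.tsv", sep="\t", index=False)
    print(f"{len(sig)} of {len(results)} terms significant (FDR<0.05, p<0.01)")
    top = results.iloc[0]
    print(
        f"top term: {top['term']} ({top['name']}) k={top['k']}/K={top['K']}, "
        f"p={top['p_value']:.3g}, fdr={top['fdr']:.3g}"
    )


if __name__ == "__main__":
    main()
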