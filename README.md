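# cernet — competing-endogenous-RNA network inference

`cernet` builds and analyses circRNA–miRNA–mRNA competing-endogenous-RNA
(ceRNA) networks from two-group RNA-seq experiments.  Circular RNAs can act
as miRNA sponges: when a circRNA and an mRNA carry response elements for
many of the same miRNAs, they compete for the same repressor pool and their
expression becomes coupled.  The package takes differential-expression
tables and miRNA-target interaction lists (the parsed output of an
energy-aware predictor such as miRanda) and produces, stage by stage:

1. **Differential expression** — low-count filtering (counts < 2 in every
   sample), CPM/TPM normalization, and thresholding at fold change > 2
   (|log2FC| > 1, strict) with p ≤ 0.05.  Precomputed DE tables from a
   dedicated count-model engine are the first-class input; a Welch t-test on
   log2(CPM+1) is built in for self-contained runs.
2. **Interaction filtering** — binding free energy ≤ −20 kcal/mol.
3. **Triple network** — the tripartite graph of DE miRNAs linked to the DE
   circRNAs and DE mRNAs they target; miRNAs must pair with both classes.
4. **Competing pairs (DCCN)** — every circRNA–mRNA pair sharing miRNAs is
   scored with the hypergeometric tail

   $$p = P(X \ge r) = 1 - \sum_{i=0}^{r-1}
         \frac{\binom{t}{i}\binom{m-t}{n-i}}{\binom{m}{n}}$$

   where *m* is the miRNA universe, *t* and *n* the numbers of miRNAs
   targeting the mRNA and the circRNA, and *r* the number shared.  Pairs
   with p < 0.05 form the dysregulated circRNA-related ceRNA network.
5. **Topology** — degree, betweenness and closeness (Cytoscape
   NetworkAnalyzer conventions), log–log least-squares power-law fits of the
   degree distribution, Wilcoxon rank-sum class comparisons, hubs as the
   intersection of the three top-10 rankings, and the key module as the
   hub-neighborhood subgraph.
6. **Enrichment** — hypergeometric over-representation of the module mRNAs
   against GMT gene sets with Benjamini–Hochberg FDR (significant at
   FDR < 0.05 and p < 0.01).

A seeded synthetic-data generator (`cernet.synth`) emulates the assumed
study design — negative-binomial counts for 3 vs 3 samples, planted DE
features at 4-fold change, planted competing pairs sharing an exact number
of miRNAs over a sparse background — and provides ground truth for recovery
tests.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic scenario (seed 1) and write to `results/analysis/`:

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_triple_network.py
python analysis/04_competing_pairs.py
python analysis/05_topology_hubs.py
python analysis/06_enrichment.py
```

which prints, among other lines:

```
mRNA: 27 up, 34 down of 200
circRNA: 10 up, 10 down of 50
251 interactions survive the energy filter
triple network: {'n_mirna': 11, 'n_circ': 15, 'n_mrna': 22, 'n_edges': 140}
universe m = 30 miRNAs; tested 254 pairs; DCCN: 74 edges between 13 circRNAs and 20 mRNAs
planted pairs recovered: 20/20
planted hub CIRC-00001 recovered: True
top term: TERM-PLANTED (planted process (DE-enriched)) k=9/K=30, p=0.000716, fdr=0.015
```

All 20 planted competing pairs reappear as DCCN edges, the planted hub
circRNA sits in the top-10 intersection hub set, and the planted gene set
leads the module enrichment — the pipeline recovers exactly the structure
that was put in.  The same run is available as one command
(`cernet run --outdir results/run --seed 1`) or from Python via
`cernet.run_pipeline(PipelineConfig(synthetic=SynthConfig(), seed=1))`,
which additionally writes a manifest with a reproducibility hash.

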