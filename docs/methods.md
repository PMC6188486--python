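# Methods

## The ceRNA model and the competing-pair statistic

The package operationalizes the competing-endogenous-RNA hypothesis on a
two-group expression study.  Differentially expressed (DE) circRNAs, miRNAs
and mRNAs are connected through predicted miRNA-target interactions into a
tripartite network (miRNA→circRNA and miRNA→mRNA edges only).  A miRNA that
pairs with only one transcript class cannot mediate competition, so miRNAs
are kept only when they touch at least one DE circRNA *and* one DE mRNA;
targets orphaned by that rule are dropped.  One removal pass per rule
reaches a fixed point: deleting a miRNA only removes edges incident to it,
which cannot restore a missing partner class for another miRNA, and orphan
removal touches no surviving miRNA edge (asserted in tests).

A circRNA *c* and mRNA *g* compete when they share significantly many
miRNAs.  With a universe of *m* miRNAs, of which *t* target *g* and *n*
target *c*, the overlap *r* under random assortment is hypergeometric, and
the reported p-value is the upper tail P(X ≥ r).  The tail is evaluated in
log-space (log-gamma binomial coefficients combined with log-sum-exp) so
universes up to ~10⁵ miRNAs neither overflow nor underflow; for r = 0 the
value is exactly 1 and such pairs are not enumerated (identical result set,
bounded work).  Pairs with p < 0.05 (strict) form the edges of the
dysregulated circRNA-related ceRNA network (DCCN); a Benjamini–Hochberg
column over all tested pairs is reported for users who prefer FDR control,
but does not gate the default network.

**Universe choice.** "All miRNAs" is not operationally defined by a
network alone.  The default takes *m* = the number of distinct miRNAs in
the input interaction table before DE filtering — reproducible from the
run's own inputs — with two alternatives: the tripartite network's own
miRNA set, or an explicit integer for a genome-wide count.  *t*, *n* and
*r* are always counted on the tripartite network's edges.

## Expression filtering

* Low-count rule: a feature is removed only if **every** sample has a count
  below 2 (the literal "in all samples" reading).
* Fold changes are computed on CPM with a pseudo-count of 1 CPM, making
  them invariant to library-size rescaling and finite on zero rows.  The
  choice of CPM (rather than TPM or an engine-internal scale) is an
  assumption; TPM is available when feature lengths are known.
* DE calls: |log2FC| > 1 strictly (fold change must *exceed* 2) and
  p ≤ 0.05 inclusive.  A `p_strict` flag switches to p < 0.05, the variant
  used by the competing-pair stage.
* The built-in two-group test is a Welch t-test on log2(CPM+1) — a simple,
  documented stand-in, not a count-model engine; precomputed DE tables are
  the canonical path.  Rows with zero variance in both groups get p = 1
  when the means agree and p = 0 otherwise.

## Interaction records

More negative binding free energy means stronger predicted binding, so the
reliability filter keeps records with energy ≤ −20 kcal/mol; the
alternative reading (dropping the strongest binders) would be nonsensical.
Records without an energy are kept and counted.  Duplicate (miRNA, target)
rows collapse to the lowest-energy record.  The bundled seed-match
predictor (exact 7mer-m8 site: reverse complement of miRNA positions 2–8,
U ≡ T) exists for fully synthetic sequence runs and is deliberately not an
alignment/thermodynamics model; its synthetic energies are ≤ −20 so its
output survives the filter.

## Topology

Centralities follow Cytoscape NetworkAnalyzer semantics, the common
toolchain in this literature: betweenness via Brandes pair-dependencies,
endpoints excluded, normalized by (N−1)(N−2)/2 with N the whole graph's
node count; closeness as (reachable−1)/Σd within each connected component,
0 for isolated nodes.  Harmonic closeness was considered and rejected as
the default because it changes hub rankings relative to the conventional
definition.

The degree distribution is summarized by ordinary least squares of
log₁₀ P(k) on log₁₀ k over distinct observed degrees k ≥ 1 — the (slope,
R²) pair conventionally quoted as evidence of scale-free structure.  This
is a descriptive fit, not an estimator with good statistical properties; a
continuous maximum-likelihood exponent (α = 1 + n/Σ ln(k/(k_min−½))) is
reported alongside.  Whether raw or cumulative distributions are fitted is
an open convention; the raw P(k) choice is recorded in the fit metadata.
Fewer than two distinct positive degrees is an error (a regular graph has
no defined fit).

Class comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration over all C(n_a+n_b, n_a) rank splits when that count is ≤ 10⁵
and the pooled sample is tie-free (two-sided p as twice the smaller tail,
capped at 1), otherwise the normal approximation with tie and continuity
correction.  The corrected approximation is slightly conservative at small
n (empirical type-I error ≈ 0.03–0.05 at the nominal 0.05).

Hubs are the intersection of the top-k (default 10) node sets by degree,
betweenness and closeness; each top-k set includes all nodes tied with the
k-th value, so the result is independent of input order.  The key module
is the induced subgraph on the hub circRNAs and all their neighbors; its
mRNA members are the gene list for enrichment.

## Enrichment

Standard hypergeometric over-representation (equivalently one-sided Fisher
exact) against GMT gene sets, using the same tail kernel as the
competing-pair test, with BH FDR across terms.  No EASE-style (k−1)
deflation is applied — the plain test is the documented, testable choice.
The background defaults to the union of the collection's members when no
explicit universe is supplied; query genes outside the background are
dropped with a logged count.  Significance uses FDR < 0.05 **and**
p < 0.01, both strict.

## Synthetic data: what it emulates and what it does not

The generator mirrors the assumed study design: two groups of 3 samples;
negative-binomial counts with variance μ + μ²φ; baseline means log-uniform
over [100, 1000] and dispersion φ = 0.05 — typical magnitudes for bulk
RNA-seq of inbred animals, where biological dispersion is low; planted DE
features (30% of mRNAs, 50% of miRNAs, 40% of circRNAs) at |log2FC| = 2,
split evenly up/down; 20 planted competing pairs each sharing exactly 5
miRNAs drawn from the planted-DE miRNAs, with ~40% of the pairs routed
through one circRNA that serves as the ground-truth hub; background
miRNA-target edges i.i.d. Bernoulli(0.01); genuine energies uniform in
[−35, −20] kcal/mol plus a 10% decoy fraction above −20 so the energy
filter demonstrably removes something.  Background edges that would push a
planted pair's shared count above its configured value are removed
deterministically, so planted sharing is exact.  When one circRNA carries
several planted pairs their miRNA sets may overlap, so non-planted pairs
involving the hub can share miRNAs even without background edges — a
side-effect of planting a hub, not of the background process.

Not emulated: read-level realism (no sequences, junctions or mapping
artifacts), technical library-size heterogeneity, correlated expression
between interacting partners, and miRNA sponging kinetics.  One realistic
artifact *is* present: with large planted-DE fractions the planted signal
itself shifts library composition, and CPM (unlike TMM-style normalization,
which is out of scope) does not correct for it, so apparent fold changes of
up-regulated features are attenuated toward the calling threshold.
Detection of planted features is therefore high but not perfect, and
planted-pair recovery varies with the seed (typically 80–100%, with the
misses concentrated in hub pairs whose shared miRNAs were attenuated below
the DE threshold).
Passing recovery tests therefore demonstrates that the inference chain is
correct under its own model assumptions, not that the thresholds are
optimal for any particular real dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run the default scenario (280 features,
~250 interactions) end-to-end in seconds; oracle comparisons use exhaustive
enumeration up to a 12-miRNA universe, 50 random graphs of ≤ 8 nodes for
centralities, 500 null replicates for the rank-sum type-I rate and 100
random configurations against Fisher's exact test — sizes at which the
independent oracles are themselves exact.  All randomness flows from one
integer seed through named substreams; identical (config, seed) reproduces
every file byte-for-byte, which the run manifest makes checkable via a
single SHA-256 hash (the output directory path is excluded from the hash,
since where results land must not change what they are).
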