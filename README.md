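# mirnet

Network analysis of miRNA–mRNA regulation from paired expression data,
with downstream gene-set over-representation, clinical-group differential
expression, and median-split survival screening.

MicroRNAs repress their target mRNAs post-transcriptionally, so a miRNA
that is active in a tissue tends to be *anti*-correlated with its targets
across samples. `mirnet` turns that observation into a mapping procedure
for bulk tumor or cell-line cohorts: find every strongly inversely
correlated miRNA–mRNA pair, organize the pairs into a bipartite graph,
and read regulatory "hubs" — groups of miRNAs acting on a shared target
program — off the graph's structure. The package is aimed at
computational biologists studying post-transcriptional regulation and at
translational groups screening candidate miRNA biomarkers against
clinical outcomes.

## Method

Given a miRNA matrix (RPM) and an mRNA matrix (FPKM) over shared samples:

1. **Inverse-correlation edges.** For every miRNA *i* and mRNA *j*,
   compute Spearman's ρ(i,j) (midranks for ties, Pearson on ranks). Keep
   the pair as an edge iff ρ < ρ_max, with ρ_max = −0.4 for tumor data
   and −0.6 for cell lines (strict inequality; no p-value gating — the
   filter is on effect size).
2. **Core filtering.** A miRNA is *core* if its degree (number of
   inversely correlated mRNAs) exceeds *d* (20 tumor / 100 cell-line).
3. **Projection and centralities.** Project the core bipartite graph
   onto miRNAs: edge (a,b) with weight w = |targets(a) ∩ targets(b)|.
   Report degree, unnormalized split-credit betweenness on the unweighted
   skeleton, harmonic closeness, and the principal eigenvector of the
   weighted adjacency scaled to max 1.
4. **Hubs.** Connected components of the core graph. An isolated
   component — miRNAs sharing no targets with anyone else — is the
   structural signature of an independent regulatory program.
5. **Enrichment.** For each hub, test its union of target genes against
   a GMT collection with the one-sided hypergeometric overlap test in an
   explicit universe; Benjamini–Hochberg q across all sets.
6. **Clinical screens.** On a treated cohort with raw miRNA counts:
   median-of-ratios size factors, log2(x/s + 1), Mann–Whitney rank-sum
   between response groups (exact when both arms ≤ 8); and per miRNA a
   median split of expression into high/low followed by a univariate Cox
   proportional-hazards fit (Efron ties, Wald 95% CI, low = reference)
   plus log-rank test and Kaplan–Meier curves.

A seeded synthetic-data generator plants hub modules (via shared latent
activities), an isolated two-miRNA module, a benefit-linked miRNA and a
known hazard ratio, so the whole pipeline is testable end to end without
patient data.

## Worked example

`python examples/01_network_from_synthetic.py` simulates 60 samples with
three planted modules and rebuilds the network:

```
edges below rho_max=-0.4 : 436
miRNAs with >=1 edge     : 10
core miRNAs (deg > 20)   : 10  carrying 100% of all edges
hubs (components)        : 2
  hub 1: 376 edges (86% of core) | miR-sim-001, ..., miR-sim-010
  hub 2: 60 edges (14% of core) | miR-sim-006, miR-sim-007
planted isolated pair    : miR-sim-006, miR-sim-007
```

The isolated planted pair is recovered as its own hub; the two bridged
modules merge into the dominant hub, whose members carry eigenvector
scores near 1 while the isolated pair scores 0 (it does not touch the
dominant component). `examples/04_survival_screen.py` then screens a
200-patient cohort where that pair's first miRNA is protective with true
hazard ratio 0.5:

```
planted protective miRNA miR-sim-006: HR 0.56 [0.40-0.76],
log-rank p = 0.0003 (truth: HR 0.5)
```

i.e. the median-split Cox screen recovers the planted effect with a
confidence interval covering the truth, and every null miRNA stays near
HR 1. The other examples cover enrichment, differential expression, and
the CLI (`mirnet simulate|network|enrich|diffexp|survive|report`), which
writes TSV/GraphML/JSON artifacts with provenance headers and is
byte-reproducible for a fixed config and seed.

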