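# Methods

This note records the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic generator does and
does not emulate, and the numerical conventions a maintainer would need
to reproduce or change behavior.

## Inverse-correlation edges

Edges are miRNA–mRNA pairs with Spearman ρ strictly below a negative
threshold. Ranks are midranks (ties share the mean of the ranks they
span) and ρ is the Pearson correlation of the rank vectors — identical
to the tie-corrected Spearman formula. Constant features have undefined
ρ; they are reported as NaN, never become edges, and their count is
logged. Matrices must be complete: a missing value is an error rather
than a silently applied pairwise deletion, because deletion policy
changes n per pair and thus the meaning of a fixed threshold.

Two named presets couple the correlation threshold with the core-degree
cutoff: `tumor` (ρ < −0.4, degree > 20) and `cell-line` (ρ < −0.6,
degree > 100). Cell-line panels, free of stromal and immune admixture,
show systematically stronger correlations; tightening the threshold
there selects a comparably sized edge set. Both values are overridable.

No p-values or multiple-testing correction are attached at the edge
level: the screen is an effect-size filter. The cost is a sample-size-
dependent false-edge rate among null pairs — about 8 × 10⁻⁴ per pair at
n = 60 for the −0.4 threshold — which matters when interpreting hub
separation (below).

All-pairs correlation ranks each feature once (O(F·n log n)) and forms
the ρ matrix as a single product of standardized rank matrices.

## Network construction

* **Bipartite graph**: nodes are the endpoints of surviving edges; a
  duplicate pair or an identifier appearing on both sides is an error.
* **Core filter**: keep miRNAs with degree strictly greater than the
  cutoff (a core miRNA regulates *more than* d mRNAs). The other
  reading — at-least-d — differs only at exact equality and is exposed
  via `keep_equal=True`.
* **Projection**: miRNAs are joined when they share ≥ 1 target; the
  weight is the shared-target count; miRNAs sharing nothing remain as
  isolated nodes.
* **Hubs**: connected components of the core bipartite graph, ordered by
  edge count. Components are the parameter-free formalization of a hub
  "having no shared targets with the rest of the network"; no community
  detection is layered on top.

### Centrality conventions

* *Degree* is the bipartite miRNA degree, not the projection degree.
* *Betweenness* is unnormalized shortest-path betweenness on the
  **unweighted** projection skeleton with credit split across equally
  short paths (hence half-integer values). Projection weights measure
  coupling strength; treating them as distances would make tightly
  coupled miRNAs "far apart", which is backwards, and scaling them as
  inverse distances would change the statistic's units seed by seed.
* *Closeness* is harmonic (sum of inverse distances, cross-component
  pairs contributing 0), because the projection is disconnected by
  design whenever an isolated hub exists and classic closeness is then
  undefined.
* *Eigenvector* centrality is the principal eigenvector of the
  **weighted** adjacency scaled to max 1, computed per connected
  component with shifted power iteration (the shift suppresses the ±λ
  oscillation of bipartite-like components; Perron–Frobenius guarantees
  a simple principal eigenvalue within a connected component). On a
  disconnected graph the mathematical principal eigenvector lives on
  the component with the largest spectral radius; other components
  score exactly 0. Spectral-radius ties (e.g. isomorphic components)
  are broken deterministically: larger component first, then smallest
  node label. An edgeless graph is fully degenerate and scores every
  node 1. The converged vector satisfies A·v = λ·v to 1e-8 relative
  residual.

## Enrichment

One-sided hypergeometric overlap test (over-representation only),
P(X ≥ k) for k of n query genes falling in a set of size K within a
universe of size N, evaluated through scipy's log-space survival
function. The universe is explicit — the intersection of the expression
matrix's genes with the collection's genes by default — because web
enrichment tools keep theirs hidden and q-values are meaningless without
knowing N. BH runs across all sets of the collection per query; the
top-10/q < 0.05 truncation is applied only in report views, never to the
stored table.

## Differential expression

The screen normalizes raw counts by median-of-ratios size factors
(geometric-mean reference over features positive in all samples),
applies log2(x/s + 1), and compares groups per miRNA with the two-sided
Mann–Whitney test: exact label enumeration when both arms have ≤ 8
samples (valid under ties, since the observed midranks are permuted),
otherwise the normal approximation with tie-corrected variance and
continuity correction. The exact and asymptotic branches differ by at
most 0.0109 in p at the crossover size (exhaustive enumeration over all
tie-free 8v8 rank splits — the intrinsic accuracy of the normal
approximation there).

This stage is deliberately *not* a negative-binomial GLM with a
variance-stabilizing transform. Every consumer of its output — group
medians, and the median-split survival screen — depends only on a
monotone transform of normalized counts, and rank statistics are
invariant to monotone transforms; the simpler transform therefore
changes no downstream decision. The reported p-values make no claim of
numerical equivalence to a GLM Wald test. The pseudocount is fixed at 1.
BH q-values are computed across the screened miRNA list; raw p-values
are retained alongside.

## Survival screening

* **Median split**: high iff expression strictly exceeds the cohort
  median (midpoint of central order statistics for even n); values tied
  with the median go low. All-constant expression is an error. Labels
  are invariant to monotone transforms, insulating the screen from the
  choice of normalization.
* **Kaplan–Meier**: product-limit estimator; subjects censored at an
  event time remain at risk at that time.
* **Log-rank**: two-group statistic with hypergeometric variance per
  distinct event time; zero total variance returns χ² = 0, p = 1. It is
  an error only when there are no events at all — a screen arm with all
  events in one stratum is still testable.
* **Cox**: univariate Newton–Raphson on the Efron tied partial
  likelihood, converged at |score| < 1e-8 (Newton steps damped to ±2 to
  prevent early overshoot); SE from the inverse observed information;
  Wald p and CI exp(β ± 1.96·se). The Efron approximation is the modern
  default for ties. The reference level is the low-expression stratum,
  so HR < 1 reads "high expression is protective". Monotone likelihood
  (complete separation of risk sets, or a score that flattens beyond
  |β| > 15 or se > 100) yields a flagged non-converged fit instead of an
  exception or an exp(20)-scale hazard ratio.

## Synthetic data generator

Each planted module m has a per-sample latent activity a ~ N(0,1);
member miRNA log-expression is a + σε and target-gene log-expression is
−β·a + σε (genes owned by several modules sum their effects). Non-
planted features are unit-normal noise. Values are exponentiated and
scaled to count magnitudes (log-normal rather than negative-binomial:
every downstream statistic is rank-based, so only the ranks matter; an
NB layer is an extension hook). Cohort counts add Poisson sampling.
Survival times are exponential with hazard h₀·HRˣ where x is the
above-median indicator of one planted miRNA — the planted HR is thus
*exactly* the estimand of the median-split screen. A fraction
`censor_rate` of subjects is censored uniformly before their event, and
clinical-benefit odds follow a logistic link on the planted miRNA's
standardized log abundance. Everything is a pure function of
(config, seed).

Default conditions: n = 60 samples; three modules of 5/2/3 miRNAs with
60/30/25 targets, the two-miRNA module fully isolated, 5 targets shared
between the first and third modules (a weak bridge, mirroring the
near-but-not-complete separation of co-occurring tumor programs); 4
null miRNAs and 110 null genes; β = 2, σ = 0.5 (marginal planted
Spearman ≈ −0.85, attenuated to ≈ −0.6 for doubly-regulated shared
genes); count scale 1000; cohorts default to 20% censoring, baseline
hazard 1/365 per day, planted HR 0.5, and a benefit base rate of 9/22
with log-odds slope 1.5. Small demo cohorts use n = 22.

What the generator does **not** emulate: library-size/batch effects,
overdispersion beyond log-normal × Poisson, tumor-purity gradients,
correlated decoy gene sets, competing risks, or informative censoring.
Tests passing on this generator show the machinery is correct and
calibrated under a clean factor model, not that real tumors satisfy it.

### A quantified limitation: hub separation is probabilistic

With ~150–400 null cross-pairs between an isolated module's features
and the rest of the core network, the per-pair false-edge rate at
(n = 60, ρ < −0.4) implies the isolated module survives as its own hub
in ~90–96% of seeds, not all of them; a single spurious edge merges
components. This is a property of effect-size-only edge filtering at
moderate n, inherited by any analysis built on it — larger cohorts or
tighter thresholds raise the separation probability steeply. The
package reports the measured separation rate rather than asserting
certainty; see `isolated_hub_rate` in the acceptance script output.

## Numerical and reporting conventions

TSV floats are written at %.17g for data (bitwise round-trip to 1e-12)
and %.10g for derived tables; edge ρ at ≥ 6 significant digits. Output
files carry a provenance comment (package version, config hash, seed,
active thresholds) and no timestamps, so identical config + seed give
byte-identical artifacts. Stage reports are recomputed from stage files
and cross-checked, never cached. GraphML export applies a display-only
degree threshold (default > 15) independent of the analytic core filter.

## Problem sizes used by tests

The statistical suites run at reduced but honest sizes chosen so each
check retains power: 1000 vector pairs for the Spearman/library
equivalence; 500 random graphs (≤ 10 projected nodes) against
brute-force enumeration; 1000 replicate × 40-set enrichment calibration
with universe 1500 / set size 100 / query 300 (sizes at which the
discrete test's attained level is ≈ 0.05, so the nominal band is
meaningful); 50 seeds for planted-structure recovery; 100 random
cohorts for survival-library equivalence plus 200 replicates at n = 500
for CI coverage; and 1000 null screens of 10 miRNAs at n = 60 for
log-rank calibration.
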