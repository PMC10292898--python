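# Methods

## The model

`netprox` implements a network-medicine screen for drug repurposing. The
substrate is the human protein–protein interactome, treated as an
undirected, unweighted graph *G*; every distance is a hop count. Two
questions are asked about each candidate compound with target set *S*
against a disease protein set *T*:

1. **Do the compound's targets form a module?** The size of the largest
   connected component (LCC) induced by *S* is compared to the LCC sizes
   of degree-matched random node sets:
   z<sub>LCC</sub> = (|LCC(S)| − μ)/σ. Compounds with |z| > 1.70 (the
   default screen threshold) occupy a coherent neighbourhood rather than
   scattering across the graph.

2. **Do they sit near the disease module?** Two proximity summaries:

   * closest distance d<sub>c</sub>(S,T) = (1/|T|) Σ<sub>t∈T</sub>
     min<sub>s∈S</sub> d(s,t),
   * shortest distance d<sub>s</sub>(S,T) = mean over all (s,t) pairs of
     d(s,t),

   each standardized as z = (d<sub>obs</sub> − μ)/σ against the same
   degree-matched null. Negative z<sub>closest</sub> means the targets
   are closer to the disease proteins than a random set of the same
   degree profile; ranking uses z<sub>closest</sub> (raw distance
   confounds degree), ties broken by raw d<sub>c</sub>, then name.

Downstream stages are conventional: the pairwise Jaccard index
quantifies how little the compounds' target sets overlap; a pooled ROC
of −z<sub>closest</sub> against known therapeutic/non-therapeutic
compound–disease pairs validates that proximity tracks indications
(screen: AUC > 0.75); differentially expressed genes are intersected
with compound targets, ranked by degree in the PPI subnetwork to
nominate hubs, and each hub is evaluated as a diagnostic marker by
single-gene ROC with a Youden-index cutoff (AUC > 0.9 = high accuracy).

## The null model

A scale-free interactome makes uniform node sampling a biased null: an
observed target set often contains hubs that uniform draws almost never
hit. Nodes are therefore stratified into degree bins (greedy merge from
the lowest degree up, closing a bin once it holds ≥ `min_bin_size`
nodes, default 100; the final undersized remainder merges downward), and
each null replicate draws, per bin, exactly as many nodes as the
observed set has there, without replacement. Defaults: 1000 replicates
per statistic; the compound set is randomized while the disease set is
held fixed (recorded in output metadata). Replicates are drawn from one
PCG64 stream per analysis with fully vectorised within-bin subset draws;
results are deterministic given the seed. σ is the sample standard
deviation of the replicates, which estimates the population sd over all
degree-matched sets — the test suite verifies this against exhaustive
enumeration on toy graphs.

Degenerate cases are flagged rather than hidden: fewer than 2 mapped
targets → `not_evaluated`; σ = 0 → `degenerate_null` with z = 0 when the
observation equals the null mean and signed infinity otherwise.

All proximity/LCC analyses run on the interactome's own largest
connected component so every distance is finite; nodes outside it (and
set members absent from it) are dropped with a warning and counted.

## Differential expression

Per-gene Welch two-sample t-tests on log2 expression with
Benjamini–Hochberg adjustment, thresholded strictly at |logFC| > 0.5 and
adjusted P < 0.05; logFC is oriented case − control (recorded in output
metadata). A moderated-variance model (as microarray pipelines use)
would share information across genes; at the default design of 26 vs 26
samples the Welch test is asymptotically equivalent and keeps the stage
self-contained. Genes constant in both groups get p = 1 when the means
agree and p = 0 when they differ (separation is then certain at any
sample size). Diagnostic cutoffs maximize J = sensitivity + specificity
− 1 over observed expression values, orientation chosen so AUC ≥ 0.5,
ties preferring higher specificity; cutoffs are reported on the input
expression scale.

The AUC-comparison test is a stratified bootstrap: positives and
negatives of each score set resampled independently (2000 replicates),
two-sided add-one-smoothed percentile p-value for the AUC difference.
Its type-I error is simulation-checked at ~5%.

## What the synthetic generator emulates — and what it does not

`SyntheticScenario` defaults define the study conditions: a 2000-node
preferential-attachment graph (attachment 2 — connected by construction,
heavy-tailed degrees), a 30-node connected disease module grown by BFS,
30 compounds of 10 targets each (3 signal, 27 null), signal overlap
fraction 0.7, a 20-disease association benchmark (10 therapeutic / 10
degree-matched negatives, disease sets of 10), and a 1000-gene, 26 + 26
expression design with 10% of genes shifted by ±2 log2 units under
Gaussian noise of sd 0.5, 12 of the shifted genes being compound
targets.

Two generator choices were genuinely open and matter:

* **Signal compounds are connected clusters.** The in-module fraction of
  a signal compound's targets is grown as a connected set expanding a
  random frontier, preferring module nodes, then module neighbours.
  Independent draws from the module neighbourhood produce scattered
  targets that carry no LCC signal and a diluted proximity signal — a
  planted compound should be detectable by the statistics the screen
  computes, as real congregated target modules are.
* **Null compounds are degree-matched to the same template profile.**
  Each null compound replaces a signal-style template node-by-node with
  degree-binned random draws, so signal and null compounds share a
  degree profile and differ only in placement. A screen that separated
  them on degree alone would be trivially confounded.

What the generator does **not** emulate: the real interactome's exact
degree sequence and clustering, literature bias in target annotation,
correlated expression (genes are independent given their group means),
probe-level artifacts, and batch effects. Passing tests therefore show
that the statistics are implemented correctly and recover signal with
the claimed operating characteristics under clean conditions — not that
those operating characteristics transfer to any particular real data
set.

## Problem sizes and numerical choices

Simulation-based checks use the default scenario at 1000 null replicates
per statistic; multi-seed checks use 50 seeds (screen recovery and null
self-consistency), 20 seeds (end-to-end ROC, DEG recovery), and 500
simulations (bootstrap calibration) — sizes chosen so each check
resolves its tolerance with comfortable binomial margin. Exhaustive
enumeration oracles run on 6–8-node toys where every degree-matched set
can be listed. Pipeline outputs are written with fixed float formatting
(`%.10g`) so identical seeds give byte-identical artifacts; the manifest
additionally carries wall-clock timings and is excluded from
byte-comparison.

## Known limitations

* Identifier namespaces are not mapped: interactome, target sets, and
  disease proteins must already share one (canonicalization is limited
  to uppercase/strip).
* Only node-set randomization is offered, not edge-rewiring
  (configuration-model) nulls.
* Proximity variants beyond closest/shortest (kernel, centre,
  separation) are out of scope, as are weighted or directed edges.
* The bootstrap AUC comparison is assumption-light but approximate; an
  analytic variance method can disagree at small n.
* With very small graphs, degree bins collapse to a single bin and
  degree matching degrades to uniform sampling (a warning is emitted).
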