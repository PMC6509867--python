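# Methods

## Model and procedure

The pipeline treats stage association as a sparse regression problem. For
each pathology stage t ∈ {t1..t4} the binary one-vs-rest label vector
Y_t ∈ {0,1}^m is regressed on the standardized multi-omics feature matrix
X ∈ R^{m×n} under

    min_beta  (1/m) ||Y_t − X·beta||²  +  lam · ( a·||beta||₁ + (1−a)·||beta||₂² )

with mixing fraction a (default 0.5, weighting the lasso and ridge terms
equally) and overall strength lam swept along a log-spaced path. The fit is
ordinary penalized least squares on the binary labels, not logistic
regression: the selection signal of interest is which coefficients are
nonzero, and the least-squares form admits exact optimality checks against
independent reference solvers. Coefficients are obtained per path point by
coordinate descent (scikit-learn's ElasticNet, reparameterized so the
objective above is minimized exactly); correctness is verified against a
bound-constrained L-BFGS-B solve of the split-positive reformulation and,
in the vanishing-L1 limit, the closed-form ridge solution.

**Stability counting.** The path has `n_models` points (default 50) from
lambda_max — the smallest penalty at which the KKT conditions hold for
beta = 0, computed as (2/m)·max_j |x_jᵀy| / a — down to
`lambda_min_ratio`·lambda_max. A gene counts as selected by a model when
any of its feature columns (expression or methylation; union, not sum) has
|beta| > `coef_threshold` (default 1e-8, i.e. numerically nonzero). Genes
selected by at least `cutoff` models (default 20) form the stage's seed
set.

**Path floor.** `lambda_min_ratio` defaults to 0.05. Selection frequency
is only informative while models are sparse: with more features than
samples, a nearly-unpenalized model activates on the order of min(m, n)
features, so extending the path into that regime credits noise features
with high counts and destroys the precision of the cutoff rule. At 0.05
the densest model on reference-sized problems (m = 200, n = 1000)
activates roughly m/2 features, keeping every path point in the sparse
regime. Users who want the conventional wide path (glmnet uses 0.01 when
features outnumber samples, 1e-4 otherwise) can set the ratio explicitly;
on data with very weak effects a lower floor raises recall at the cost of
precision.

**Modules.** Seed genes plus their direct (one-hop) neighbors in the
undirected PPI graph induce a subnetwork carrying all background edges
among its nodes (including neighbor–neighbor edges). Only the giant
connected component survives; size ties are broken first by the number of
seed genes contained, then by lexicographically smallest node list, making
the output deterministic. Module nodes keep their role (detected seed vs.
neighbor), and genes present in two stage modules get cross-stage tags of
the form `2-3N` / `2N-4N` encoding both roles with the lower stage first.

**Enrichment and the pathway network.** Over-representation of a module's
gene set in each pathway uses the upper-tail hypergeometric probability
P[overlap ≥ k] with the universe defaulting to the GMT gene universe
intersected with the measured genes, Benjamini–Hochberg adjusted within
each stage, significant at q ≤ 0.05. Pathways significant in ≥1 stage
become network nodes (one node per pathway, carrying its stage set);
every pair sharing annotated genes is linked, weighted by
W = k²/(p·q) computed on the pathways' full annotated gene sets. Edges can
be display-filtered with `min_w`; by default any shared gene (k ≥ 1) makes
an edge. Connected components, ordered by size then name, are the reported
groups; the stage composition per group is the raw material for reading an
evolution history.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_mix` | 0.5 | L1 share of the penalty; 0.5 weights lasso and ridge equally |
| `n_models` | 50 | path length (number of fitted models per stage) |
| `cutoff` | 20 | minimum number of models that must select a gene |
| `coef_threshold` | 1e-8 | \|beta\| above which a coefficient counts as a selection |
| `lambda_min_ratio` | 0.05 | path floor as a fraction of lambda_max (see above) |
| `fdr` | 0.05 | BH significance level for pathway enrichment |
| `min_w` | 0.0 | minimum overlap score for a pathway-network edge |

## Synthetic data

`synthio` generates the statistical structure the pipeline assumes, with
ground truth recorded for parameter-recovery testing. Defaults describe
the reference simulation used throughout the test suite: 200 samples
assigned uniformly to 4 stages, 500 genes, 10 planted signal genes per
stage. Planted genes are shifted by +`effect_size` (default 2) in
expression and −`effect_size` in methylation for samples of their stage —
the anti-correlation mimics the canonical promoter-methylation/expression
relation and exercises the rule that a gene's two feature columns count as
one selection. Background entries are N(0, `noise_sd`²) on a z-score-like
scale for both layers; since the pipeline standardizes features, marginal
distribution shape is not load-bearing. The PPI graph wires each stage's
planted genes to a stage hub (guaranteeing mutual reachability within two
hops, so the giant-component step has signal to find) and adds uniform
random background edges to a mean degree of 8, the density of curated
human interactomes of ~9.5k proteins and ~37k interactions; a
preferential-attachment variant is available behind a flag, as component
structure rather than the degree law is what the giant-component step
consumes. Half of the 50 pathways (sizes 10–40) are signal pathways seeded
with a majority of one stage's planted genes, and the first signal pathway
of each consecutive stage pair shares 3 genes with the next, planting the
cross-stage edges the pathway network should recover.

What the generator does **not** emulate: batch effects, probe-level
methylation structure with multi-gene CpG loci beyond the equal-sharing
rule, copy-number or mutation layers, stage-size imbalance (available via
`stage_proportions` but not default), and correlated co-expression
backgrounds. Passing recovery tests therefore demonstrate that the
pipeline's logic is correct and well-calibrated on clean additive signal;
they do not certify performance on real tumor cohorts, where effect sizes
are weaker and confounding is richer.

## Numerical choices and degenerate inputs

- Feature standardization is population z-scoring (ddof 0); constant
  columns are dropped with a warning before fitting.
- Solver tolerance defaults to 1e-8 with `max_iter` 10 000; hitting the
  iteration cap raises a warning, not an error.
- lambda_max is included as the first path point, so the first model's
  coefficients are exactly zero by the KKT conditions.
- A label vector orthogonal to every feature column yields an all-zero
  path on a nominal grid rather than an error; a constant label vector is
  rejected as degenerate.
- Empty seed sets, empty subnetworks and empty pathway networks are legal
  and produce empty outputs with warnings; a singleton giant component is
  permitted.
- Substage labels (t2a, T2b) normalize to their major stage; samples with
  a missing stage are excluded at ingest.
- Methylation loci mapped to several genes are divided equally among them,
  and a gene's value is the mean of its locus contributions — an
  order-independent rule that preserves the original scale.
- All randomness flows from a single integer seed through independent,
  crc32-tagged child streams per artifact, so regenerating one input does
  not perturb the others and repeated runs are byte-identical.

## Problem sizes used in validation

The test suite and the acceptance script validate solver optimality on
random instances up to 50 samples × 20 features (where the independent
reference minimization is reliable to ~1e-10), graph routines on random
graphs up to 200 nodes against brute-force enumeration, enrichment
p-values on universes up to 30 genes against exact combinatorics, and
end-to-end recovery on five simulated cohorts at the reference size
(200 × 500 genes, 1000 features). These sizes make the full validation run
in well under a minute while leaving the verified code paths identical to
those used at scale.

## Known limitations

- Least-squares on binary labels ignores the variance structure a
  logistic model would capture; with very unbalanced stages the selection
  power for the minority stage drops.
- The ≥20-of-50 cutoff is a frequency heuristic, not an error-controlled
  procedure; no resampling-based stability selection (subsampling or
  complementary pairs) is implemented.
- The enrichment universe choice (GMT ∩ measured genes) is conservative;
  a permissive universe inflates significance.
- Pathway groups are connected components; any denser community structure
  within a component is not resolved.
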